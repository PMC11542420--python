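"""Reading, validation and cross-trait harmonization of GWAS summary statistics.

A summary-statistic table holds one row per SNP with the canonical columns

    variant_id, chromosome, position, effect_allele, other_allele,
    eaf, beta, se, pval, n

where ``beta`` is the per-allele effect of the *effect allele* on the trait
(log-odds for binary traits), ``se`` its standard error and ``eaf`` the
effect-allele frequency.  Two-sample MR combines effects measured in
different GWAS, so before any analysis all tables must refer to the same
effect allele per SNP; :func:`harmonize` performs that alignment, flipping
signs for swapped alleles, resolving strand complements, and dropping
palindromic SNPs whose allele frequency cannot disambiguate the strand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "SummaryFormatError",
    "HarmonizationError",
    "SummaryTable",
    "HarmonizedPanel",
    "read_summary",
    "write_summary",
    "harmonize",
]

CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: eaf may be missing (NA); it is only needed for palindromic SNPs and R².
REQUIRED_COLUMNS = [c for c in CANONICAL_COLUMNS if c != "eaf"]

_NUMERIC_COLUMNS = ["position", "eaf", "beta", "se", "pval", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")

#: Palindromic SNPs with eaf in this window (in any table) are ambiguous.
PALINDROME_EAF_WINDOW = (0.42, 0.58)


class SummaryFormatError(ValueError):
    """A summary-statistic file is structurally unusable (missing columns, no valid rows)."""


class HarmonizationError(ValueError):
    """Tables cannot be harmonized (e.g. no shared variants)."""


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and G/C pairs, where strand cannot be told from alleles alone."""
    return _COMPLEMENT.get(effect_allele) == other_allele


@dataclass
class SummaryTable:
    """GWAS summary statistics for one trait, one validated record per SNP.

    ``records`` is a DataFrame with the canonical columns, unique
    ``variant_id``, and dtypes enforced by :func:`validate_records`.
    ``rejections`` lists ``(variant_id_or_row_label, reason)`` for input rows
    that failed validation.
    """

    trait_name: str
    trait_type: str = "quantitative"  # "binary" | "quantitative"
    records: pd.DataFrame = field(default_factory=lambda: _empty_records())
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"trait_type must be binary|quantitative, got {self.trait_type!r}")
        if self.records["variant_id"].duplicated().any():
            dup = self.records.loc[self.records["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant_id {dup!r} in SummaryTable")

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def equals(self, other: "SummaryTable") -> bool:
        if (self.trait_name, self.trait_type) != (other.trait_name, other.trait_type):
            return False
        a = self.records.reset_index(drop=True)
        b = other.records.reset_index(drop=True)
        return a.equals(b)


def _empty_records() -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in CANONICAL_COLUMNS})
    return _coerce_dtypes(df)


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["variant_id"] = out["variant_id"].astype(str)
    out["chromosome"] = out["chromosome"].astype(str)
    out["position"] = out["position"].astype(np.int64)
    for col in ("effect_allele", "other_allele"):
        out[col] = out[col].astype(str)
    for col in ("eaf", "beta", "se", "pval"):
        out[col] = out[col].astype(float)
    out["n"] = out["n"].astype(np.int64)
    return out[CANONICAL_COLUMNS]


def validate_records(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Validate raw rows against the record invariants.

    Returns the clean records (canonical dtypes, uppercased alleles) and the
    list of per-row rejection reasons.  Row-level problems are never fatal;
    structural problems (missing columns) raise :class:`SummaryFormatError`.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SummaryFormatError(f"missing required column(s): {', '.join(missing)}")
    df = raw.copy()
    if "eaf" not in df.columns:
        df["eaf"] = np.nan

    df["variant_id"] = df["variant_id"].astype(str).str.strip()
    df["chromosome"] = df["chromosome"].astype(str).str.strip()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, why: str) -> None:
        mask = mask.fillna(False) if mask.dtype == object else mask
        reason[(reason == "") & mask] = why

    numeric_required = ["position", "beta", "se", "pval", "n"]
    flag(df[numeric_required].isna().any(axis=1), "unparseable or missing numeric field")
    flag(~df["effect_allele"].isin(_VALID_ALLELES), "invalid effect allele")
    flag(~df["other_allele"].isin(_VALID_ALLELES), "invalid other allele")
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    flag(df["se"] <= 0, "nonpositive se")
    flag((df["eaf"] < 0) | (df["eaf"] > 1), "eaf outside [0,1]")
    flag((df["pval"] <= 0) | (df["pval"] > 1), "pval outside (0,1]")
    flag(df["n"] < 2, "sample size below 2")
    ok = reason == ""
    flag(ok & df["variant_id"].duplicated(keep="first"), "duplicate variant_id")
    ok = reason == ""

    rejections = [
        (str(df.loc[i, "variant_id"]), str(reason[i])) for i in df.index[~ok]
    ]
    clean = _coerce_dtypes(df.loc[ok, CANONICAL_COLUMNS])
    return clean.reset_index(drop=True), rejections


def read_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "quantitative",
    sep: str | None = None,
) -> SummaryTable:
    """Read a delimited summary-statistic file into a validated SummaryTable.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.  The delimiter
        is sniffed unless ``sep`` is given.
    column_map
        Mapping of file column headers to canonical field names, for files
        using non-canonical headers (e.g. ``{"SNP": "variant_id"}``).
    trait_name
        Defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        na_values=["NA"],
        dtype=str,
    )
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    records, rejections = validate_records(raw)
    if len(raw) > 0 and len(records) == 0:
        raise SummaryFormatError(
            f"all {len(raw)} rows of {path.name} failed validation "
            f"(first reason: {rejections[0][1]})"
        )
    return SummaryTable(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        records=records,
        rejections=rejections,
    )


def write_summary(table: SummaryTable, path: str | Path) -> None:
    """Write a SummaryTable as tab-delimited text; NA sentinel for missing eaf.

    Floats are written with shortest round-trip repr, so
    ``read_summary(write_summary(t))`` reproduces ``t`` field for field.
    """
    table.records.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class HarmonizedPanel:
    """Two or more traits aligned to a shared SNP set and common effect alleles.

    Per-trait arrays (``beta``, ``se``, ``eaf``, ``n``) are DataFrames indexed
    by ``snp_ids`` with one column per trait; ``effect_allele[j]`` is the
    single shared effect allele every trait's beta refers to.
    """

    snp_ids: list[str]
    trait_names: list[str]
    trait_types: dict[str, str]
    effect_allele: pd.Series
    other_allele: pd.Series
    chromosome: pd.Series
    position: pd.Series
    beta: pd.DataFrame
    se: pd.DataFrame
    eaf: pd.DataFrame
    n: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def arrays(self, trait: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta, se, eaf, n) numpy arrays for one trait, in snp_ids order."""
        return (
            self.beta[trait].to_numpy(float),
            self.se[trait].to_numpy(float),
            self.eaf[trait].to_numpy(float),
            self.n[trait].to_numpy(float),
        )

    def subset(self, snp_ids: Sequence[str]) -> "HarmonizedPanel":
        """Restrict the panel to the given SNPs (e.g. an instrument set)."""
        keep = [s for s in self.snp_ids if s in set(snp_ids)]
        return dataclasses.replace(
            self,
            snp_ids=keep,
            effect_allele=self.effect_allele.loc[keep],
            other_allele=self.other_allele.loc[keep],
            chromosome=self.chromosome.loc[keep],
            position=self.position.loc[keep],
            beta=self.beta.loc[keep],
            se=self.se.loc[keep],
            eaf=self.eaf.loc[keep],
            n=self.n.loc[keep],
            dropped=list(self.dropped),
        )

    def to_tables(self) -> list[SummaryTable]:
        """Re-express the panel as one SummaryTable per trait (for round trips)."""
        out = []
        for t in self.trait_names:
            beta = self.beta[t].to_numpy(float)
            se = self.se[t].to_numpy(float)
            n = self.n[t].to_numpy(float)
            pval = 2.0 * _norm_sf(np.abs(beta) / se)
            pval = np.clip(pval, np.finfo(float).tiny, 1.0)
            df = pd.DataFrame(
                {
                    "variant_id": self.snp_ids,
                    "chromosome": self.chromosome.to_numpy(),
                    "position": self.position.to_numpy(),
                    "effect_allele": self.effect_allele.to_numpy(),
                    "other_allele": self.other_allele.to_numpy(),
                    "eaf": self.eaf[t].to_numpy(float),
                    "beta": beta,
                    "se": se,
                    "pval": pval,
                    "n": n.astype(np.int64),
                }
            )
            out.append(
                SummaryTable(trait_name=t, trait_type=self.trait_types[t], records=_coerce_dtypes(df))
            )
        return out


def _norm_sf(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.sf(z)


def harmonize(
    tables: Sequence[SummaryTable],
    ambiguity_window: tuple[float, float] = PALINDROME_EAF_WINDOW,
) -> HarmonizedPanel:
    """Align two or more summary tables to shared SNPs and effect alleles.

    The first table defines the reference effect allele per SNP.  SNPs are
    processed in sorted variant_id order so the result does not depend on
    input row order.  For each other table and SNP:

    * exact allele match — kept as is;
    * swapped alleles — beta negated, eaf := 1 − eaf;
    * strand complement (or complement of the swap) — relabelled, then as above;
    * palindromic SNP (A/T or G/C) — dropped as ``"ambiguous palindrome"``
      whenever any table's eaf lies in ``ambiguity_window`` or is missing;
      otherwise aligned by allele labels and flipped again if the aligned eaf
      sits on the opposite side of 0.5 from the reference eaf (strand fix);
    * anything else — dropped as ``"irreconcilable alleles"``.
    """
    if len(tables) < 2:
        raise ValueError("harmonize requires at least two tables")
    names = [t.trait_name for t in tables]
    if len(set(names)) != len(names):
        raise ValueError("trait names must be unique across tables")

    frames = [t.records.set_index("variant_id") for t in tables]
    shared: set[str] = set(frames[0].index)
    for f in frames[1:]:
        shared &= set(f.index)
    if not shared:
        raise HarmonizationError("no shared variants")
    ids = sorted(shared)

    cols = {}
    for f in frames:
        sub = f.loc[ids]
        cols[id(f)] = {
            "ea": sub["effect_allele"].tolist(),
            "oa": sub["other_allele"].tolist(),
            "eaf": sub["eaf"].to_numpy(float),
            "beta": sub["beta"].to_numpy(float),
            "se": sub["se"].to_numpy(float),
            "n": sub["n"].to_numpy(np.int64),
            "chrom": sub["chromosome"].tolist(),
            "pos": sub["position"].to_numpy(np.int64),
        }

    lo, hi = ambiguity_window
    kept_idx: list[int] = []
    dropped: list[tuple[str, str]] = []
    # aligned[t] rows follow kept_idx
    aligned_beta = [[] for _ in tables]
    aligned_se = [[] for _ in tables]
    aligned_eaf = [[] for _ in tables]
    aligned_n = [[] for _ in tables]

    ref = cols[id(frames[0])]
    for j, snp in enumerate(ids):
        ea, oa = ref["ea"][j], ref["oa"][j]
        pal = is_palindromic(ea, oa)
        if pal:
            ambiguous = False
            for f in frames:
                eaf_t = cols[id(f)]["eaf"][j]
                if np.isnan(eaf_t) or (lo <= eaf_t <= hi):
                    ambiguous = True
                    break
            if ambiguous:
                dropped.append((snp, "ambiguous palindrome"))
                continue
        row_vals: list[tuple[float, float, float, int]] | None = []
        ref_eaf = ref["eaf"][j]
        for ti, f in enumerate(frames):
            c = cols[id(f)]
            res = _align_one(
                ea, oa, pal, ref_eaf,
                c["ea"][j], c["oa"][j], c["beta"][j], c["se"][j], c["eaf"][j], int(c["n"][j]),
                is_reference=(ti == 0),
            )
            if isinstance(res, str):
                dropped.append((snp, res))
                row_vals = None
                break
            row_vals.append(res)
        if row_vals is None:
            continue
        kept_idx.append(j)
        for ti, (b, s, e, nn) in enumerate(row_vals):
            aligned_beta[ti].append(b)
            aligned_se[ti].append(s)
            aligned_eaf[ti].append(e)
            aligned_n[ti].append(nn)

    kept_ids = [ids[j] for j in kept_idx]
    index = pd.Index(kept_ids, name="variant_id")

    def frame(data: list[list[float]]) -> pd.DataFrame:
        return pd.DataFrame({name: vals for name, vals in zip(names, data)}, index=index)

    return HarmonizedPanel(
        snp_ids=kept_ids,
        trait_names=list(names),
        trait_types={t.trait_name: t.trait_type for t in tables},
        effect_allele=pd.Series([ref["ea"][j] for j in kept_idx], index=index),
        other_allele=pd.Series([ref["oa"][j] for j in kept_idx], index=index),
        chromosome=pd.Series([ref["chrom"][j] for j in kept_idx], index=index),
        position=pd.Series(
            np.asarray([ref["pos"][j] for j in kept_idx], dtype=np.int64), index=index
        ),
        beta=frame(aligned_beta),
        se=frame(aligned_se),
        eaf=frame(aligned_eaf),
        n=frame(aligned_n).astype(np.int64),
        dropped=dropped,
    )


def _align_one(
    ref_ea: str,
    ref_oa: str,
    pal: bool,
    ref_eaf: float,
    ea: str,
    oa: str,
    beta: float,
    se: float,
    eaf: float,
    n: int,
    is_reference: bool,
) -> tuple[float, float, float, int] | str:
    """Align one table's record to the reference allele pair.

    Returns the aligned (beta, se, eaf, n) or a drop reason string.
    """
    if pal:
        # complement == swap for palindromic pairs, so only labels + eaf help
        if (ea, oa) == (ref_ea, ref_oa):
            pass
        elif (ea, oa) == (ref_oa, ref_ea):
            beta, eaf = -beta, 1.0 - eaf
        else:
            return "irreconcilable alleles"
        if not is_reference and (eaf - 0.5) * (ref_eaf - 0.5) < 0:
            # labels match but frequencies disagree: reported on other strand
            beta, eaf = -beta, 1.0 - eaf
        return beta, se, eaf, n
    cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
    if (ea, oa) == (ref_ea, ref_oa) or (cea, coa) == (ref_ea, ref_oa):
        return beta, se, eaf, n
    if (ea, oa) == (ref_oa, ref_ea) or (cea, coa) == (ref_oa, ref_ea):
        return -beta, se, 1.0 - eaf, n
    return "irreconcilable alleles"
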