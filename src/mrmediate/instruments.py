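"""Instrumental-variable selection and instrument-strength statistics.

Instruments are SNPs that (i) reach genome-wide significance for the
exposure (p < 5e-8 by default, strict), (ii) pass a minor-allele-frequency
floor (MAF >= 0.01), and (iii) survive greedy LD clumping within a 10,000 kb
window (r^2 < 0.01 where pairwise LD is supplied; pure position-window
thinning otherwise).  Per-SNP instrument strength uses

    R^2 = 2 * MAF * (1 - MAF) * beta^2        (variance explained)
    F   = (N - 2) * R^2 / (1 - R^2)

with F > 10 the conventional low-weak-instrument-bias threshold; sets whose
mean F is at or below 10 are flagged, never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .summary_io import SummaryTable

__all__ = [
    "InstrumentCriteria",
    "InstrumentSet",
    "NoInstrumentsError",
    "compute_r2",
    "compute_f",
    "clump",
    "select_instruments",
    "read_ld",
    "WEAK_INSTRUMENT_F",
]

#: F at or below this value flags possible weak-instrument bias.
WEAK_INSTRUMENT_F = 10.0


class NoInstrumentsError(ValueError):
    """No SNP survived the instrument-selection criteria."""


class InstrumentCriteria(BaseModel):
    """Selection thresholds for instrumental variables."""

    pval_threshold: float = Field(5e-8, gt=0)
    clump_window_kb: int = Field(10_000, gt=0)
    clump_r2: float = Field(0.01, gt=0, le=1)
    maf_min: float = Field(0.01, ge=0, le=0.5)


@dataclass
class InstrumentSet:
    """Post-QC instruments with per-SNP variance explained and F statistics.

    ``r2`` and ``f_stat`` are NaN for SNPs with missing allele frequency;
    ``mean_f`` averages over the non-missing entries.
    """

    snp_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    eaf: np.ndarray
    n: np.ndarray
    pval: np.ndarray
    r2: np.ndarray
    f_stat: np.ndarray
    mean_f: float
    weak: bool = field(default=False)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.snp_ids,
                "beta": self.beta,
                "se": self.se,
                "eaf": self.eaf,
                "n": self.n,
                "pval": self.pval,
                "r2": self.r2,
                "f_stat": self.f_stat,
            }
        )


def compute_r2(maf, beta):
    """Variance in the exposure explained by one SNP: 2*MAF*(1-MAF)*beta^2.

    ``maf`` must be the *minor* allele frequency; for an effect-allele
    frequency above 0.5 pass ``1 - eaf``.  Accepts scalars or arrays.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("maf must lie in [0, 0.5]")
    out = 2.0 * maf * (1.0 - maf) * np.asarray(beta, dtype=float) ** 2
    return out if out.ndim else float(out)


def compute_f(r2, n):
    """Instrument F statistic (N - 2) * R^2 / (1 - R^2)."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((r2 < 0) | (r2 >= 1)):
        raise ValueError("r2 must lie in [0, 1)")
    if np.any(n <= 2):
        raise ValueError("n must exceed 2")
    out = (n - 2.0) * r2 / (1.0 - r2)
    return out if out.ndim else float(out)


def read_ld(path: str | Path) -> dict[tuple[str, str], float]:
    """Read pairwise LD r^2 from 3-column delimited text (snp_a, snp_b, r2)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    ld: dict[tuple[str, str], float] = {}
    for a, b, r2 in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2].astype(float)):
        key = (str(a), str(b)) if str(a) <= str(b) else (str(b), str(a))
        ld[key] = r2
    return ld


def _pair_r2(ld: Mapping[tuple[str, str], float], a: str, b: str) -> float:
    key = (a, b) if a <= b else (b, a)
    return float(ld.get(key, 0.0))


def clump(
    candidates: pd.DataFrame,
    criteria: InstrumentCriteria | None = None,
    ld: Mapping[tuple[str, str], float] | None = None,
) -> list[str]:
    """Greedy clumping of significant SNPs into approximately independent hits.

    Repeatedly takes the smallest-p remaining SNP (ties broken by
    variant_id) and removes every remaining SNP on the same chromosome
    within ``clump_window_kb`` that is in LD (r^2 >= ``clump_r2``) with it.
    Without an LD lookup, everything inside the window is removed — position
    thinning, the conservative degenerate case.  Output order follows
    selection order; the result is independent of input row order.
    """
    if len(candidates) == 0:
        raise ValueError("clump requires at least one candidate SNP")
    criteria = criteria or InstrumentCriteria()
    df = candidates.sort_values(["pval", "variant_id"], kind="mergesort")
    ids = df["variant_id"].tolist()
    chrom = df["chromosome"].tolist()
    pos = df["position"].to_numpy(np.int64)
    window_bp = criteria.clump_window_kb * 1000
    alive = np.ones(len(df), dtype=bool)
    kept: list[str] = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(ids[i])
        alive[i] = False
        for j in range(len(df)):
            if not alive[j] or chrom[j] != chrom[i]:
                continue
            if abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            if ld is None or _pair_r2(ld, ids[i], ids[j]) >= criteria.clump_r2:
                alive[j] = False
    return kept


def select_instruments(
    table: SummaryTable,
    criteria: InstrumentCriteria | None = None,
    ld: Mapping[tuple[str, str], float] | None = None,
) -> InstrumentSet:
    """Apply the three selection criteria and compute per-SNP R^2 and F.

    SNPs with missing eaf cannot be MAF-filtered or strength-scored; they are
    retained as instruments with NaN R^2/F and a warning, since frequency is
    only needed for the strength statistics.
    """
    criteria = criteria or InstrumentCriteria()
    df = table.records
    sig = df["pval"] < criteria.pval_threshold  # strict, per the "<" convention
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    maf_ok = (maf >= criteria.maf_min) | df["eaf"].isna()
    df = df.loc[sig & maf_ok]
    if len(df) == 0:
        raise NoInstrumentsError(
            f"no instruments for {table.trait_name!r}: no SNP passes "
            f"p < {criteria.pval_threshold:g} and MAF >= {criteria.maf_min:g}"
        )
    kept = clump(df, criteria, ld)
    df = df.set_index("variant_id").loc[kept].reset_index()

    eaf = df["eaf"].to_numpy(float)
    beta = df["beta"].to_numpy(float)
    n = df["n"].to_numpy(float)
    maf = np.minimum(eaf, 1.0 - eaf)
    missing = np.isnan(maf)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} instrument(s) lack eaf; excluded from R^2/F",
            stacklevel=2,
        )
    r2 = np.full(len(df), np.nan)
    f_stat = np.full(len(df), np.nan)
    ok = ~missing
    r2[ok] = compute_r2(maf[ok], beta[ok])
    r2[ok] = np.minimum(r2[ok], np.nextafter(1.0, 0.0))  # guard pathological beta
    f_stat[ok] = compute_f(r2[ok], n[ok])
    mean_f = float(np.nanmean(f_stat)) if ok.any() else float("nan")
    return InstrumentSet(
        snp_ids=df["variant_id"].tolist(),
        beta=beta,
        se=df["se"].to_numpy(float),
        eaf=eaf,
        n=df["n"].to_numpy(np.int64),
        pval=df["pval"].to_numpy(float),
        r2=r2,
        f_stat=f_stat,
        mean_f=mean_f,
        weak=bool(np.isfinite(mean_f) and mean_f <= WEAK_INSTRUMENT_F),
    )
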