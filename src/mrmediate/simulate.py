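"""Synthetic GWAS summary statistics with recorded ground truth.

The generator emulates the summary-level structure a two-sample MR mediation
study consumes: three GWAS (exposure, mediator, outcome) over a shared panel
of independent SNPs, where a subset of SNPs instruments the exposure, a
disjoint subset instruments the mediator directly, and true per-SNP effects
follow the mediation model

    mediator effect_j = a * gamma_j + delta_j + pleio_m_j
    outcome  effect_j = direct * gamma_j + b * (mediator effect_j) + pleio_y_j

with gamma_j the exposure effects, delta_j the mediator-specific effects and
pleio_* horizontal-pleiotropy draws (mean 0 = balanced, nonzero = directional).
Observed betas add sampling noise with the standardized-trait standard error

    se_T,j = 1 / sqrt(2 * maf_j * (1 - maf_j) * N_T)

so per-trait sample sizes control precision exactly as in real summary data.
The implied true total effect is c = direct + a*b and the true proportion
mediated a*b/c.  Everything is driven by one integer seed, so identical
configs give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .summary_io import SummaryTable, _coerce_dtypes

__all__ = ["SimulationConfig", "SimulatedStudy", "TruthRecord", "simulate_study", "scenario_battery", "SCENARIOS"]

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPAL_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and (a, b) not in _PALINDROMIC_PAIRS
]


class SimulationConfig(BaseModel):
    """Generative parameters for one synthetic three-trait study.

    Defaults are the "valid" study conditions: 50 strong exposure
    instruments and 30 mediator-specific instruments among 100 independent
    SNPs; effect sizes a = 0.26, b = 0.30, direct = 1.0 (true proportion
    mediated = 0.078/1.078 ~ 7.2%); GWAS sample sizes on the scale of the
    insomnia/BMI/low-back-pain cohorts the design mirrors.
    """

    n_snps: int = Field(100, ge=1)
    n_instruments: int = Field(50, ge=0)
    n_mediator_instruments: int = Field(30, ge=0)
    maf_range: tuple[float, float] = (0.1, 0.5)
    exposure_effect_sd: float = Field(0.2, ge=0)
    mediator_effect_sd: float = Field(0.2, ge=0)
    true_a: float = 0.26
    true_b: float = 0.30
    true_direct: float = 1.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = Field(0.0, ge=0)
    n_exposure: int = Field(1_000_000, ge=100)
    n_mediator: int = Field(800_000, ge=100)
    n_outcome: int = Field(180_000, ge=100)
    palindromic_frac: float = Field(0.0, ge=0, le=1)
    allele_swap_frac: float = Field(0.2, ge=0, le=1)
    position_spacing_kb: int = Field(10_001, gt=0)
    outcome_binary: bool = True
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.n_instruments + self.n_mediator_instruments > self.n_snps:
            raise ValueError("instrument counts exceed n_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        return self

    @property
    def true_c(self) -> float:
        return self.true_direct + self.true_a * self.true_b

    @property
    def true_proportion(self) -> float:
        c = self.true_c
        return self.true_a * self.true_b / c if c != 0 else float("nan")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated study."""

    config: SimulationConfig
    gamma: np.ndarray
    delta: np.ndarray
    pleio_m: np.ndarray
    pleio_y: np.ndarray
    instrument_ids: list[str]
    mediator_instrument_ids: list[str]
    c: float
    proportion: float

    def as_dict(self) -> dict[str, Any]:
        return {
            "config": self.config.model_dump(),
            "c": self.c,
            "proportion": self.proportion,
            "instrument_ids": self.instrument_ids,
            "mediator_instrument_ids": self.mediator_instrument_ids,
        }


@dataclass
class SimulatedStudy:
    exposure: SummaryTable
    mediator: SummaryTable
    outcome: SummaryTable

    truth: TruthRecord

    @property
    def tables(self) -> list[SummaryTable]:
        return [self.exposure, self.mediator, self.outcome]


def _observed(rng, true_effect, se):
    return true_effect + se * rng.standard_normal(len(se))


def _pvals(beta, se):
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # z ~ 100+ underflows the normal tail to 0.0; keep p in (0, 1]
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one three-trait study; same seed, same bytes."""
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)

    gamma = np.zeros(m)
    gamma[: config.n_instruments] = config.exposure_effect_sd * rng.standard_normal(
        config.n_instruments
    )
    delta = np.zeros(m)
    sl = slice(config.n_instruments, config.n_instruments + config.n_mediator_instruments)
    delta[sl] = config.mediator_effect_sd * rng.standard_normal(config.n_mediator_instruments)
    pleio_m = config.pleiotropy_mean + config.pleiotropy_sd * rng.standard_normal(m)
    pleio_y = config.pleiotropy_mean + config.pleiotropy_sd * rng.standard_normal(m)

    true_med = config.true_a * gamma + delta + pleio_m
    true_out = config.true_direct * gamma + config.true_b * true_med + pleio_y

    ids = [f"rs{i + 1:05d}" for i in range(m)]
    chrom = [str(i % 22 + 1) for i in range(m)]
    pos = np.array(
        [(i // 22 + 1) * config.position_spacing_kb * 1000 + (i % 22) for i in range(m)],
        dtype=np.int64,
    )
    pal = rng.random(m) < config.palindromic_frac
    pair_idx = rng.integers(0, 4, size=m)
    nonpal_idx = rng.integers(0, len(_NONPAL_PAIRS), size=m)
    ea = np.where(pal, [_PALINDROMIC_PAIRS[i][0] for i in pair_idx], [_NONPAL_PAIRS[i][0] for i in nonpal_idx])
    oa = np.where(pal, [_PALINDROMIC_PAIRS[i][1] for i in pair_idx], [_NONPAL_PAIRS[i][1] for i in nonpal_idx])
    eaf = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)

    def table(name, trait_type, true_effect, n_samples, swap_mask):
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_samples)
        beta = _observed(rng, true_effect, se)
        b, e = beta.copy(), eaf.copy()
        ea_t, oa_t = ea.copy(), oa.copy()
        b[swap_mask] *= -1.0
        e[swap_mask] = 1.0 - e[swap_mask]
        ea_t[swap_mask], oa_t[swap_mask] = oa[swap_mask], ea[swap_mask]
        df = pd.DataFrame(
            {
                "variant_id": ids,
                "chromosome": chrom,
                "position": pos,
                "effect_allele": ea_t,
                "other_allele": oa_t,
                "eaf": e,
                "beta": b,
                "se": se,
                "pval": _pvals(beta, se),
                "n": np.full(m, n_samples, dtype=np.int64),
            }
        )
        return SummaryTable(trait_name=name, trait_type=trait_type, records=_coerce_dtypes(df))

    no_swap = np.zeros(m, dtype=bool)
    swap_med = rng.random(m) < config.allele_swap_frac
    swap_out = rng.random(m) < config.allele_swap_frac
    exposure = table("exposure", "quantitative", gamma, config.n_exposure, no_swap)
    mediator = table("mediator", "quantitative", true_med, config.n_mediator, swap_med)
    outcome = table(
        "outcome",
        "binary" if config.outcome_binary else "quantitative",
        true_out,
        config.n_outcome,
        swap_out,
    )
    truth = TruthRecord(
        config=config,
        gamma=gamma,
        delta=delta,
        pleio_m=pleio_m,
        pleio_y=pleio_y,
        instrument_ids=ids[: config.n_instruments],
        mediator_instrument_ids=ids[sl],
        c=config.true_c,
        proportion=config.true_proportion,
    )
    return SimulatedStudy(exposure=exposure, mediator=mediator, outcome=outcome, truth=truth)


#: Named study conditions.  "valid" is the reference mediation study; the
#: pleiotropy scenarios perturb only the pleiotropy draws; the null
#: scenarios zero out the causal paths they are named for.
SCENARIOS: dict[str, dict[str, Any]] = {
    "valid": {"seed": 101},
    "balanced_pleiotropy": {"seed": 202, "pleiotropy_mean": 0.0, "pleiotropy_sd": 0.002},
    "directional_pleiotropy": {"seed": 303, "pleiotropy_mean": 0.002, "pleiotropy_sd": 0.002},
    # complete null: no causal paths at all, so the true total effect is 0
    "null_effect": {"seed": 404, "true_a": 0.0, "true_b": 0.0, "true_direct": 0.0},
    # a candidate mediator with no causal role (neither upstream nor
    # downstream), like the screened-out mediators in a real study
    "null_mediator": {"seed": 505, "true_a": 0.0, "true_b": 0.0, "true_direct": 1.0},
}


def scenario_battery(name: str, **overrides: Any) -> SimulationConfig:
    """A fully specified, seeded config for a named scenario.

    Overrides replace individual fields; everything else keeps the scenario
    defaults.  Unknown names raise with the list of valid scenarios.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    params = dict(SCENARIOS[name])
    params.update(overrides)
    return SimulationConfig(**params)
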