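"""Multivariable inverse-variance-weighted Mendelian randomization.

Regresses outcome betas jointly on two or more exposures' betas (no
intercept, weights 1/se_Y^2).  Each exposure's coefficient is its *direct*
effect on the outcome conditional on the other exposures — the quantity the
two-step mediation decomposition needs for the mediator (its effect on the
outcome adjusting for the primary exposure).  SEs use the weighted residual
variance floored at 1 (multiplicative random effects, matching the
univariable IVW convention); residual heterogeneity is the weighted residual
sum of squares on J - k degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .summary_io import HarmonizedPanel
from .uvmr import Z95, MREstimate

__all__ = ["MVMRResult", "mvmr_ivw"]


@dataclass
class MVMRResult:
    """Per-exposure direct effects plus residual-heterogeneity diagnostics."""

    exposures: list[str]
    outcome: str
    estimates: dict[str, MREstimate]
    n_snps: int
    q_stat: float
    q_pval: float

    def __getitem__(self, exposure: str) -> MREstimate:
        return self.estimates[exposure]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.exposures:
            e = self.estimates[name]
            rows.append(
                {
                    "exposure": name,
                    "n_snps": e.n_snps,
                    "beta": e.beta,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "odds_ratio": e.odds_ratio,
                    "or_ci_low": e.or_ci_low,
                    "or_ci_high": e.or_ci_high,
                    "pval": e.pval,
                }
            )
        return pd.DataFrame(rows)


def mvmr_ivw(
    panel: HarmonizedPanel,
    outcome: str,
    exposures: Sequence[str] | None = None,
    snp_ids: Sequence[str] | None = None,
) -> MVMRResult:
    """Multivariable IVW over a harmonized panel.

    Requires more instruments than exposures and a full-column-rank exposure
    beta matrix.  With a single exposure this reduces exactly to the
    univariable random-effects IVW (same point estimate and floored SE).
    """
    p = panel if snp_ids is None else panel.subset(snp_ids)
    if exposures is None:
        exposures = [t for t in p.trait_names if t != outcome]
    exposures = list(exposures)
    k = len(exposures)
    if k < 1:
        raise ValueError("mvmr_ivw requires at least one exposure")
    x = np.column_stack([p.beta[e].to_numpy(float) for e in exposures])
    by, sy, _, _ = p.arrays(outcome)
    j = len(by)
    if j <= k:
        raise ValueError(f"insufficient instruments: J={j} <= k={k}")
    if np.linalg.matrix_rank(x) < k:
        raise ValueError("collinear exposures: exposure beta matrix is rank deficient")

    fit = sm.WLS(by, x, weights=1.0 / sy**2).fit()
    scale = float(fit.scale)  # weighted residual mean square, df = J - k
    infl = np.sqrt(max(1.0, scale) / scale)
    q = float(np.sum((by - fit.fittedvalues) ** 2 / sy**2))
    q_pval = float(stats.chi2.sf(q, j - k))

    binary = p.trait_types.get(outcome) == "binary"
    estimates = {}
    for i, name in enumerate(exposures):
        beta = float(fit.params[i])
        se = float(fit.bse[i]) * infl
        est = MREstimate(
            method="mvmr_ivw",
            beta=beta,
            se=se,
            ci_low=beta - Z95 * se,
            ci_high=beta + Z95 * se,
            pval=float(2 * stats.norm.sf(abs(beta) / se)),
            n_snps=j,
        )
        estimates[name] = est.exponentiate() if binary else est
    return MVMRResult(
        exposures=exposures,
        outcome=outcome,
        estimates=estimates,
        n_snps=j,
        q_stat=q,
        q_pval=q_pval,
    )
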