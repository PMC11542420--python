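"""Univariable two-sample Mendelian randomization estimators and diagnostics.

Per-SNP causal estimates are Wald ratios beta_Y / beta_X with first-order
standard errors se_Y / |beta_X|.  Five estimators combine them:

* ``ivw`` — inverse-variance-weighted meta-analysis, equivalently a
  zero-intercept weighted regression of outcome on exposure betas with
  weights 1/se_Y^2.  The multiplicative random-effects SE inflates the
  fixed-effects SE by max(1, sqrt(Q/(J-1))) and never shrinks below it.
* ``egger`` — the same regression with a free intercept after orienting all
  SNPs to non-negative exposure betas; the intercept estimates average
  directional pleiotropy, the slope the causal effect.
* ``weighted_median`` — the ratio at cumulative inverse-variance weight 0.5,
  consistent when valid instruments carry a majority of the weight.
* ``weighted_mode`` / ``simple_mode`` — argmax of a Gaussian-kernel-smoothed
  density of the ratios (inverse-variance or uniform weights), consistent
  when the largest cluster of ratios is the valid one.

Cochran's Q quantifies heterogeneity of the ratios around the fitted model;
the MR-Egger intercept test probes directional pleiotropy.  A report bundle
runs all five, checks cross-method direction consistency against IVW, and
picks the random-effects IVW as headline whenever Q is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .summary_io import HarmonizedPanel

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "HeterogeneityResult",
    "PleiotropyResult",
    "UVMRReport",
    "UVMROptions",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "simple_mode",
    "cochran_q",
    "run_uvmr",
    "panel_arrays",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class RatioEstimate:
    snp_id: str
    ratio: float
    ratio_se: float


@dataclass
class MREstimate:
    """One estimator's causal estimate with normal-theory 95% CI.

    ``odds_ratio`` (and its CI) is populated only for binary outcomes, as
    exp(beta); the log scale is always the primary scale.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    def exponentiate(self) -> "MREstimate":
        return replace(
            self,
            odds_ratio=float(np.exp(self.beta)),
            or_ci_low=float(np.exp(self.ci_low)),
            or_ci_high=float(np.exp(self.ci_high)),
        )


@dataclass
class HeterogeneityResult:
    q_stat: float
    df: int
    pval: float
    i2: float
    method: str = "ivw"


@dataclass
class PleiotropyResult:
    intercept: float
    intercept_se: float
    pval: float


class UVMROptions:
    """Estimator options: effects model, bootstrap reps, mode bandwidth, seed."""

    def __init__(
        self,
        effects_model: str = "random",
        n_boot: int = 1000,
        bandwidth_factor: float = 1.0,
        seed: int = 0,
    ):
        if effects_model not in ("fixed", "random"):
            raise ValueError("effects_model must be fixed|random")
        if n_boot < 1:
            raise ValueError("n_boot must be positive")
        if bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be positive")
        self.effects_model = effects_model
        self.n_boot = int(n_boot)
        self.bandwidth_factor = float(bandwidth_factor)
        self.seed = int(seed)


def panel_arrays(
    panel: HarmonizedPanel,
    exposure: str,
    outcome: str,
    snp_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Extract aligned (bx, sx, by, sy, ids) for an exposure/outcome pair."""
    p = panel if snp_ids is None else panel.subset(snp_ids)
    bx, sx, _, _ = p.arrays(exposure)
    by, sy, _, _ = p.arrays(outcome)
    return bx, sx, by, sy, list(p.snp_ids)


def wald_ratios(
    bx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    snp_ids: Sequence[str] | None = None,
) -> list[RatioEstimate]:
    """Per-SNP Wald ratios by/bx with first-order SE sy/|bx|.

    SNPs with a zero exposure beta are excluded (ratio undefined).
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    ids = list(snp_ids) if snp_ids is not None else [f"snp_{i}" for i in range(len(bx))]
    out = []
    for i in range(len(bx)):
        if bx[i] == 0:
            import warnings

            warnings.warn(f"{ids[i]}: zero exposure beta, Wald ratio undefined", stacklevel=2)
            continue
        out.append(RatioEstimate(ids[i], float(by[i] / bx[i]), float(sy[i] / abs(bx[i]))))
    return out


def _ivw_core(bx, by, sy):
    w = bx**2 / sy**2
    ratio = by / bx
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratio - beta) ** 2))
    return beta, se_fixed, q, w


def ivw(
    bx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    effects_model: str = "random",
) -> MREstimate:
    """Inverse-variance-weighted estimate over >= 2 instruments.

    With ``effects_model="random"`` the SE is the fixed-effects SE times
    max(1, sqrt(Q/(J-1))) (multiplicative overdispersion, floored so it never
    undercuts the fixed-effects SE).  P-values are two-sided normal.
    """
    bx, by, sy = (np.asarray(a, float) for a in (bx, by, sy))
    j = len(bx)
    if j < 2:
        raise ValueError("IVW requires >= 2 instruments")
    if effects_model not in ("fixed", "random"):
        raise ValueError("effects_model must be fixed|random")
    beta, se_fixed, q, _ = _ivw_core(bx, by, sy)
    se = se_fixed
    if effects_model == "random":
        se = se_fixed * max(1.0, np.sqrt(q / (j - 1)))
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return MREstimate(
        method=f"ivw_{effects_model}",
        beta=beta,
        se=float(se),
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=pval,
        n_snps=j,
    )


def egger(
    bx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger regression: weighted fit of by on bx with a free intercept.

    SNPs are first oriented so every exposure beta is non-negative.  SEs use
    the weighted-regression residual variance floored at 1 (multiplicative
    random effects); p-values are two-sided t with J-2 df.
    """
    bx, by, sy = (np.asarray(a, float) for a in (bx, by, sy))
    j = len(bx)
    if j < 3:
        raise ValueError("MR-Egger requires >= 3 instruments")
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    scale = float(fit.scale)  # weighted residual mean square, df = J - 2
    infl = np.sqrt(max(1.0, scale) / scale)
    inter, slope = (float(v) for v in fit.params)
    se_inter, se_slope = (float(v) * infl for v in fit.bse)
    t95 = stats.t.ppf(0.975, j - 2)
    slope_p = float(2 * stats.t.sf(abs(slope) / se_slope, j - 2))
    inter_p = float(2 * stats.t.sf(abs(inter) / se_inter, j - 2))
    est = MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - t95 * se_slope,
        ci_high=slope + t95 * se_slope,
        pval=slope_p,
        n_snps=j,
    )
    return est, PleiotropyResult(intercept=inter, intercept_se=se_inter, pval=inter_p)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(estimator, ratios, ratio_se, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    draws = ratios + ratio_se * rng.standard_normal((n_boot, len(ratios)))
    ests = np.array([estimator(row) for row in draws])
    return float(np.std(ests, ddof=1))


def _finish(method, beta, se, j, n_boot_note=None) -> MREstimate:
    pval = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else (0.0 if beta else 1.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=pval,
        n_snps=j,
    )


def weighted_median(
    ratios: Sequence[RatioEstimate] | np.ndarray,
    ratio_se: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Ratios are ordered with normalized inverse-variance weights; the
    estimate interpolates linearly to cumulative weight 0.5.  The SE is the
    SD of the estimate over ``n_boot`` resamples ratio_j* ~ N(ratio_j, se_j).
    """
    r, s = _ratio_arrays(ratios, ratio_se)
    if len(r) < 3:
        raise ValueError("weighted median requires >= 3 instruments")
    w = 1.0 / s**2
    beta = _weighted_median(r, w)
    se = _bootstrap_se(lambda rr: _weighted_median(rr, w), r, s, n_boot, seed)
    return _finish("weighted_median", beta, se, len(r))


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    r = np.asarray(ratios, float)
    if np.ptp(r) == 0:
        return float(r[0])
    sd = float(np.std(r, ddof=1))
    q75, q25 = np.percentile(r, [75, 25])
    iqr = float(q75 - q25)
    h = 0.9 * min(sd, iqr / 1.349) * len(r) ** -0.2 * bandwidth_factor
    if h <= 0:  # degenerate IQR with spread: fall back to sd bandwidth
        h = 0.9 * sd * len(r) ** -0.2 * bandwidth_factor
    w = weights / weights.sum()
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[int(np.argmax(dens))])


def _mode_estimate(ratios, ratio_se, weights, method, bandwidth_factor, n_boot, seed):
    r, s = _ratio_arrays(ratios, ratio_se)
    if len(r) < 3:
        raise ValueError(f"{method} requires >= 3 instruments")
    w = weights(r, s)
    beta = _mode_point(r, w, bandwidth_factor)
    se = _bootstrap_se(lambda rr: _mode_point(rr, w, bandwidth_factor), r, s, n_boot, seed)
    return _finish(method, beta, se, len(r))


def weighted_mode(ratios, ratio_se=None, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode estimator with inverse-variance weights and bootstrap SE."""
    return _mode_estimate(
        ratios, ratio_se, lambda r, s: 1.0 / s**2, "weighted_mode", bandwidth_factor, n_boot, seed
    )


def simple_mode(ratios, ratio_se=None, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode estimator with uniform weights and bootstrap SE."""
    return _mode_estimate(
        ratios, ratio_se, lambda r, s: np.ones_like(r), "simple_mode", bandwidth_factor, n_boot, seed
    )


def _ratio_arrays(ratios, ratio_se):
    if ratio_se is not None:
        return np.asarray(ratios, float), np.asarray(ratio_se, float)
    return (
        np.array([x.ratio for x in ratios], float),
        np.array([x.ratio_se for x in ratios], float),
    )


def cochran_q(
    bx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    method: str = "ivw",
) -> HeterogeneityResult:
    """Cochran's Q around the fixed-effects fit of the named method.

    For IVW, Q = sum w_j (ratio_j - beta)^2 with w_j = bx_j^2/sy_j^2 and
    df = J-1; for Egger the weighted residual sum of squares of the
    intercept-plus-slope fit, df = J-2.  P from the chi-square null; I^2 is
    the excess-heterogeneity fraction max(0, (Q-df)/Q).
    """
    bx, by, sy = (np.asarray(a, float) for a in (bx, by, sy))
    j = len(bx)
    if method == "ivw":
        if j < 2:
            raise ValueError("Q (IVW) requires >= 2 instruments")
        _, _, q, _ = _ivw_core(bx, by, sy)
        df = j - 1
    elif method == "egger":
        if j < 3:
            raise ValueError("Q (Egger) requires >= 3 instruments")
        flip = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * flip, by * flip
        fit = sm.WLS(byo, sm.add_constant(bxo), weights=1.0 / sy**2).fit()
        q = float(np.sum((byo - fit.fittedvalues) ** 2 / sy**2))
        df = j - 2
    else:
        raise ValueError("method must be ivw|egger")
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q_stat=q, df=df, pval=pval, i2=i2, method=method)


@dataclass
class UVMRReport:
    """All five estimators plus heterogeneity/pleiotropy diagnostics.

    ``headline`` names the estimate a reader should quote: random-effects
    IVW when Q's p < 0.05 (significant heterogeneity), fixed-effects IVW
    otherwise.  ``direction_consistent`` is True iff all five estimators'
    betas share the IVW sign.
    """

    exposure: str
    outcome: str
    estimates: dict[str, MREstimate]
    heterogeneity: HeterogeneityResult
    heterogeneity_egger: HeterogeneityResult
    pleiotropy: PleiotropyResult
    direction_consistent: bool
    headline: str
    snp_ids: list[str] = field(default_factory=list)

    @property
    def headline_estimate(self) -> MREstimate:
        return self.estimates[self.headline]

    def to_frame(self) -> pd.DataFrame:
        """Per-method rows (method, n_snps, beta, se, CI, OR, p)."""
        rows = []
        for key in ("ivw_fixed", "ivw_random", "egger", "weighted_median", "weighted_mode", "simple_mode"):
            e = self.estimates[key]
            rows.append(
                {
                    "method": key,
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

    def diagnostics_frame(self) -> pd.DataFrame:
        """Single-row diagnostics mirroring a heterogeneity/pleiotropy table."""
        return pd.DataFrame(
            [
                {
                    "exposure": self.exposure,
                    "outcome": self.outcome,
                    "cochran_q_ivw": self.heterogeneity.q_stat,
                    "q_pval_ivw": self.heterogeneity.pval,
                    "egger_intercept": self.pleiotropy.intercept,
                    "egger_intercept_pval": self.pleiotropy.pval,
                    "direction_consistent": self.direction_consistent,
                    "headline": self.headline,
                }
            ]
        )


def run_uvmr(
    panel: HarmonizedPanel,
    exposure: str,
    outcome: str,
    snp_ids: Sequence[str] | None = None,
    options: UVMROptions | None = None,
) -> UVMRReport:
    """Run the full univariable MR battery for one exposure/outcome pair."""
    options = options or UVMROptions()
    bx, _, by, sy, ids = panel_arrays(panel, exposure, outcome, snp_ids)
    keep = bx != 0
    bx, by, sy = bx[keep], by[keep], sy[keep]
    ids = [i for i, k in zip(ids, keep) if k]

    est_fixed = ivw(bx, by, sy, "fixed")
    est_random = ivw(bx, by, sy, "random")
    est_egger, pleio = egger(bx, by, sy)
    ratios = wald_ratios(bx, by, sy, ids)
    r = np.array([x.ratio for x in ratios])
    s = np.array([x.ratio_se for x in ratios])
    seeds = np.random.SeedSequence(options.seed).spawn(3)
    est_med = weighted_median(r, s, options.n_boot, seeds[0])
    est_wmode = weighted_mode(r, s, options.bandwidth_factor, options.n_boot, seeds[1])
    est_smode = simple_mode(r, s, options.bandwidth_factor, options.n_boot, seeds[2])

    het = cochran_q(bx, by, sy, "ivw")
    het_egger = cochran_q(bx, by, sy, "egger")
    headline = "ivw_random" if het.pval < 0.05 else "ivw_fixed"

    estimates = {
        "ivw_fixed": est_fixed,
        "ivw_random": est_random,
        "egger": est_egger,
        "weighted_median": est_med,
        "weighted_mode": est_wmode,
        "simple_mode": est_smode,
    }
    if panel.trait_types.get(outcome) == "binary":
        estimates = {k: v.exponentiate() for k, v in estimates.items()}
    ivw_sign = np.sign(estimates["ivw_random"].beta)
    direction = all(
        np.sign(estimates[k].beta) == ivw_sign
        for k in ("ivw_random", "egger", "weighted_median", "weighted_mode", "simple_mode")
    )
    return UVMRReport(
        exposure=exposure,
        outcome=outcome,
        estimates=estimates,
        heterogeneity=het,
        heterogeneity_egger=het_egger,
        pleiotropy=pleio,
        direction_consistent=bool(direction),
        headline=headline,
        snp_ids=ids,
    )
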