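"""Two-step MR mediation: product-method decomposition with uncertainty.

The total effect c of the exposure on the outcome (univariable MR) is split
into an indirect path through the mediator and a direct remainder:

    a        exposure -> mediator        (univariable MR)
    b        mediator -> outcome, adjusted for the exposure (MVMR)
    indirect = a * b
    direct   = c - a * b
    proportion mediated = (a * b) / c

Delta-method variances treat a, b and c as independent (two-sample setting;
the shared outcome sample behind b and c is ignored — see the bootstrap
alternative):

    var(indirect)   = b^2 var(a) + a^2 var(b)
    var(proportion) = (b/c)^2 var(a) + (a/c)^2 var(b) + (ab/c^2)^2 var(c)

A parametric-bootstrap CI for the proportion (independent normal draws of
a, b, c) is always available and is reported alongside the delta CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .instruments import InstrumentCriteria, InstrumentSet, select_instruments
from .summary_io import HarmonizedPanel, SummaryTable, harmonize
from .mvmr import MVMRResult, mvmr_ivw
from .uvmr import Z95, MREstimate, UVMROptions, ivw, panel_arrays, run_uvmr

__all__ = [
    "Estimate",
    "MediationResult",
    "MediationStudy",
    "PipelineOptions",
    "decompose",
    "proportion_ci_bootstrap",
    "mediate_pipeline",
]


class Estimate(NamedTuple):
    """A point estimate with its standard error (log scale for binary traits)."""

    beta: float
    se: float


def _ci(beta: float, se: float) -> tuple[float, float]:
    return beta - Z95 * se, beta + Z95 * se


@dataclass
class MediationResult:
    """Product-method decomposition of a total effect.

    The identities ``indirect + direct == c`` and
    ``proportion == indirect / c`` hold exactly by construction.
    """

    c: Estimate
    a: Estimate
    b: Estimate
    indirect: Estimate
    direct: Estimate
    proportion: float
    proportion_se: float
    proportion_ci: tuple[float, float]
    ci_method: str = "delta"
    bootstrap_ci: tuple[float, float] | None = None
    warnings_: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Rows {total, a, b, indirect, direct, proportion} x {estimate, se, CI}."""
        rows = []
        for name, est in (
            ("total", self.c),
            ("a", self.a),
            ("b", self.b),
            ("indirect", self.indirect),
            ("direct", self.direct),
        ):
            lo, hi = _ci(est.beta, est.se)
            rows.append({"quantity": name, "estimate": est.beta, "se": est.se, "ci_low": lo, "ci_high": hi})
        lo, hi = self.proportion_ci
        rows.append(
            {
                "quantity": "proportion",
                "estimate": self.proportion,
                "se": self.proportion_se,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
        return pd.DataFrame(rows)

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion


def decompose(c_est: Estimate, a_est: Estimate, b_est: Estimate) -> MediationResult:
    """Product-method mediation decomposition with delta-method CIs."""
    c, a, b = c_est.beta, a_est.beta, b_est.beta
    if c == 0:
        raise ValueError("undefined proportion: total effect c is zero")
    va, vb, vc = a_est.se**2, b_est.se**2, c_est.se**2
    indirect = a * b
    direct = c - indirect
    proportion = indirect / c
    var_indirect = b**2 * va + a**2 * vb
    var_direct = vc + var_indirect  # independence of (c, ab)
    var_prop = (b / c) ** 2 * va + (a / c) ** 2 * vb + (indirect / c**2) ** 2 * vc
    se_prop = float(np.sqrt(var_prop))
    notes = []
    if not 0.0 <= proportion <= 1.0:
        notes.append(
            f"proportion mediated {proportion:.4g} lies outside [0, 1] (inconsistent mediation)"
        )
        warnings.warn(notes[-1], stacklevel=2)
    return MediationResult(
        c=c_est,
        a=a_est,
        b=b_est,
        indirect=Estimate(indirect, float(np.sqrt(var_indirect))),
        direct=Estimate(direct, float(np.sqrt(var_direct))),
        proportion=float(proportion),
        proportion_se=se_prop,
        proportion_ci=(proportion - Z95 * se_prop, proportion + Z95 * se_prop),
        ci_method="delta",
        warnings_=notes,
    )


def proportion_ci_bootstrap(
    a_est: Estimate,
    b_est: Estimate,
    c_est: Estimate,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap 95% CI for the proportion mediated.

    Draws a, b, c independently from Normal(estimate, se) and takes the
    2.5th/97.5th percentiles of (a*b)/c.  Draws where c crosses zero make
    the ratio unstable; if more than 1% do, a warning is raised (the CI is
    still returned).
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    rng = np.random.default_rng(seed)
    a = a_est.beta + a_est.se * rng.standard_normal(n_draws)
    b = b_est.beta + b_est.se * rng.standard_normal(n_draws)
    c = c_est.beta + c_est.se * rng.standard_normal(n_draws)
    crossed = int(np.sum(np.sign(c) != np.sign(c_est.beta)))
    if crossed > 0.01 * n_draws:
        warnings.warn(
            f"unstable proportion: {crossed}/{n_draws} bootstrap draws of c cross zero",
            stacklevel=2,
        )
    prop = a * b / c
    lo, hi = np.percentile(prop, [2.5, 97.5])
    return float(lo), float(hi)


class PipelineOptions(UVMROptions):
    """Options for the three-stage mediation pipeline.

    ``effects_model`` selects the IVW variant used for the stage estimates
    (the random-effects model is the default, never undercutting the
    fixed-effects SE).  ``gate_alpha`` is the significance level of the
    mediator->outcome screen; ``full_reports`` additionally runs the five
    sensitivity estimators at each univariable stage.
    """

    def __init__(
        self,
        effects_model: str = "random",
        n_boot: int = 1000,
        bandwidth_factor: float = 1.0,
        ci_method: str = "delta",
        n_draws: int = 10_000,
        gate_alpha: float = 0.05,
        full_reports: bool = False,
        seed: int = 0,
    ):
        super().__init__(effects_model, n_boot, bandwidth_factor, seed)
        if ci_method not in ("delta", "bootstrap"):
            raise ValueError("ci_method must be delta|bootstrap")
        self.ci_method = ci_method
        self.n_draws = int(n_draws)
        self.gate_alpha = float(gate_alpha)
        self.full_reports = bool(full_reports)


@dataclass
class MediationStudy:
    """Everything the three-stage pipeline produced."""

    mediation: MediationResult
    c_estimate: MREstimate
    a_estimate: MREstimate
    b_estimate: MREstimate
    mvmr: MVMRResult
    gate_pval: float
    mediator_excluded: bool
    exposure_instruments: InstrumentSet
    mediator_instruments: InstrumentSet
    n_snps_stage: dict[str, int]
    reports: dict = field(default_factory=dict)


def _stage_ivw(
    panel: HarmonizedPanel,
    exposure: str,
    outcome: str,
    snp_ids: Sequence[str],
    effects_model: str,
) -> MREstimate:
    bx, _, by, sy, _ = panel_arrays(panel, exposure, outcome, snp_ids)
    keep = bx != 0
    return ivw(bx[keep], by[keep], sy[keep], effects_model)


def mediate_pipeline(
    exposure: SummaryTable,
    mediator: SummaryTable,
    outcome: SummaryTable,
    criteria: InstrumentCriteria | None = None,
    options: PipelineOptions | None = None,
    ld=None,
) -> MediationStudy:
    """Run the full two-step MR mediation study.

    Stage 1: c = UVMR(exposure -> outcome) on the exposure's instruments.
    Stage 2: a = UVMR(exposure -> mediator) on the same instruments.
    Gate:    UVMR(mediator -> outcome) on the mediator's own instruments;
             a non-significant mediator (p > gate_alpha) is flagged as
             excluded from MVMR-based mediation (the decomposition is still
             computed so the flag can be inspected alongside the numbers).
    Stage 3: b = the mediator's direct effect from MVMR of the outcome on
             exposure + mediator over the union of both instrument sets.
    Finally the product-method decomposition with delta and bootstrap CIs.
    """
    criteria = criteria or InstrumentCriteria()
    options = options or PipelineOptions()

    inst_x = select_instruments(exposure, criteria, ld)
    inst_m = select_instruments(mediator, criteria, ld)

    panel_xy = harmonize([exposure, outcome])
    panel_xm = harmonize([exposure, mediator])
    panel_my = harmonize([mediator, outcome])
    panel_all = harmonize([exposure, mediator, outcome])

    xname, mname, yname = exposure.trait_name, mediator.trait_name, outcome.trait_name
    ids_c = [s for s in panel_xy.snp_ids if s in set(inst_x.snp_ids)]
    ids_a = [s for s in panel_xm.snp_ids if s in set(inst_x.snp_ids)]
    ids_gate = [s for s in panel_my.snp_ids if s in set(inst_m.snp_ids)]
    union = set(inst_x.snp_ids) | set(inst_m.snp_ids)
    ids_b = [s for s in panel_all.snp_ids if s in union]

    c_est = _stage_ivw(panel_xy, xname, yname, ids_c, options.effects_model)
    a_est = _stage_ivw(panel_xm, xname, mname, ids_a, options.effects_model)
    gate_est = _stage_ivw(panel_my, mname, yname, ids_gate, options.effects_model)
    mediator_excluded = gate_est.pval > options.gate_alpha

    mv = mvmr_ivw(panel_all, yname, exposures=[xname, mname], snp_ids=ids_b)
    b_est = mv[mname]

    result = decompose(
        Estimate(c_est.beta, c_est.se),
        Estimate(a_est.beta, a_est.se),
        Estimate(b_est.beta, b_est.se),
    )
    seeds = np.random.SeedSequence(options.seed).spawn(4)
    result.bootstrap_ci = proportion_ci_bootstrap(
        result.a, result.b, result.c, options.n_draws, seeds[0]
    )
    if options.ci_method == "bootstrap":
        result.ci_method = "bootstrap"
        result.proportion_ci = result.bootstrap_ci
    if mediator_excluded:
        result.warnings_.append(
            f"mediator {mname!r} excluded from subsequent MVMR analysis "
            f"(UVMR p = {gate_est.pval:.3g} > {options.gate_alpha:g})"
        )

    reports = {}
    if options.full_reports:
        uv_opts = UVMROptions(
            options.effects_model, options.n_boot, options.bandwidth_factor, int(seeds[1].generate_state(1)[0] % 2**31)
        )
        reports["c"] = run_uvmr(panel_xy, xname, yname, ids_c, uv_opts)
        uv_opts_a = UVMROptions(
            options.effects_model, options.n_boot, options.bandwidth_factor, int(seeds[2].generate_state(1)[0] % 2**31)
        )
        reports["a"] = run_uvmr(panel_xm, xname, mname, ids_a, uv_opts_a)

    return MediationStudy(
        mediation=result,
        c_estimate=c_est,
        a_estimate=a_est,
        b_estimate=b_est,
        mvmr=mv,
        gate_pval=gate_est.pval,
        mediator_excluded=bool(mediator_excluded),
        exposure_instruments=inst_x,
        mediator_instruments=inst_m,
        n_snps_stage={"c": len(ids_c), "a": len(ids_a), "gate": len(ids_gate), "b": len(ids_b)},
        reports=reports,
    )
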