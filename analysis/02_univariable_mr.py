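#!/usr/bin/env python
"""Univariable MR of the simulated study: total and exposure->mediator effects.

Selects genome-wide-significant instruments for the exposure, harmonizes
them against the outcome and the mediator, and runs the five-estimator
battery twice:

  c  exposure -> outcome   (the total effect; odds-ratio scale reported)
  a  exposure -> mediator

Writes per-method estimate tables and a heterogeneity/pleiotropy
diagnostics table (Cochran's Q, Egger intercept p, mean R^2 and F) under
results/uvmr/.  Run 01_simulate_study.py first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mrmediate.instruments import select_instruments
from mrmediate.summary_io import harmonize, read_summary
from mrmediate.uvmr import UVMROptions, run_uvmr

IN = Path("results/study")
OUT = Path("results/uvmr")


def main() -> None:
    exposure = read_summary(IN / "exposure.tsv", trait_name="exposure")
    mediator = read_summary(IN / "mediator.tsv", trait_name="mediator")
    outcome = read_summary(IN / "outcome.tsv", trait_name="outcome", trait_type="binary")

    inst = select_instruments(exposure)
    print(f"instruments for exposure: {inst.n_snps} SNPs, "
          f"mean R^2 = {np.nanmean(inst.r2):.3g}, mean F = {inst.mean_f:.1f}"
          + ("  [weak-instrument flag]" if inst.weak else ""))

    OUT.mkdir(parents=True, exist_ok=True)
    diags = []
    for target, label in ((outcome, "c (total effect)"), (mediator, "a (exposure->mediator)")):
        panel = harmonize([exposure, target])
        ids = [s for s in panel.snp_ids if s in set(inst.snp_ids)]
        report = run_uvmr(panel, "exposure", target.trait_name, ids, UVMROptions(seed=11))
        est = report.headline_estimate
        scale = (f"OR {est.odds_ratio:.3f} ({est.or_ci_low:.3f}-{est.or_ci_high:.3f})"
                 if est.odds_ratio else f"beta {est.beta:.4f} +/- {est.se:.4f}")
        print(f"{label}: {scale} via {report.headline} over {est.n_snps} SNPs; "
              f"direction-consistent across methods: {report.direction_consistent}")
        report.to_frame().to_csv(OUT / f"uvmr_{target.trait_name}.tsv", sep="\t",
                                 index=False, na_rep="NA", float_format="%.6g")
        diags.append(report.diagnostics_frame())
    pd.concat(diags, ignore_index=True).to_csv(
        OUT / "diagnostics.tsv", sep="\t", index=False, float_format="%.6g"
    )
    print(f"wrote {OUT}/uvmr_outcome.tsv, uvmr_mediator.tsv, diagnostics.tsv")


if __name__ == "__main__":
    main()
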