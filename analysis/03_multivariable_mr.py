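#!/usr/bin/env python
"""Multivariable MR: the mediator's direct effect adjusted for the exposure.

Takes the union of the exposure's and the mediator's genome-wide-significant
instruments, harmonizes all three traits, and jointly regresses outcome
betas on both exposures' betas.  The mediator's coefficient is b — its
effect on the outcome holding the exposure fixed — which the mediation
decomposition multiplies with a.  Writes results/mvmr/mvmr.tsv.
Run 01_simulate_study.py first.
"""

from pathlib import Path

from mrmediate.instruments import select_instruments
from mrmediate.mvmr import mvmr_ivw
from mrmediate.summary_io import harmonize, read_summary

IN = Path("results/study")
OUT = Path("results/mvmr")


def main() -> None:
    exposure = read_summary(IN / "exposure.tsv", trait_name="exposure")
    mediator = read_summary(IN / "mediator.tsv", trait_name="mediator")
    outcome = read_summary(IN / "outcome.tsv", trait_name="outcome", trait_type="binary")

    union = set(select_instruments(exposure).snp_ids) | set(select_instruments(mediator).snp_ids)
    panel = harmonize([exposure, mediator, outcome])
    ids = [s for s in panel.snp_ids if s in union]
    result = mvmr_ivw(panel, "outcome", exposures=["exposure", "mediator"], snp_ids=ids)

    for name in result.exposures:
        e = result[name]
        print(f"direct effect of {name}: beta {e.beta:.4f} "
              f"(OR {e.odds_ratio:.3f}, 95% CI {e.or_ci_low:.3f}-{e.or_ci_high:.3f}, "
              f"p {e.pval:.3g})")
    print(f"residual heterogeneity Q = {result.q_stat:.1f} over {result.n_snps} SNPs "
          f"(p = {result.q_pval:.3g})")
    OUT.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(OUT / "mvmr.tsv", sep="\t", index=False,
                             na_rep="NA", float_format="%.6g")
    print(f"wrote {OUT}/mvmr.tsv")


if __name__ == "__main__":
    main()
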