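# Methods

## Model and assumptions

The package works entirely at the summary-statistic level of two-sample
Mendelian randomization.  For SNP j and trait T we observe an estimated
per-allele effect β̂_T,j with standard error se_T,j.  A SNP is a valid
instrument for the exposure X if it is associated with X, affects the
outcome Y only through X (no horizontal pleiotropy), and is independent of
confounders.  Under these assumptions each Wald ratio β̂_Y,j / β̂_X,j
estimates the same causal effect, and the estimators below are different
ways of combining them that trade efficiency against robustness to
pleiotropy.

The mediation model is a linear path diagram X → M → Y with a direct
X → Y path: total effect c, exposure→mediator effect a, mediator→outcome
effect b conditional on X.  Then indirect = a·b, direct = c − a·b and the
proportion mediated is a·b/c.  For a binary outcome all effects are on the
log-odds scale; because logistic models are non-collapsible this
decomposition is an approximation that is standard practice in two-step MR,
exact in the linear model the synthetic data implements.

## Estimators

* **Wald ratio**: r_j = β̂_Y,j / β̂_X,j with first-order SE
  se_Y,j / |β̂_X,j|.  The second-order term involving the exposure SE is
  deliberately omitted (see Limitations).
* **IVW**: weighted mean of ratios with weights w_j = β̂²_X,j / se²_Y,j,
  equivalently zero-intercept WLS of β̂_Y on β̂_X.  Fixed-effects SE
  (Σw)^(−1/2); the multiplicative random-effects SE multiplies it by
  max(1, √(Q/(J−1))) — floored so it never undercuts the fixed-effects SE.
  P-values are two-sided normal.
* **MR-Egger**: the same regression with a free intercept after orienting
  all SNPs to β̂_X ≥ 0.  The intercept estimates average directional
  pleiotropy; SEs scale the WLS covariance by max(1, residual mean square);
  p-values use t with J−2 df (honest at small J).
* **Weighted median**: ratios ordered, normalized inverse-variance weights
  accumulated, linear interpolation to cumulative weight 0.5.  Consistent
  when valid instruments carry > 50% of the weight.
* **Weighted/simple mode**: argmax of a Gaussian-kernel density of the
  ratios (weights inverse-variance or uniform) with bandwidth
  0.9·min(sd, IQR/1.349)·J^(−1/5) times a user factor; evaluated on a
  512-point grid spanning the ratio range ± 3 bandwidths, first grid argmax
  on ties.  If all ratios coincide the common value is returned.
* Median and mode SEs come from a parametric bootstrap (default 1,000
  resamples of r_j ~ N(r_j, se_j), seeded).
* **Cochran's Q**: weighted squared deviations of ratios from the
  fixed-effects fit; df J−1 (IVW) or J−2 (Egger); I² = max(0, (Q−df)/Q).
* **MVMR**: zero-intercept WLS of β̂_Y on the exposure-beta matrix, weights
  1/se²_Y, over the union of the exposures' instruments re-harmonized
  across all traits; SE floor as in IVW; residual Q on J−k df.  Rank
  deficiency of the beta matrix and J ≤ k are errors.
* **Reporting rule**: the univariable report always contains both IVW
  variants and labels the random-effects one headline when Q's p < 0.05;
  the pipeline's stage estimates default to the random-effects model
  throughout.  Cross-method direction consistency means all five estimators
  share the IVW sign.

## Mediation uncertainty

Delta-method variances treat a, b, c as independent (they come from
different regressions, though b and c share the outcome GWAS — see
Limitations):

    var(a·b)  = b²·var(a) + a²·var(b)
    var(a·b/c) = (b/c)²·var(a) + (a/c)²·var(b) + (ab/c²)²·var(c)

A parametric bootstrap (independent normal draws of a, b, c; percentile
interval of a·b/c; default 10,000 draws) is always computed alongside.
Draws in which c crosses zero are counted and trigger an "unstable
proportion" warning above 1%.  Proportions outside [0, 1] (inconsistent
mediation) are reported with a warning, never clipped.

## Harmonization rules

Tables are matched by variant ID only, processed in sorted ID order, with
the first table fixing the reference effect allele.  Swapped alleles negate
the beta and flip the frequency; strand complements are relabelled first.
Palindromic SNPs (A/T, G/C) are dropped as ambiguous whenever any table's
effect-allele frequency is missing or falls in [0.42, 0.58] (a configurable
window; a common MR-ecosystem convention), and are otherwise oriented by
requiring frequencies to agree on their side of 0.5.  Anything
irreconcilable is dropped with a reason; kept + dropped always equals the
ID intersection.  Missing frequency is otherwise tolerated — it is needed
only for palindrome resolution and R².

## Instrument selection

The p-value cut is strict (<), the MAF filter uses min(eaf, 1−eaf), and
clumping greedily keeps the smallest-p SNP (ties by variant ID) while
removing window-mates; with pairwise LD supplied, only window-mates with
r² ≥ 0.01 are removed, and absent pairs are treated as unlinked.  Without
an LD reference the window rule alone applies (conservative position
thinning) — shipping an LD panel is out of scope.  SNPs lacking frequency
are retained as instruments but excluded from R²/F with a warning.  F ≤ 10
sets a flag; nothing is auto-dropped.  The per-exposure F is summarized as
the arithmetic mean of per-SNP F values, and the package makes no claim
that externally reported per-exposure F values were constructed the same
way.

## Synthetic data: what it emulates and what it does not

Each study draws MAFs uniformly, exposure instrument effects
γ_j ~ N(0, 0.2²) for 50 of 100 SNPs, mediator-specific effects
δ_j ~ N(0, 0.2²) for a further 30, and builds true mediator/outcome effects
through the path model (a = 0.26, b = 0.30, direct = 1.0 by default, so
c = 1.078 and true proportion ≈ 7.24%, the regime of the motivating
application).  Observed betas add noise with se = 1/√(2·maf·(1−maf)·N),
with N = 1,000,000 / 800,000 / 180,000 for exposure/mediator/outcome —
the sample-size scale of the insomnia/BMI/low-back-pain GWAS the design
mirrors.  P-values are two-sided normal, clamped at the smallest positive
double so extreme associations never underflow the (0,1] invariant.
Positions are spaced beyond the clump window, so SNPs are independent by
construction; a configurable fraction of tables' rows has swapped allele
labels (exercising harmonization) and optionally palindromic allele pairs.

Design choices worth making explicit:

* **Mediator-specific instruments.**  Without SNPs that affect the mediator
  independently of the exposure, the exposure and mediator beta columns are
  proportional and the MVMR coefficient b is unidentified.  Real candidate
  mediators (e.g. BMI) have their own GWAS hits; the generator therefore
  plants a disjoint block of mediator instruments, and the MVMR stage uses
  the union of both significant sets.
* **Strong instruments.**  Defaults put per-SNP F in the thousands.  This
  keeps the first-order Wald SE accurate, so recovery and coverage
  experiments measure the estimators rather than the weak-instrument
  approximation error.  Weak-instrument behaviour can be explored by
  lowering `exposure_effect_sd` or sample sizes.
* **Scenarios.**  `valid` (reference conditions), `balanced_pleiotropy`
  (pleiotropy sd 0.002, mean 0 — InSIDE holds), `directional_pleiotropy`
  (mean 0.002), `null_effect` (all paths zero), `null_mediator` (a = b = 0:
  a candidate mediator with no causal role, which the gate rule must flag;
  with a ≠ 0 and b = 0 the mediator's own significant SNPs would include
  exposure-shared ones, making its univariable effect on the outcome
  non-null and the gate untriggerable).
* **Calibration conditions.**  With a nonzero causal slope the Wald-ratio
  variance is (se²_Y + c²·se²_X)/γ², so Q is inflated above J−1 by a
  constant multiplicative factor no sample size removes; Q calibration is
  therefore measured under `null_effect` (exactly homogeneous ratios), and
  CI coverage with the random-effects IVW, whose multiplicative
  overdispersion model matches that constant inflation exactly (the SE
  ratio per SNP is constant because all traits share each SNP's MAF).

What the generator does **not** emulate: linkage disequilibrium between
SNPs (LD scenarios require injecting pairwise r²), sample overlap between
GWAS (a, b, c are generated from independent noise; real b and c share the
outcome cohort), binary-trait likelihoods (all traits are simulated as
quantitative; the binary outcome is a labelling that switches on odds-ratio
reporting), allele-frequency estimation error, and population
stratification.  Passing tests therefore certify the estimators and
pipeline logic under these idealized conditions, not robustness to
LD-induced or overlap-induced bias.

## Numerical choices

Replicate experiments run 1,000 studies (recovery/coverage) and 2,000
(test calibration) of 100 SNPs each, with Monte-Carlo standard errors
reported alongside every mean.  All randomness flows from one integer seed
through `numpy` SeedSequence spawning; derived seeds stay below 2³¹.
Bootstrap defaults: 1,000 resamples (estimator SEs), 10,000 draws
(proportion CI).  Output tables print 6 significant digits; computation is
double precision throughout.  Degenerate inputs are defined errors, not
silent results: fewer than 2 (IVW) / 3 (Egger, median, modes) instruments,
k ≥ J or collinear exposures in MVMR, c = 0 in the decomposition, zero
exposure betas in Wald ratios (excluded with a warning).

## Limitations

* First-order Wald SEs ignore exposure-side noise; with weak instruments
  both the SEs and the estimates (regression dilution) degrade.
* The delta method assumes a, b, c independent; the shared outcome sample
  behind b and c induces correlation the bootstrap alternative also
  ignores.
* No MR-PRESSO/Steiger/leave-one-out sensitivity machinery, no conditional
  F statistics, and no real-LD clumping — user-supplied pairwise r² is the
  only LD input.
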