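"""Univariable MR estimators, heterogeneity and pleiotropy diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate.summary_io import harmonize
from mrmediate.instruments import select_instruments
from mrmediate.uvmr import (
    UVMROptions,
    cochran_q,
    egger,
    ivw,
    run_uvmr,
    simple_mode,
    wald_ratios,
    weighted_median,
    weighted_mode,
)


def _random_panel(rng, j=8):
    bx = rng.normal(0.1, 0.05, j)
    bx[np.abs(bx) < 0.01] = 0.05
    by = rng.normal(0.05, 0.03, j)
    sy = rng.uniform(0.01, 0.05, j)
    return bx, by, sy


def _wls_oracle(x, y, w, intercept):
    """Closed-form weighted least squares via the normal equations."""
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    scale = float(resid @ (w * resid) / dof)
    cov = np.linalg.inv(xtwx) * scale
    return coef, np.sqrt(np.diag(cov)), scale


class TestWaldRatios:
    @pytest.mark.parametrize("bx,expected", [(0.1, 2.0), (-0.1, -2.0)])
    def test_ratio_and_first_order_se(self, bx, expected):
        [r] = wald_ratios([bx], [0.2], [0.05])
        assert r.ratio == pytest.approx(expected)
        assert r.ratio_se == pytest.approx(0.5)

    def test_zero_exposure_beta_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero exposure beta"):
            out = wald_ratios([0.0, 0.1], [0.2, 0.2], [0.05, 0.05])
        assert len(out) == 1

    def test_mean_ratio_recovers_truth(self, rng):
        true = 0.3
        j, reps = 20, 200
        means = []
        for _ in range(reps):
            bx = rng.normal(0.2, 0.05, j)
            by = true * bx + 0.01 * rng.standard_normal(j)
            ratios = wald_ratios(bx, by, np.full(j, 0.01))
            means.append(np.mean([r.ratio for r in ratios]))
        mcse = np.std(means, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(means) - true) < 3 * mcse


class TestIVW:
    def test_equal_ratios_give_zero_heterogeneity(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 1.7 * bx
        sy = np.array([0.01, 0.02, 0.03])
        fixed = ivw(bx, by, sy, "fixed")
        random = ivw(bx, by, sy, "random")
        assert fixed.beta == pytest.approx(1.7)
        assert random.beta == pytest.approx(1.7)
        assert random.se == pytest.approx(fixed.se)  # floor at the fixed-effects se
        assert cochran_q(bx, by, sy).q_stat == pytest.approx(0.0)

    def test_matches_wls_oracle_to_ten_digits(self, rng):
        for _ in range(20):
            bx, by, sy = _random_panel(rng)
            est = ivw(bx, by, sy, "fixed")
            coef, _, _ = _wls_oracle(bx, by, 1 / sy**2, intercept=False)
            assert est.beta == pytest.approx(float(coef[0]), rel=1e-10)
            assert est.se == pytest.approx(float(np.sum(bx**2 / sy**2) ** -0.5), rel=1e-10)

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError, match=">= 2"):
            ivw([0.1], [0.2], [0.05])

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(10):
            bx, by, sy = _random_panel(rng)
            assert ivw(bx, by, sy, "random").se >= ivw(bx, by, sy, "fixed").se

    def test_interval_coverage_with_valid_instruments(self, rng):
        true, j, reps = 0.5, 50, 1500
        covered = 0
        for _ in range(reps):
            bx = rng.normal(0.2, 0.05, j)
            sy = np.full(j, 0.02)
            by = true * bx + sy * rng.standard_normal(j)
            est = ivw(bx, by, sy, "random")
            covered += est.ci_low <= true <= est.ci_high
        assert 0.93 <= covered / reps <= 0.97


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        by = 0.1 + 0.4 * bx
        est, pleio = egger(bx, by, np.full(4, 0.02))
        assert pleio.intercept == pytest.approx(0.1, abs=1e-12)
        assert est.beta == pytest.approx(0.4, abs=1e-12)

    def test_zero_intercept_constraint_equals_fixed_ivw(self, rng):
        # constrained WLS (no intercept) is exactly the IVW estimator
        for _ in range(10):
            bx, by, sy = _random_panel(rng)
            bx = np.abs(bx)  # already oriented
            coef, _, _ = _wls_oracle(bx, by, 1 / sy**2, intercept=False)
            assert ivw(bx, by, sy, "fixed").beta == pytest.approx(float(coef[0]), rel=1e-10)

    def test_matches_wls_oracle_with_intercept(self, rng):
        for _ in range(20):
            bx, by, sy = _random_panel(rng)
            flip = np.where(bx < 0, -1.0, 1.0)
            est, pleio = egger(bx, by, sy)
            coef, se, scale = _wls_oracle(bx * flip, by * flip, 1 / sy**2, intercept=True)
            infl = np.sqrt(max(1.0, scale) / scale)
            assert est.beta == pytest.approx(float(coef[1]), rel=1e-10)
            assert est.se == pytest.approx(float(se[1]) * infl, rel=1e-10)
            assert pleio.intercept == pytest.approx(float(coef[0]), rel=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match=">= 3"):
            egger([0.1, 0.2], [0.1, 0.2], [0.01, 0.01])


class TestMedianAndModes:
    def test_equal_weights_reduce_to_simple_median(self):
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        est = weighted_median(r, np.ones(5), n_boot=50, seed=0)
        assert est.beta == pytest.approx(3.0)

    def test_matches_interpolation_oracle(self):
        r = np.array([0.1, 0.5, 1.0, 2.0])
        s = np.array([0.1, 0.2, 0.05, 0.4])
        w = 1 / s**2
        # brute-force cumulative-weight interpolation
        order = np.argsort(r)
        rw = w[order] / w.sum()
        cum = np.cumsum(rw) - rw / 2
        k = np.searchsorted(cum, 0.5)
        frac = (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
        expected = r[order][k - 1] + frac * (r[order][k] - r[order][k - 1])
        est = weighted_median(r, s, n_boot=50, seed=0)
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_median_robust_to_minority_invalid_instruments(self, rng):
        # 40% of instruments carry directional pleiotropy; the weighted
        # median stays near the truth (it sits inside the valid majority of
        # the weight) while IVW absorbs ~40% of the pleiotropic shift.
        true, j, reps = 0.3, 25, 120
        med, ivw_est = [], []
        for _ in range(reps):
            bx = rng.normal(0.2, 0.03, j)
            sy = np.full(j, 0.004)
            pleio = np.zeros(j)
            pleio[: j * 2 // 5] = 0.05  # ratio-scale shift ~ 0.25
            by = true * bx + pleio + sy * rng.standard_normal(j)
            r = by / bx
            med.append(weighted_median(r, sy / np.abs(bx), n_boot=10, seed=0).beta)
            ivw_est.append(ivw(bx, by, sy, "fixed").beta)
        assert abs(np.mean(med) - true) < 0.03
        assert np.mean(ivw_est) - true > 0.05  # IVW dragged by the invalid 40%

    def test_identical_ratios_give_common_value(self):
        est = weighted_mode(np.full(5, 1.3), np.full(5, 0.1), n_boot=20, seed=0)
        assert est.beta == pytest.approx(1.3)

    def test_mode_finds_majority_cluster(self, rng):
        r = np.concatenate([rng.normal(0.3, 0.005, 7), rng.normal(1.0, 0.005, 3)])
        s = np.full(10, 0.05)
        est = weighted_mode(r, s, n_boot=20, seed=0)
        assert 0.25 < est.beta < 0.35

    def test_weighted_equals_simple_on_equal_weights(self, rng):
        r = rng.normal(0.5, 0.2, 9)
        s = np.full(9, 0.1)
        w = weighted_mode(r, s, n_boot=10, seed=3)
        sm_ = simple_mode(r, s, n_boot=10, seed=3)
        assert w.beta == pytest.approx(sm_.beta)

    def test_bootstrap_se_deterministic_under_seed(self):
        r = np.array([0.1, 0.4, 0.2, 0.9])
        s = np.array([0.1, 0.2, 0.1, 0.3])
        a = weighted_median(r, s, n_boot=200, seed=7)
        b = weighted_median(r, s, n_boot=200, seed=7)
        assert a.se == b.se

    def test_minimum_instruments(self):
        with pytest.raises(ValueError, match=">= 3"):
            weighted_median([1.0, 2.0], [0.1, 0.1])


class TestCochranQ:
    def test_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        het = cochran_q(bx, 2.0 * bx, np.array([0.01, 0.02, 0.01]))
        assert het.q_stat == pytest.approx(0.0)
        assert het.pval == pytest.approx(1.0)
        assert het.df == 2

    def test_permutation_invariance(self, rng):
        bx, by, sy = _random_panel(rng)
        perm = rng.permutation(len(bx))
        a = cochran_q(bx, by, sy)
        b = cochran_q(bx[perm], by[perm], sy[perm])
        assert a.q_stat == pytest.approx(b.q_stat, rel=1e-12)

    def test_mean_q_matches_chi_square_null(self, rng):
        # homogeneous ratios: E[Q] = J - 1
        j, reps = 30, 400
        qs = []
        for _ in range(reps):
            bx = rng.normal(0.2, 0.05, j)
            sy = np.full(j, 0.02)
            by = 0.5 * bx + sy * rng.standard_normal(j)
            qs.append(cochran_q(bx, by, sy).q_stat)
        mcse = np.std(qs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(qs) - (j - 1)) < 3 * mcse

    def test_egger_variant_uses_two_fewer_df(self, rng):
        bx, by, sy = _random_panel(rng)
        assert cochran_q(bx, by, sy, "egger").df == len(bx) - 2


class TestEstimatorInvariances:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_negating_outcome_negates_estimates(self, seed):
        rng = np.random.default_rng(seed)
        bx, by, sy = _random_panel(rng)
        for model in ("fixed", "random"):
            a, b = ivw(bx, by, sy, model), ivw(bx, -by, sy, model)
            assert b.beta == pytest.approx(-a.beta, rel=1e-12)
            assert b.se == pytest.approx(a.se, rel=1e-12)
        ea, pa = egger(bx, by, sy)
        eb, pb = egger(bx, -by, sy)
        assert eb.beta == pytest.approx(-ea.beta, rel=1e-12)
        assert pb.pval == pytest.approx(pa.pval, rel=1e-9)
        qa, qb = cochran_q(bx, by, sy), cochran_q(bx, -by, sy)
        assert qa.q_stat == pytest.approx(qb.q_stat, rel=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10**6), st.floats(0.2, 5.0))
    def test_rescaling_exposure_rescales_estimates(self, seed, k):
        rng = np.random.default_rng(seed)
        bx, by, sy = _random_panel(rng)
        a = ivw(bx, by, sy, "fixed")
        b = ivw(k * bx, by, sy, "fixed")
        assert b.beta == pytest.approx(a.beta / k, rel=1e-10)
        ea, _ = egger(bx, by, sy)
        eb, _ = egger(k * bx, by, sy)
        assert eb.beta == pytest.approx(ea.beta / k, rel=1e-10)


@pytest.fixture(scope="module")
def report(valid_study):
    inst = select_instruments(valid_study.exposure)
    panel = harmonize([valid_study.exposure, valid_study.outcome])
    ids = [s for s in panel.snp_ids if s in set(inst.snp_ids)]
    return run_uvmr(panel, "exposure", "outcome", ids, UVMROptions(seed=11, n_boot=200))


class TestRunUVMR:
    def test_strong_positive_effect_is_direction_consistent(self, report):
        assert report.direction_consistent
        assert report.estimates["ivw_random"].beta > 0

    def test_binary_outcome_gets_odds_ratios(self, report):
        est = report.estimates["ivw_random"]
        assert est.odds_ratio == pytest.approx(np.exp(est.beta))
        assert est.or_ci_low == pytest.approx(np.exp(est.ci_low))

    def test_headline_follows_heterogeneity_gate(self, report):
        expected = "ivw_random" if report.heterogeneity.pval < 0.05 else "ivw_fixed"
        assert report.headline == expected

    def test_report_serializes_per_method_rows(self, report):
        frame = report.to_frame()
        assert len(frame) == 6
        assert set(frame.method) >= {"ivw_random", "egger", "weighted_median"}

    def test_single_snp_panel_propagates_precondition(self, valid_study):
        panel = harmonize([valid_study.exposure, valid_study.outcome])
        with pytest.raises(ValueError, match=">= 2"):
            run_uvmr(panel, "exposure", "outcome", panel.snp_ids[:1], UVMROptions(seed=0))

    def test_null_effect_pvalues_are_uniform(self):
        # fixed-effects IVW p under a complete null should be U(0,1)
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(300):
            bx = rng.normal(0.2, 0.05, 40)
            sy = np.full(40, 0.02)
            by = sy * rng.standard_normal(40)
            pvals.append(ivw(bx, by, sy, "fixed").pval)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
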