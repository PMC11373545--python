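"""MR estimator suite against closed-form and library oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from protmr.instruments import HarmonizedSet, InsufficientInstrumentsError
from protmr.mr_core import (
    DegenerateInstrumentError,
    bh_fdr,
    cochran_q,
    estimate_all,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from protmr.synthetic import MRSimConfig, simulate_harmonized


def hset(beta_exp, beta_out, se_out, se_exp=0.01):
    return HarmonizedSet.from_arrays(beta_exp, se_exp, beta_out, se_out)


class TestWaldRatio:
    def test_arithmetic(self):
        h = hset([0.5], [0.055], [0.01])
        est = wald_ratio(h)
        assert est.beta == pytest.approx(0.11)
        assert est.se == pytest.approx(0.02)
        assert est.or_ == pytest.approx(np.exp(0.11))

    def test_zero_outcome_effect(self):
        est = wald_ratio(hset([0.5], [0.0], [0.01]))
        assert est.beta == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(hset([0.0], [0.1], [0.01]))

    def test_second_order_se_close_for_strong_instrument(self):
        # se_exp/|beta_exp| = 0.02 < 0.05: orders differ by < 1%
        h = hset([0.5], [0.055], [0.01], se_exp=0.01)
        first = wald_ratio(h).se
        second = wald_ratio(h, second_order=True).se
        assert abs(second - first) / first < 0.01

    def test_ci_and_or_construction(self):
        est = wald_ratio(hset([0.5], [0.055], [0.01]))
        assert est.ci_low == pytest.approx(est.beta - 1.959964 * est.se, abs=1e-6)
        assert est.or_low == pytest.approx(np.exp(est.ci_low))


class TestIVW:
    def test_equal_weights_average(self):
        h = hset([1.0, 1.0], [0.1, 0.3], [0.05, 0.05])
        assert ivw(h, model="fixed").beta == pytest.approx(0.2)

    def test_single_variant_delegates_to_wald(self):
        h = hset([0.5], [0.055], [0.01])
        assert ivw(h).beta == wald_ratio(h).beta
        assert ivw(h).method == "wald"

    def test_matches_zero_intercept_wls_oracle(self, rng):
        """IVW-FE equals the zero-intercept WLS slope with weights se_out^-2."""
        for _ in range(10):
            j = int(rng.integers(2, 9))
            bx = rng.uniform(0.1, 1.0, j) * rng.choice([-1, 1], j)
            by = rng.normal(0.1 * bx, 0.05)
            so = rng.uniform(0.01, 0.1, j)
            h = hset(bx, by, so)
            mine = ivw(h, model="fixed")
            wls = sm.WLS(by, bx, weights=1 / so**2).fit()
            assert mine.beta == pytest.approx(wls.params[0], rel=1e-10)
            # statsmodels rescales by residual variance; its unscaled
            # (fixed-dispersion) SE is sqrt of the normalized cov
            se_wls = float(np.sqrt(wls.normalized_cov_params[0, 0]))
            assert mine.se == pytest.approx(se_wls, rel=1e-10)

    def test_random_effects_se_never_smaller(self, rng):
        for seed in range(5):
            h, _ = simulate_harmonized(MRSimConfig(n_snp=6, theta=0.1, seed=seed, pleio_sd=0.1, prop_invalid=0.5, pleio_mean=0.0))
            assert ivw(h, model="random").se >= ivw(h, model="fixed").se - 1e-15

    def test_order_and_signflip_invariance(self, rng):
        h, _ = simulate_harmonized(MRSimConfig(n_snp=6, theta=0.2, seed=9))
        base = ivw(h, model="fixed").beta
        perm = rng.permutation(6)
        assert ivw(h.subset(perm), model="fixed").beta == pytest.approx(base)
        flipped = HarmonizedSet.from_arrays(
            -h.beta_exp, h.se_exp, -h.beta_out, h.se_out
        )
        assert ivw(flipped, model="fixed").beta == pytest.approx(base)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        h = hset([1.0, 1.0, 1.0], [0.2, 0.2, 0.2], [0.05, 0.05, 0.05])
        est = ivw(h, model="fixed")
        het = cochran_q(h, est)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.pval == pytest.approx(1.0)
        assert het.i2 == 0.0

    def test_two_ratio_chi_square_arithmetic(self):
        # ratios 0.1, 0.3 with weight 100 each around IVW beta 0.2:
        # Q = 100*(0.01) + 100*(0.01) = 2, df = 1, p = P(chi2_1 > 2) = 0.1573
        h = hset([1.0, 1.0], [0.1, 0.3], [0.1, 0.1])
        est = ivw(h, model="fixed")
        het = cochran_q(h, est)
        assert est.beta == pytest.approx(0.2)
        assert het.q == pytest.approx(2.0)
        assert het.df == 1
        assert het.pval == pytest.approx(0.1573, abs=1e-4)

    def test_i2_clamped_at_zero(self):
        h = hset([1.0, 1.0, 1.0], [0.2, 0.201, 0.199], [0.5, 0.5, 0.5])
        het = cochran_q(h, ivw(h, model="fixed"))
        assert het.q < het.df
        assert het.i2 == 0.0


class TestEgger:
    def test_closed_form_line(self):
        # (x, y) = (1, 0.2), (2, 0.3), (3, 0.4) with equal weights:
        # OLS slope 0.1, intercept 0.1
        h = hset([1.0, 2.0, 3.0], [0.2, 0.3, 0.4], [1.0, 1.0, 1.0])
        est, intercept = mr_egger(h)
        assert est.beta == pytest.approx(0.1)
        assert intercept.value == pytest.approx(0.1)

    def test_matches_statsmodels_wls_oracle(self, rng):
        bx = rng.uniform(0.2, 1.0, 6)
        by = rng.normal(0.15 * bx + 0.03, 0.02)
        so = rng.uniform(0.02, 0.08, 6)
        est, intercept = mr_egger(hset(bx, by, so))
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1 / so**2).fit()
        assert est.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert intercept.value == pytest.approx(fit.params[0], rel=1e-10)

    def test_recovers_constant_pleiotropy(self):
        # every instrument carries the same pleiotropic shift c = 0.05
        h, truth = simulate_harmonized(
            MRSimConfig(n_snp=50, theta=0.1, prop_invalid=1.0, pleio_mean=0.05, pleio_sd=1e-6, se_x=0.001, se_y=0.001, seed=4, gamma_positive=True)
        )
        est, intercept = mr_egger(h)
        assert intercept.value == pytest.approx(0.05, abs=3 * intercept.se)
        assert est.beta == pytest.approx(0.1, abs=3 * est.se)

    def test_constrained_intercept_reproduces_ivw(self, ratio_set):
        est, _ = mr_egger(ratio_set, constrain_intercept=True)
        assert est.beta == pytest.approx(ivw(ratio_set, model="fixed").beta)

    def test_too_few_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hset([1.0, 2.0], [0.1, 0.2], [0.1, 0.1]))

    def test_collinear_design_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            mr_egger(hset([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1]))


class TestWeightedMedian:
    def test_odd_equal_weights_is_middle(self):
        h = hset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(2.0)

    def test_even_equal_weights_interpolates(self):
        # cumulative midpoints at 1/8, 3/8, 5/8, 7/8: p=0.5 interpolates
        # halfway between ratios 2 and 3 -> 2.5
        h = hset([1.0] * 4, [1.0, 2.0, 3.0, 4.0], [0.5] * 4)
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(2.5)

    def test_robust_to_minority_invalid(self):
        # 10 valid instruments at theta=0.1 plus 4 outliers at ratio 1.0
        bx = np.full(14, 1.0)
        by = np.concatenate([np.full(10, 0.1), np.full(4, 1.0)])
        h = hset(bx, by, np.full(14, 0.005), se_exp=0.005)
        est = weighted_median(h, n_boot=500, seed=3)
        assert est.beta == pytest.approx(0.1, abs=3 * est.se)

    def test_bootstrap_reproducible(self, ratio_set):
        a = weighted_median(ratio_set, n_boot=200, seed=11)
        b = weighted_median(ratio_set, n_boot=200, seed=11)
        assert a.se == b.se


class TestWeightedMode:
    def test_modal_cluster_wins(self):
        h = hset([1.0] * 4, [0.1, 0.1, 0.1, 0.5], [0.05] * 4)
        est = weighted_mode(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.1, abs=0.02)

    def test_degenerate_all_equal(self):
        h = hset([1.0] * 3, [0.3, 0.3, 0.3], [0.05] * 3)
        assert weighted_mode(h, n_boot=50, seed=0).beta == pytest.approx(0.3)

    def test_majority_valid_recovery(self):
        # 60% of instruments valid at theta=0.1, rest scattered
        bx = np.full(10, 1.0)
        by = np.concatenate([np.full(6, 0.1), [0.5, 0.7, -0.4, 0.9]])
        h = hset(bx, by, np.full(10, 0.01), se_exp=0.005)
        est = weighted_mode(h, n_boot=500, seed=5)
        assert est.beta == pytest.approx(0.1, abs=3 * est.se)


class TestEstimateAll:
    def test_single_variant_only_wald(self):
        ests, het = estimate_all(hset([0.5], [0.05], [0.01]))
        assert [e.method for e in ests] == ["wald"]
        assert het is None

    def test_all_methods_at_five_snps(self):
        h, _ = simulate_harmonized(MRSimConfig(n_snp=5, theta=0.1, seed=2))
        ests, het = estimate_all(h, seed=0, n_boot=100)
        methods = {e.method for e in ests}
        assert {"weighted_median", "weighted_mode", "egger"} <= methods
        assert any(m.startswith("ivw") for m in methods)
        assert all(e.n_snp == 5 for e in ests)
        assert het is not None

    def test_null_coverage(self):
        """CIs of every method cover theta=0 in >=90% of seeded null draws."""
        n_rep, covered = 60, {}
        for seed in range(n_rep):
            h, _ = simulate_harmonized(MRSimConfig(n_snp=5, theta=0.0, seed=seed, se_x=0.01, se_y=0.01))
            for est in estimate_all(h, seed=seed, n_boot=100)[0]:
                hit = est.ci_low <= 0.0 <= est.ci_high
                covered.setdefault(est.method.replace("ivw_re", "ivw").replace("ivw_fe", "ivw"), []).append(hit)
        for method, hits in covered.items():
            assert np.mean(hits) >= 0.90, f"{method}: coverage {np.mean(hits):.2f}"


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_statsmodels_oracle(self, rng):
        p = rng.uniform(1e-6, 1, 40)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_ref, rtol=1e-12)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_monotone_in_p(self, pvals):
        q = bh_fdr(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)
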