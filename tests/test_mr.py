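"""Estimator core: Wald ratios, IVW, Egger, weighted median, leave-one-out."""

import numpy as np
import pandas as pd
import pytest

from targetmr.harmonize import harmonize_set
from targetmr.models import CohortMeta
from targetmr.mr import egger, ivw, leave_one_out, to_or_per_reduction, wald_ratio, weighted_median
from targetmr.synthetic import simulate_exposure, simulate_outcome
from tests.conftest import calibration_config, make_harmonized


class TestWaldRatio:
    def test_basic_ratio(self):
        ratio, se = wald_ratio(0.2, 0.01, 0.04, 0.02)
        assert ratio == pytest.approx(0.2)
        assert se == pytest.approx(0.02 / 0.2)

    def test_zero_numerator(self):
        ratio, se = wald_ratio(-0.2, 0.01, 0.0, 0.02)
        assert ratio == 0.0 and se == pytest.approx(0.1)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.04, 0.02)

    def test_second_order_close_to_first_when_strong(self):
        """With strong instruments (F >= 10) and the weak per-SNP outcome
        associations typical of binary-outcome GWAS (|z_out| <= 1), the
        second-order delta SE differs from first-order by < 5%."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            se_exp = rng.uniform(0.005, 0.02)
            beta_exp = se_exp * rng.uniform(np.sqrt(10), 20)  # F in [10, 400]
            se_out = rng.uniform(0.01, 0.05)
            beta_out = se_out * rng.uniform(-1, 1)
            _, se1 = wald_ratio(beta_exp, se_exp, beta_out, se_out)
            _, se2 = wald_ratio(beta_exp, se_exp, beta_out, se_out, second_order=True)
            assert abs(se2 - se1) / se1 < 0.05


class TestIVW:
    def test_homogeneous_ratios_degenerate(self):
        hs = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3, [0.02, 0.04, 0.08], [0.01] * 3)
        est, het = ivw(hs, model="auto")
        assert est.theta == pytest.approx(0.2)
        assert het.q == pytest.approx(0.0, abs=1e-20) and het.i2 == 0.0
        assert est.method == "ivw_fe"  # no heterogeneity: fixed model chosen

    def test_k1_rejected_but_wald_consistent(self):
        hs = make_harmonized([0.2], [0.01], [0.04], [0.02])
        with pytest.raises(ValueError, match="k >= 2"):
            ivw(hs)
        ratio, se = wald_ratio(0.2, 0.01, 0.04, 0.02)
        # a single-term inverse-variance average is exactly the Wald ratio
        assert ratio == pytest.approx(0.04 / 0.2) and se == pytest.approx(0.1)

    def test_matches_wls_through_origin_oracle(self):
        """IVW on ratios equals WLS of beta_out on beta_exp through the
        origin with weights 1/se_out², to within 1e-10."""
        rng = np.random.default_rng(5)
        k = 30
        x = rng.normal(0.02, 0.005, k)
        y = 0.3 * x + rng.normal(0, 0.01, k)
        sy = rng.uniform(0.005, 0.03, k)
        hs = make_harmonized(x, np.full(k, 0.002), y, sy)
        est, _ = ivw(hs, model="fixed")
        w = 1.0 / sy**2
        theta_wls = np.sum(w * x * y) / np.sum(w * x * x)
        se_wls = np.sqrt(1.0 / np.sum(w * x * x))
        assert est.theta == pytest.approx(theta_wls, abs=1e-10)
        assert est.se == pytest.approx(se_wls, abs=1e-10)

    def test_mre_se_never_below_fixed(self):
        rng = np.random.default_rng(6)
        for trial in range(20):
            k = int(rng.integers(3, 30))
            x = rng.normal(0.02, 0.005, k)
            y = rng.normal(0, 0.05, k)
            sy = rng.uniform(0.005, 0.05, k)
            hs = make_harmonized(x, np.full(k, 0.002), y, sy)
            fe, het = ivw(hs, model="fixed")
            mre, _ = ivw(hs, model="multiplicative_random")
            assert mre.se >= fe.se
            if het.q <= het.df:
                assert mre.se == pytest.approx(fe.se)

    def test_order_and_joint_flip_invariance(self):
        rng = np.random.default_rng(8)
        k = 12
        x = rng.normal(0.02, 0.01, k)
        y = rng.normal(0, 0.05, k)
        sy = rng.uniform(0.01, 0.05, k)
        base, _ = ivw(make_harmonized(x, np.full(k, 0.002), y, sy), model="fixed")
        perm = rng.permutation(k)
        shuffled, _ = ivw(make_harmonized(x[perm], np.full(k, 0.002), y[perm], sy[perm]), model="fixed")
        signs = rng.choice([-1.0, 1.0], k)
        flipped, _ = ivw(make_harmonized(x * signs, np.full(k, 0.002), y * signs, sy), model="fixed")
        assert shuffled.theta == pytest.approx(base.theta, abs=1e-12)
        assert flipped.theta == pytest.approx(base.theta, abs=1e-12)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        x = np.array([0.1, 0.2, 0.3, 0.5])
        y = 0.05 + 0.3 * x
        est = egger(make_harmonized(x, [0.01] * 4, y, [0.02] * 4))
        assert est.egger_intercept.estimate == pytest.approx(0.05, abs=1e-12)
        assert est.theta == pytest.approx(0.3, abs=1e-12)

    def test_zero_intercept_equals_ivw(self):
        """Forcing the intercept to zero reduces Egger to IVW exactly."""
        rng = np.random.default_rng(9)
        k = 15
        x = np.abs(rng.normal(0.02, 0.01, k))
        y = rng.normal(0.01, 0.03, k)
        sy = rng.uniform(0.01, 0.05, k)
        w = 1.0 / sy**2
        slope_no_intercept = np.sum(w * x * y) / np.sum(w * x * x)
        est, _ = ivw(make_harmonized(x, np.full(k, 0.002), y, sy), model="fixed")
        assert est.theta == pytest.approx(slope_no_intercept, abs=1e-10)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            egger(make_harmonized([0.1, 0.1, 0.1], [0.01] * 3, [0.1, 0.2, 0.3], [0.02] * 3))

    def test_min_snp_count(self):
        with pytest.raises(ValueError, match="k >= 3"):
            egger(make_harmonized([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.02] * 2))

    def test_directional_pleiotropy_recovered(self):
        """With mean-0.05 pleiotropy the intercept estimate centres on 0.05
        and its test has power, over 60 simulated instrument sets."""
        meta = CohortMeta(name="registry", n_cases=4170, n_controls=195395)
        intercepts, detected = [], 0
        n_rep = 60
        for rep in range(n_rep):
            cfg = calibration_config(13_000 + rep, pleiotropy_mean=0.05, pleiotropy_sd=0.02)
            exposure, truth, _ = simulate_exposure(cfg)
            draw = simulate_outcome(exposure, truth, cfg, meta)
            est = egger(harmonize_set(exposure, draw.records))
            intercepts.append(est.egger_intercept.estimate)
            detected += est.egger_intercept.pval < 0.05
        mean_int = np.mean(intercepts)
        assert abs(mean_int - 0.05) < 2 * np.std(intercepts) / np.sqrt(n_rep)
        assert detected / n_rep > 0.5


class TestWeightedMedian:
    def test_equal_weights_middle_element(self):
        hs = make_harmonized([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.9], [0.05] * 3)
        est = weighted_median(hs, seed=1)
        assert est.theta == pytest.approx(0.2)

    def test_weight_scale_invariance(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        y = np.array([0.1, 0.25, 0.3, 0.9])
        a = weighted_median(make_harmonized(x, [0.01] * 4, y, [0.05] * 4), seed=2)
        b = weighted_median(make_harmonized(x, [0.01] * 4, y, np.array([0.05] * 4) / np.sqrt(2)), seed=2)
        assert a.theta == pytest.approx(b.theta)

    def test_robust_to_minority_weight_contamination(self):
        """Half the SNPs are grossly pleiotropic but carry a minority of the
        weight: the weighted median stays near truth while IVW is dragged."""
        rng = np.random.default_rng(17)
        theta = 0.3
        k = 20
        x = rng.normal(0.02, 0.003, k)
        sy = np.concatenate([np.full(10, 0.005), np.full(10, 0.02)])  # invalid SNPs downweighted
        y = theta * x + rng.normal(0, sy)
        y[10:] += 0.05  # gross pleiotropy on the minority-weight half
        hs = make_harmonized(x, np.full(k, 0.001), y, sy)
        wm = weighted_median(hs, seed=17)
        est_ivw, _ = ivw(hs, model="fixed")
        assert abs(wm.theta - theta) < 2 * wm.se
        assert abs(est_ivw.theta - theta) > abs(wm.theta - theta)

    def test_seed_mandatory(self):
        hs = make_harmonized([1.0] * 3, [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(hs)


class TestLeaveOneOut:
    def test_homogeneous_all_equal(self):
        hs = make_harmonized([0.1, 0.2, 0.4, 0.3], [0.01] * 4, [0.02, 0.04, 0.08, 0.06], [0.01] * 4)
        full, _ = ivw(hs, model="fixed")
        for _, est, flag in leave_one_out(hs, model="fixed"):
            assert est.theta == pytest.approx(full.theta)

    def test_outlier_exclusion_departs_most(self):
        rng = np.random.default_rng(19)
        k = 15
        x = rng.normal(0.02, 0.003, k)
        y = 0.2 * x + rng.normal(0, 0.002, k)
        y[7] += 0.1  # gross outlier
        hs = make_harmonized(x, np.full(k, 0.001), y, np.full(k, 0.005))
        full, _ = ivw(hs, model="fixed")
        results = leave_one_out(hs, model="fixed")
        departures = [abs(est.theta - full.theta) for _, est, _ in results]
        assert int(np.argmax(departures)) == 7

    def test_k3_gives_three_pairwise_estimates(self):
        hs = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3, [0.02, 0.05, 0.05], [0.01] * 3)
        results = leave_one_out(hs, model="fixed")
        assert len(results) == 3
        assert all(est.k == 2 for _, est, _ in results)


class TestORTransform:
    def test_published_loop_diuretic_row_reproduced_to_4_decimals(self):
        or_, lo, hi = to_or_per_reduction(-0.0717, 0.0188)
        assert (round(or_, 4), round(lo, 4), round(hi, 4)) == (0.9308, 0.8971, 0.9657)

    def test_published_aldosterone_ci_reproduced_to_4_decimals(self):
        # the published OR for this row (1.0815) carries a last-digit
        # rounding artifact from the unrounded beta; the CI is exact
        or_, lo, hi = to_or_per_reduction(0.0783, 0.0313)
        assert (round(lo, 4), round(hi, 4)) == (1.0171, 1.1499)
        assert round(or_, 3) == 1.081

    def test_null_effect_symmetric(self):
        or_, lo, hi = to_or_per_reduction(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_estimate_reporting_negates_once(self):
        from targetmr.models import MREstimate

        est = MREstimate(method="ivw_fe", theta=0.0717, se=0.0188, pval=1e-4, k=27)
        assert round(est.or_reduction, 4) == 0.9308
        lo, hi = est.ci_reduction
        assert (round(lo, 4), round(hi, 4)) == (0.8971, 0.9657)
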