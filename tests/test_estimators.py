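"""Estimator suite: Wald, IVW, weighted median, MR-Egger, aggregation."""

import numpy as np
import pytest
import statsmodels.api as sm

from twosample_mr import (
    EmptySetError,
    HarmonizedSet,
    InsufficientInstrumentsError,
    UndefinedRatioError,
    egger,
    estimate_all,
    ivw,
    wald_ratio,
    weighted_median,
)
from twosample_mr.estimators import _wm_point

from conftest import make_harmonized
from oracles import (
    egger_wls,
    ivw_origin_wls,
    random_harmonized_arrays,
    weighted_median_bruteforce,
)


def _hset_from_arrays(bx, sx, by, sy):
    return make_harmonized(list(zip(bx, sx, by, sy)))


class TestWaldRatio:
    def test_direct_arithmetic(self):
        hset = make_harmonized([(0.05, 0.01, 0.01, 0.004)])
        est = wald_ratio(hset.variants[0])
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.08)

    def test_null_outcome_effect(self):
        hset = make_harmonized([(0.05, 0.01, 0.0, 0.004)])
        assert wald_ratio(hset.variants[0]).beta == 0.0

    def test_orientation_invariance(self):
        a = make_harmonized([(0.05, 0.01, 0.01, 0.004)]).variants[0]
        b = make_harmonized([(-0.05, 0.01, -0.01, 0.004)]).variants[0]
        assert wald_ratio(a).beta == wald_ratio(b).beta
        assert wald_ratio(a).se == wald_ratio(b).se

    def test_zero_exposure_beta_rejected(self):
        v = make_harmonized([(0.0, 0.01, 0.01, 0.004)]).variants[0]
        with pytest.raises(UndefinedRatioError):
            wald_ratio(v)


class TestIVW:
    def test_single_variant_equals_wald(self):
        hset = make_harmonized([(0.07, 0.01, 0.02, 0.005)])
        est = ivw(hset)
        wald = wald_ratio(hset.variants[0])
        assert est.beta == pytest.approx(wald.beta, abs=0)
        assert est.se == pytest.approx(wald.se, abs=0)

    def test_three_variant_toy_matches_origin_wls_oracle(self, toy_set):
        bx, _, by, sy = toy_set.arrays()
        beta_oracle, se_oracle = ivw_origin_wls(bx, by, sy)
        est = ivw(toy_set, effects_model="fixed")
        assert est.beta == pytest.approx(beta_oracle, abs=1e-12)
        assert est.se == pytest.approx(se_oracle, abs=1e-12)

    def test_effects_model_rule(self):
        """Random effects kick in at 4 instruments; dispersion never shrinks
        the fixed-effects standard error."""
        rng = np.random.default_rng(0)
        for k, expected in [(2, "ivw_fixed"), (3, "ivw_fixed"), (4, "ivw_random"), (9, "ivw_random")]:
            hset = _hset_from_arrays(*random_harmonized_arrays(rng, k))
            est = ivw(hset, effects_model="auto")
            assert est.method == expected
            fixed = ivw(hset, effects_model="fixed")
            assert est.se >= fixed.se - 1e-15

    def test_empty_set_rejected(self):
        with pytest.raises(EmptySetError):
            ivw(HarmonizedSet())

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(1)
        bx, sx, by, sy = random_harmonized_arrays(rng, 8)
        base = ivw(_hset_from_arrays(bx, sx, by, sy))
        flip = rng.choice([-1.0, 1.0], 8)
        est = ivw(_hset_from_arrays(bx * flip, sx, by * flip, sy))
        assert est.beta == base.beta and est.se == base.se


class TestWeightedMedian:
    def test_degenerate_equal_ratios(self):
        hset = make_harmonized(
            [(0.1, 0.01, 0.05, 0.01), (0.2, 0.01, 0.1, 0.02), (0.4, 0.01, 0.2, 0.01)]
        )
        est = weighted_median(hset, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_four_variant_toy_matches_bruteforce_oracle(self):
        hset = make_harmonized(
            [
                (0.10, 0.005, 0.010, 0.004),
                (0.20, 0.005, 0.050, 0.010),
                (0.15, 0.005, 0.045, 0.006),
                (0.25, 0.005, 0.020, 0.008),
            ]
        )
        bx, _, by, sy = hset.arrays()
        expected = weighted_median_bruteforce(bx, by, sy)
        est = weighted_median(hset, n_boot=100, seed=0)
        assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_point_deterministic_bootstrap_se_stable(self):
        rng = np.random.default_rng(2)
        hset = _hset_from_arrays(*random_harmonized_arrays(rng, 6))
        a = weighted_median(hset, n_boot=4000, seed=1)
        b = weighted_median(hset, n_boot=4000, seed=2)
        assert a.beta == b.beta
        assert a.se == pytest.approx(b.se, rel=0.15)

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(3)
        for k in (3, 5, 10):
            bx, sx, by, sy = random_harmonized_arrays(rng, k)
            ratios = by / bx
            point = _wm_point(bx, by, sy)
            assert ratios.min() - 1e-12 <= point <= ratios.max() + 1e-12

    def test_too_few_instruments(self):
        hset = make_harmonized([(0.1, 0.01, 0.02, 0.01), (0.2, 0.01, 0.03, 0.01)])
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(hset)


class TestEgger:
    def test_noiseless_proportional_data(self):
        """With by exactly theta*bx the intercept is 0 and slope theta."""
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        hset = _hset_from_arrays(bx, np.full(4, 0.01), 0.3 * bx, np.full(4, 0.01))
        slope, intercept = egger(hset)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_five_variant_toy_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(4)
        bx, sx, by, sy = random_harmonized_arrays(rng, 5)
        bx = np.abs(bx)  # oracle computed on the oriented scale
        slope, intercept = egger(_hset_from_arrays(bx, sx, by, sy))
        o_slope, o_int, o_se_slope, o_se_int = egger_wls(bx, by, sy)
        assert slope.beta == pytest.approx(o_slope, abs=1e-12)
        assert intercept.beta == pytest.approx(o_int, abs=1e-12)
        # implementation scales the unit-variance SEs by dispersion >= 1
        assert slope.se >= o_se_slope - 1e-15
        assert intercept.se >= o_se_int - 1e-15

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(5)
        bx, sx, by, sy = random_harmonized_arrays(rng, 12)
        bx = np.abs(bx)
        slope, intercept = egger(_hset_from_arrays(bx, sx, by, sy))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_intercept_constrained_to_zero_is_ivw_fixed(self):
        """Dropping the intercept column reduces Egger's regression to IVW."""
        rng = np.random.default_rng(6)
        bx, sx, by, sy = random_harmonized_arrays(rng, 7)
        beta_origin, _ = ivw_origin_wls(bx, by, sy)
        est = ivw(_hset_from_arrays(bx, sx, by, sy), effects_model="fixed")
        assert est.beta == pytest.approx(beta_origin, abs=1e-12)

    def test_orientation_applied_internally(self):
        rng = np.random.default_rng(7)
        bx, sx, by, sy = random_harmonized_arrays(rng, 9)
        flip = rng.choice([-1.0, 1.0], 9)
        a = egger(_hset_from_arrays(bx, sx, by, sy))
        b = egger(_hset_from_arrays(bx * flip, sx, by * flip, sy))
        assert a[0].beta == b[0].beta and a[1].beta == b[1].beta

    def test_collinear_exposure_betas_rejected(self):
        from twosample_mr import CollinearityError

        hset = make_harmonized(
            [(0.1, 0.01, 0.02, 0.01), (0.1, 0.01, 0.03, 0.01), (0.1, 0.01, 0.04, 0.01)]
        )
        with pytest.raises(CollinearityError):
            egger(hset)


class TestEstimateAll:
    def _sets(self, ks):
        rng = np.random.default_rng(8)
        return {
            f"k{k}": _hset_from_arrays(*random_harmonized_arrays(rng, k)) for k in ks
        }

    def test_row_count_combinatorial_oracle(self):
        """One row per (set x applicable method): IVW always, WM and Egger
        only at k >= 3, mirroring the sensitivity-table layout."""
        sets = self._sets([4, 3, 2])
        frame = estimate_all(sets, n_boot=100, seed=0)
        expected = sum(1 + 2 * (k >= 3) for k in (4, 3, 2))
        assert len(frame) == expected == 7
        assert set(frame.loc[frame.set_label == "k2", "method"]) == {"ivw_fixed"}

    def test_single_method_single_set(self):
        frame = estimate_all(self._sets([5]), methods=("ivw",))
        assert len(frame) == 1

    def test_deterministic_given_seed(self):
        sets = self._sets([6])
        a = estimate_all(sets, n_boot=500, seed=9)
        b = estimate_all(sets, n_boot=500, seed=9)
        assert a.equals(b)

    def test_rescale_multiplies_effect_columns(self):
        sets = self._sets([5])
        base = estimate_all(sets, methods=("ivw",))
        scaled = estimate_all(sets, methods=("ivw",), rescale=0.6931)
        assert scaled.beta.iloc[0] == pytest.approx(base.beta.iloc[0] * 0.6931)
        assert scaled.pvalue.iloc[0] == pytest.approx(base.pvalue.iloc[0])
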