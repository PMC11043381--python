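import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mr2s import (
    ValidationError,
    egger,
    generate_study,
    harmonize_all,
    ivw_random_effects,
    make_truth,
    ratio_estimates,
    to_odds_scale,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import instruments_from_arrays, make_instrument


class TestRatioEstimates:
    def test_direct_arithmetic(self):
        theta, se, w, kept = ratio_estimates(
            [make_instrument(beta_exp=0.1, beta_out=0.02, se_out=0.005)]
        )
        assert theta[0] == pytest.approx(0.2)
        assert se[0] == pytest.approx(0.05)
        assert w[0] == pytest.approx(400.0)

    def test_zero_outcome_effect(self):
        theta, *_ = ratio_estimates([make_instrument(beta_out=0.0)])
        assert theta[0] == 0.0

    def test_negative_exposure_effect_sign(self):
        theta, se, *_ = ratio_estimates(
            [make_instrument(beta_exp=-0.1, beta_out=0.02, se_out=0.005)]
        )
        assert theta[0] == pytest.approx(-0.2)
        assert se[0] == pytest.approx(0.05)  # SE uses |beta_exp|

    def test_null_instrument_dropped(self):
        theta, _se, _w, kept = ratio_estimates(
            [make_instrument("rs1", beta_exp=0.0), make_instrument("rs2")]
        )
        assert [k.snp_id for k in kept] == ["rs2"]


class TestWaldRatio:
    def test_single_snp(self):
        r = wald_ratio([make_instrument(beta_exp=0.1, beta_out=0.05, se_out=0.01)])
        assert r.beta_hat == pytest.approx(0.5)
        assert r.se_hat == pytest.approx(0.1)
        assert r.n_snps == 1

    def test_two_identical_snps_halve_variance(self):
        inst = make_instrument(beta_exp=0.1, beta_out=0.05, se_out=0.01)
        single = wald_ratio([inst])
        double = wald_ratio([inst, inst])
        assert double.beta_hat == pytest.approx(single.beta_hat)
        assert double.se_hat == pytest.approx(single.se_hat / math.sqrt(2))

    def test_null_outcome_gives_unit_odds_ratio(self):
        r = wald_ratio([make_instrument(beta_out=0.0)])
        assert r.beta_hat == 0.0
        assert r.or_point == 1.0

    @pytest.mark.parametrize("n", [0, 3])
    def test_snp_count_bounds(self, n):
        with pytest.raises(ValidationError):
            wald_ratio([make_instrument(f"rs{i}") for i in range(n)])


class TestIvw:
    def test_hand_worked_two_snp_example(self):
        insts = instruments_from_arrays([1.0, 1.0], [0.1, 0.3], [0.1, 0.2])
        r = ivw_random_effects(insts)
        # weights 100 and 25; weighted mean (100*0.1 + 25*0.3)/125 = 0.14
        assert r.beta_hat == pytest.approx(0.14)
        # Q = 100*(0.1-0.14)^2 + 25*(0.3-0.14)^2 = 0.8 < 1 df: no inflation
        assert r.se_hat == pytest.approx(math.sqrt(1 / 125))
        assert r.se_hat == pytest.approx(0.0894, abs=2e-4)

    def test_identical_ratios_have_zero_heterogeneity(self):
        insts = instruments_from_arrays([0.1, 0.2, 0.4], [0.05, 0.1, 0.2], [0.01, 0.01, 0.01])
        r = ivw_random_effects(insts)
        assert r.beta_hat == pytest.approx(0.5)

    def test_single_snp_is_hard_error(self):
        with pytest.raises(ValidationError):
            ivw_random_effects([make_instrument()])

    def test_equal_weights_reduce_to_simple_mean(self):
        bx = np.full(5, 0.2)
        by = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        insts = instruments_from_arrays(bx, by, np.full(5, 0.01))
        r = ivw_random_effects(insts)
        assert r.beta_hat == pytest.approx(np.mean(by / bx))

    def test_wald_ratio_point_matches_ivw_of_duplicated_snp(self):
        inst = make_instrument(beta_exp=0.15, beta_out=0.03, se_out=0.004)
        assert wald_ratio([inst]).beta_hat == pytest.approx(
            ivw_random_effects([inst, inst]).beta_hat
        )

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_matches_weighted_regression_through_origin(self, data):
        """IVW equals weighted least squares of beta_out on beta_exp with
        no intercept and weights 1/se_out^2 (statsmodels oracle)."""
        import statsmodels.api as sm

        n = data.draw(st.integers(2, 8))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        bx = rng.uniform(0.05, 0.5, n) * rng.choice([-1, 1], n)
        by = rng.normal(0, 0.05, n)
        sy = rng.uniform(0.005, 0.05, n)
        insts = instruments_from_arrays(bx, by, sy)
        r = ivw_random_effects(insts)
        fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert r.beta_hat == pytest.approx(fit.params[0], abs=1e-10)


class TestEgger:
    def test_exact_line_fit(self):
        insts = instruments_from_arrays([1.0, 2.0, 3.0], [0.3, 0.5, 0.7], [0.1, 0.1, 0.1])
        r = egger(insts)
        assert r.beta_hat == pytest.approx(0.2, abs=1e-12)
        assert r.egger_intercept == pytest.approx(0.1, abs=1e-12)

    def test_null_outcome_gives_zero_slope_and_intercept(self):
        insts = instruments_from_arrays([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [0.01] * 3)
        r = egger(insts)
        assert r.beta_hat == 0.0
        assert r.egger_intercept == 0.0

    def test_orientation_applied_before_fit(self):
        """Flipping any SNP's allele labels must not change the fit."""
        insts = instruments_from_arrays(
            [0.1, 0.2, 0.3, 0.4], [0.03, 0.05, 0.08, 0.09], [0.01] * 4
        )
        flipped = instruments_from_arrays(
            [-0.1, 0.2, -0.3, 0.4], [-0.03, 0.05, -0.08, 0.09], [0.01] * 4
        )
        assert egger(flipped).beta_hat == pytest.approx(egger(insts).beta_hat)
        assert egger(flipped).egger_intercept == pytest.approx(
            egger(insts).egger_intercept
        )

    def test_degenerate_design_is_hard_error(self):
        insts = instruments_from_arrays([0.2, 0.2, 0.2], [0.1, 0.2, 0.3], [0.01] * 3)
        with pytest.raises(ValidationError):
            egger(insts)

    def test_too_few_snps_is_hard_error(self):
        with pytest.raises(ValidationError):
            egger([make_instrument("rs1"), make_instrument("rs2")])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_matches_statsmodels_wls_with_intercept(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n = 8
        bx = rng.uniform(0.05, 0.5, n)
        by = 0.1 + 0.3 * bx + rng.normal(0, 0.02, n)
        sy = rng.uniform(0.005, 0.05, n)
        insts = instruments_from_arrays(bx, by, sy)
        r = egger(insts)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert r.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert r.beta_hat == pytest.approx(fit.params[1], abs=1e-10)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        insts = instruments_from_arrays([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.1] * 3)
        r = weighted_median(insts, n_boot=200, seed=0)
        assert r.beta_hat == pytest.approx(0.2)

    def test_outlier_robustness(self):
        insts = instruments_from_arrays(
            [1.0] * 5, [0.10, 0.11, 0.12, 0.13, 5.0], [0.1] * 5
        )
        r = weighted_median(insts, n_boot=200, seed=0)
        assert 0.11 <= r.beta_hat <= 0.13

    def test_bootstrap_se_deterministic_for_seed(self):
        insts = instruments_from_arrays([1.0] * 4, [0.1, 0.15, 0.2, 0.25], [0.1] * 4)
        a = weighted_median(insts, n_boot=300, seed=5)
        b = weighted_median(insts, n_boot=300, seed=5)
        assert a.se_hat == b.se_hat

    def test_degenerate_ratios_collapse_to_common_value(self):
        insts = instruments_from_arrays([1.0] * 3, [0.2] * 3, [1e-6] * 3)
        r = weighted_median(insts, n_boot=200, seed=0)
        assert r.beta_hat == pytest.approx(0.2)
        assert r.se_hat < 1e-5


class TestWeightedMode:
    def test_majority_cluster_wins(self):
        insts = instruments_from_arrays(
            [1.0] * 4, [0.2, 0.2, 0.2, 1.0], [0.1] * 4
        )
        r = weighted_mode(insts, n_boot=100, seed=0)
        assert r.beta_hat == pytest.approx(0.2, abs=0.05)

    def test_identical_ratios_return_common_value(self):
        insts = instruments_from_arrays([1.0] * 3, [0.3] * 3, [0.1] * 3)
        assert weighted_mode(insts, n_boot=50, seed=0).beta_hat == pytest.approx(0.3)

    def test_seed_determinism(self):
        insts = instruments_from_arrays([1.0] * 4, [0.1, 0.2, 0.25, 0.6], [0.1] * 4)
        assert (
            weighted_mode(insts, n_boot=100, seed=3).se_hat
            == weighted_mode(insts, n_boot=100, seed=3).se_hat
        )


class TestOddsScale:
    def test_null_estimate_straddles_one(self):
        d = to_odds_scale(0.0, 0.1)
        assert d["or_point"] == 1.0
        assert d["or_low"] < 1.0 < d["or_high"]
        assert d["pval"] == pytest.approx(1.0)

    def test_doubling_example(self):
        d = to_odds_scale(math.log(2), 0.1)
        assert d["or_point"] == pytest.approx(2.0)
        assert d["or_low"] == pytest.approx(math.exp(math.log(2) - 1.959964 * 0.1), rel=1e-6)
        assert d["or_low"] == pytest.approx(1.644, abs=1e-3)
        assert d["or_high"] == pytest.approx(2.433, abs=1e-3)

    def test_monotone_in_beta(self):
        assert to_odds_scale(0.5, 0.1)["or_point"] > to_odds_scale(0.3, 0.1)["or_point"]


class TestParameterRecoveryProperties:
    def test_median_more_robust_than_ivw_under_planted_outliers(self):
        """With 20% of instruments pleiotropic, the weighted median drifts
        less than IVW on average."""
        from mr2s import plant_outliers

        ivw_bias, med_bias = [], []
        for seed in range(30):
            study = generate_study(make_truth(m_snps=25, beta_causal=0.2, seed=seed))
            shift = 8 * max(r.se for r in study.outcome_records)
            planted = plant_outliers(study, 5, shift, seed=seed + 1)
            h = harmonize_all(planted.exposure_records, planted.outcome_records)
            ivw_bias.append(ivw_random_effects(h).beta_hat - 0.2)
            med_bias.append(weighted_median(h, n_boot=50, seed=seed).beta_hat - 0.2)
        assert abs(np.median(med_bias)) < abs(np.median(ivw_bias))
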