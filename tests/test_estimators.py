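"""Wald ratios, IVW pooling, heterogeneity, rescaling and OR conversion."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrwald import (
    ExposureScale,
    InputError,
    MRResult,
    StateError,
    UndefinedRatioError,
    ivw_pool,
    relative_effect,
    rescale_per_sd,
    to_odds_ratio,
    wald_ratio,
)

from conftest import make_harmonized, random_wald_estimates


class TestWaldRatio:
    def test_first_order_hand_oracle(self):
        # ratio = 0.02/0.1 = 0.2; se = 0.005/0.1 = 0.05
        est = wald_ratio(make_harmonized(), se_order="first")
        assert est.ratio == pytest.approx(0.2, abs=1e-12)
        assert est.se == pytest.approx(0.05, abs=1e-12)
        assert est.ci_low == pytest.approx(0.2 - 1.96 * 0.05, abs=1e-12)
        assert est.ci_high == pytest.approx(0.2 + 1.96 * 0.05, abs=1e-12)

    def test_second_order_hand_oracle(self):
        # sqrt(0.005^2/0.1^2 + 0.02^2 * 0.01^2 / 0.1^4) = sqrt(0.0029)
        est = wald_ratio(make_harmonized(), se_order="second")
        assert est.se == pytest.approx(math.sqrt(0.0029), abs=1e-12)
        assert est.ratio == pytest.approx(0.2, abs=1e-12)

    def test_null_outcome_gives_zero_ratio_and_p_one(self):
        est = wald_ratio(make_harmonized(beta_outcome=0.0))
        assert est.ratio == 0.0 and est.pvalue == 1.0

    def test_zero_exposure_beta_is_undefined_and_names_rsid(self):
        with pytest.raises(UndefinedRatioError, match="rs1"):
            wald_ratio(make_harmonized(beta_exposure=0.0))

    def test_negative_exposure_beta_uses_absolute_value_in_se(self):
        est = wald_ratio(make_harmonized(beta_exposure=-0.1))
        assert est.ratio == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.05)

    def test_pvalue_is_two_sided_normal(self):
        est = wald_ratio(make_harmonized())
        z = est.ratio / est.se
        assert est.pvalue == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)


class TestIVWPool:
    def _two_estimates(self, rng):
        ests = random_wald_estimates(rng, 2)
        ests[0].ratio, ests[0].se = 0.2, 0.05
        ests[1].ratio, ests[1].se = 0.1, 0.1
        return ests

    def test_two_estimate_hand_oracle(self, rng):
        # weights 400 and 100: estimate 0.18, se 1/sqrt(500), Q 0.8
        pooled = ivw_pool(self._two_estimates(rng))
        assert pooled.estimate == pytest.approx(0.18, abs=1e-12)
        assert pooled.se == pytest.approx(1 / math.sqrt(500), abs=1e-12)
        assert pooled.q_stat == pytest.approx(0.8, abs=1e-12)
        assert pooled.q_df == 1
        assert pooled.q_pvalue == pytest.approx(stats.chi2.sf(0.8, 1), rel=1e-12)

    def test_single_estimate_pools_to_itself(self, rng):
        (est,) = random_wald_estimates(rng, 1)
        pooled = ivw_pool([est])
        assert pooled.estimate == pytest.approx(est.ratio, abs=1e-14)
        assert pooled.se == pytest.approx(est.se, abs=1e-14)
        assert pooled.n_snps == 1 and pooled.q_df == 0
        assert pooled.q_pvalue is None
        assert pooled.q_stat == pytest.approx(0.0, abs=1e-14)

    def test_empty_list_is_input_error(self):
        with pytest.raises(InputError):
            ivw_pool([])

    def test_permutation_invariance(self, rng):
        ests = random_wald_estimates(rng, 7)
        a = ivw_pool(ests)
        b = ivw_pool(list(reversed(ests)))
        assert a.estimate == pytest.approx(b.estimate, rel=1e-14)
        assert a.q_stat == pytest.approx(b.q_stat, rel=1e-12)

    @given(st.integers(2, 12), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_pooled_estimate_bracketing_and_se_dominance(self, n, seed):
        """Pooled estimate lies within per-variant range; pooled SE below min SE."""
        ests = random_wald_estimates(np.random.default_rng(seed), n)
        pooled = ivw_pool(ests)
        ratios = [e.ratio for e in ests]
        assert min(ratios) - 1e-12 <= pooled.estimate <= max(ratios) + 1e-12
        assert pooled.se <= min(e.se for e in ests) + 1e-12

    def test_invariant_se_equals_inverse_root_weight_sum(self, rng):
        ests = random_wald_estimates(rng, 5)
        pooled = ivw_pool(ests)
        w = sum(1 / e.se**2 for e in ests)
        assert pooled.se == pytest.approx(1 / math.sqrt(w), abs=1e-12)
        assert pooled.ci_low == pytest.approx(pooled.estimate - 1.96 * pooled.se, abs=1e-12)
        assert pooled.ci_high == pytest.approx(pooled.estimate + 1.96 * pooled.se, abs=1e-12)

    def test_weighted_regression_through_origin_oracle(self, rng):
        """IVW equals WLS of outcome on exposure betas through the origin."""
        import statsmodels.api as sm

        from mrwald import harmonize
        from conftest import make_assoc

        n = 8
        bx = rng.normal(0.05, 0.01, size=n)
        by = rng.normal(0.01, 0.005, size=n)
        se_y = rng.uniform(0.002, 0.01, size=n)
        exp = [make_assoc(rsid=f"rs{j}", beta=float(bx[j])) for j in range(n)]
        out = [
            make_assoc(rsid=f"rs{j}", beta=float(by[j]), se=float(se_y[j]))
            for j in range(n)
        ]
        ests = [wald_ratio(h, se_order="first") for h in harmonize(exp, out)]
        pooled = ivw_pool(sorted(ests, key=lambda e: e.rsid))
        fit = sm.WLS(by, bx, weights=1 / se_y**2).fit()
        assert pooled.estimate == pytest.approx(float(fit.params[0]), rel=1e-10)

    def test_multiplicative_model_inflates_se_only_under_heterogeneity(self, rng):
        ests = random_wald_estimates(rng, 6)
        fixed = ivw_pool(ests, model="fixed")
        mult = ivw_pool(ests, model="multiplicative")
        assert mult.estimate == fixed.estimate
        if fixed.q_stat / fixed.q_df > 1:
            assert mult.se == pytest.approx(
                fixed.se * math.sqrt(fixed.q_stat / fixed.q_df), rel=1e-12
            )
        else:
            assert mult.se == fixed.se


class TestRescalePerSD:
    def test_rescale_hand_oracle(self, rng):
        pooled = ivw_pool(random_wald_estimates(rng, 3))
        scaled = rescale_per_sd(pooled, 0.25)
        assert scaled.estimate == pytest.approx(pooled.estimate * 0.25, rel=1e-14)
        assert scaled.per_sd and scaled.sd_used == 0.25

    def test_per_log_unit_to_per_sd(self, rng):
        ests = random_wald_estimates(rng, 2)
        ests[0].ratio = ests[1].ratio = 0.28
        pooled = ivw_pool(ests)
        assert rescale_per_sd(pooled, 0.25).estimate == pytest.approx(0.07, abs=1e-12)

    def test_unit_sd_is_identity_with_flag(self, rng):
        pooled = ivw_pool(random_wald_estimates(rng, 3))
        scaled = rescale_per_sd(pooled, 1.0)
        assert scaled.estimate == pooled.estimate and scaled.se == pooled.se
        assert scaled.per_sd

    def test_rescaling_preserves_z_and_p(self, rng):
        pooled = ivw_pool(random_wald_estimates(rng, 3))
        scaled = rescale_per_sd(pooled, 3.5)
        assert scaled.estimate / scaled.se == pytest.approx(
            pooled.estimate / pooled.se, rel=1e-12
        )
        assert scaled.pvalue == pooled.pvalue

    def test_double_application_is_state_error(self, rng):
        pooled = rescale_per_sd(ivw_pool(random_wald_estimates(rng, 3)), 0.25)
        with pytest.raises(StateError):
            rescale_per_sd(pooled, 0.25)

    def test_nonpositive_sd_is_input_error(self, rng):
        pooled = ivw_pool(random_wald_estimates(rng, 3))
        with pytest.raises(InputError):
            rescale_per_sd(pooled, 0.0)

    def test_wald_estimate_rescaling(self):
        est = wald_ratio(make_harmonized())
        scaled = rescale_per_sd(est, 0.25)
        assert scaled.ratio == pytest.approx(0.05, abs=1e-14)
        with pytest.raises(StateError):
            rescale_per_sd(scaled, 0.25)


def _mr_result(estimate, se, scale="log_odds"):
    return MRResult(
        estimate=estimate,
        se=se,
        ci_low=estimate - 1.96 * se,
        ci_high=estimate + 1.96 * se,
        pvalue=float(2 * stats.norm.sf(abs(estimate / se))),
        n_snps=3,
        q_stat=1.0,
        q_df=2,
        q_pvalue=0.6,
        scale=scale,
    )


class TestOddsRatioConversion:
    def test_null_estimate_gives_or_one(self):
        assert to_odds_ratio(_mr_result(0.0, 0.1)).oratio == 1.0

    def test_hand_exponentiation(self):
        o = to_odds_ratio(_mr_result(-0.0305, 0.0366))
        assert o.oratio == pytest.approx(math.exp(-0.0305), rel=1e-12)
        assert o.oratio == pytest.approx(0.970, abs=5e-4)
        assert o.ci_low == pytest.approx(math.exp(-0.0305 - 1.96 * 0.0366), rel=1e-12)
        assert o.ci_low == pytest.approx(0.903, abs=5e-4)
        assert o.ci_high == pytest.approx(1.042, abs=5e-4)

    def test_p_unchanged_by_exponentiation(self):
        r = _mr_result(-0.0305, 0.0366)
        assert to_odds_ratio(r).pvalue == r.pvalue

    def test_linear_scale_refused(self):
        with pytest.raises(StateError):
            to_odds_ratio(_mr_result(0.07, 0.01, scale="linear"))


class TestRelativeEffect:
    @pytest.mark.parametrize(
        "estimate,reference,expected",
        [(0.07, 0.51, 100 * 0.07 / 0.51), (0.07, 0.56, 12.5), (0.0, 0.51, 0.0)],
    )
    def test_percent_of_reference_mean(self, estimate, reference, expected):
        r = _mr_result(estimate, 0.01, scale="linear")
        assert relative_effect(r, reference) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_reference_is_input_error(self):
        with pytest.raises(InputError):
            relative_effect(_mr_result(0.07, 0.01, scale="linear"), 0.0)

    def test_log_odds_scale_refused(self):
        with pytest.raises(StateError):
            relative_effect(_mr_result(0.07, 0.01), 0.51)


def test_exposure_scale_requires_positive_values():
    ExposureScale(sd_linear=3.5, sd_log=0.25, mean_linear=13.1, mean_log=2.5)
    with pytest.raises(InputError):
        ExposureScale(sd_linear=0.0, sd_log=0.25, mean_linear=13.1, mean_log=2.5)
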