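import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from liabilitymr.estimators import (
    InsufficientInstrumentsError,
    egger,
    ivw,
    scale_to_doubling,
    wald_ratio,
    weighted_median,
)
from liabilitymr.harmonize import HarmonizedSet

from conftest import make_pair, make_set


class TestWaldRatio:
    def test_direct_division(self):
        res = wald_ratio(make_pair(beta_exp=0.5, beta_out=0.05, se_out=0.01))
        assert res.beta == pytest.approx(0.10)
        assert res.se == pytest.approx(0.02)
        assert res.n_snp == 1
        assert res.q is None

    def test_null_effect(self):
        res = wald_ratio(make_pair(beta_exp=1.0, beta_out=0.0))
        assert res.beta == 0.0

    def test_pvalue_from_normal_tail(self):
        # (0.25, 0.02, 0.005): beta 0.08, se 0.02, |z| = 4.
        res = wald_ratio(make_pair(beta_exp=0.25, beta_out=0.02, se_out=0.005))
        assert res.beta == pytest.approx(0.08)
        assert res.se == pytest.approx(0.02)
        assert res.pval == pytest.approx(2 * stats.norm.sf(4.0), rel=1e-12)

    def test_zero_exposure_effect_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_pair(beta_exp=0.0))

    def test_negative_exposure_effect_keeps_se_positive(self):
        res = wald_ratio(make_pair(beta_exp=-0.5, beta_out=0.05, se_out=0.01))
        assert res.beta == pytest.approx(-0.10)
        assert res.se == pytest.approx(0.02)


class TestIVW:
    def test_homogeneous_ratios_give_zero_q_and_fixed_se(self):
        hs = make_set(bx=[0.2, 0.4, 0.5], by=[0.02, 0.04, 0.05],
                      sy=[0.01, 0.01, 0.02])
        res = ivw(hs)
        assert res.beta == pytest.approx(0.1)
        assert res.q == pytest.approx(0.0, abs=1e-20)
        w = np.array([0.2, 0.4, 0.5]) ** 2 / np.array([0.01, 0.01, 0.02]) ** 2
        assert res.se == pytest.approx(w.sum() ** -0.5)

    def test_two_snp_weighted_mean_oracle(self):
        # w = (0.4/0.01)^2 style first-order weights: (1600, 625);
        # beta = (1600*0.05 + 625*0.08)/2225 = 130/2225.
        hs = make_set(bx=[0.4, 0.5], by=[0.02, 0.04], sy=[0.01, 0.02])
        res = ivw(hs)
        assert res.beta == pytest.approx(130 / 2225, rel=1e-12)
        assert res.q_df == 1

    def test_equals_zero_intercept_weighted_regression(self, toy_set):
        """Algebraic identity: IVW = slope of by ~ bx with weights 1/se_y²."""
        bx = np.array([p.beta_exp for p in toy_set])
        by = np.array([p.beta_out for p in toy_set])
        sy = np.array([p.se_out for p in toy_set])
        fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert ivw(toy_set).beta == pytest.approx(float(fit.params[0]), rel=1e-10)

    def test_random_effects_se_floors_at_fixed_effect(self, toy_set):
        res = ivw(toy_set)
        w = np.array([p.beta_exp**2 / p.se_out**2 for p in toy_set])
        se_fixed = w.sum() ** -0.5
        assert res.se >= se_fixed - 1e-15
        expected = se_fixed * max(1.0, math.sqrt(res.q / res.q_df))
        assert res.se == pytest.approx(expected)

    def test_single_instrument_rejected(self):
        hs = make_set(bx=[0.2], by=[0.02], sy=[0.01])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(hs)

    def test_zero_exposure_pair_excluded_with_warning(self, caplog):
        hs = make_set(bx=[0.2, 0.0, 0.4], by=[0.02, 0.01, 0.04],
                      sy=[0.01, 0.01, 0.01])
        res = ivw(hs)
        assert res.n_snp == 2


class TestEgger:
    def test_exact_proportionality_recovers_slope_and_zero_intercept(self):
        bx = [0.2, 0.3, 0.4, 0.5]
        hs = make_set(bx=bx, by=[0.1 * b for b in bx], sy=[0.01] * 4)
        res = egger(hs)
        assert res.beta == pytest.approx(0.1, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        bx = [0.2, 0.3, 0.4, 0.5]
        hs = make_set(bx=bx, by=[0.02 + 0.1 * b for b in bx], sy=[0.01] * 4)
        res = egger(hs)
        assert res.intercept == pytest.approx(0.02, abs=1e-12)
        assert res.beta == pytest.approx(0.1, abs=1e-12)

    def test_matches_weighted_least_squares_oracle(self):
        """Independent WLS fit (statsmodels) on a 5-SNP toy."""
        bx = np.array([0.2, 0.35, 0.15, 0.5, 0.4])
        by = np.array([0.03, 0.02, 0.04, 0.06, 0.01])
        sy = np.array([0.01, 0.02, 0.015, 0.01, 0.02])
        hs = make_set(bx=list(bx), by=list(by), sy=list(sy))
        res = egger(hs)
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1 / sy**2).fit()
        assert res.intercept == pytest.approx(float(fit.params[0]), rel=1e-9)
        assert res.beta == pytest.approx(float(fit.params[1]), rel=1e-9)
        # SEs agree once both use the same overdispersion convention:
        # statsmodels scales by RSS_w/(k-2) without flooring at 1.
        rss_w = float(np.sum((1 / sy**2) * fit.resid**2))
        phi = max(1.0, math.sqrt(rss_w / 3))
        unit_se = np.sqrt(np.diag(np.linalg.inv(X.T @ np.diag(1 / sy**2) @ X)))
        assert res.intercept_se == pytest.approx(phi * unit_se[0], rel=1e-9)
        assert res.se == pytest.approx(phi * unit_se[1], rel=1e-9)
        assert res.q == pytest.approx(rss_w, rel=1e-9)
        assert res.q_df == 3

    def test_orientation_invariance(self):
        """Relabelling an instrument's alleles (negating both betas) leaves
        the Egger fit unchanged."""
        bx = [0.2, 0.35, 0.15, 0.5]
        by = [0.03, 0.02, 0.04, 0.06]
        hs1 = make_set(bx=bx, by=by, sy=[0.01] * 4)
        hs2 = make_set(bx=[-bx[0]] + bx[1:], by=[-by[0]] + by[1:], sy=[0.01] * 4)
        r1, r2 = egger(hs1), egger(hs2)
        assert r1.beta == pytest.approx(r2.beta)
        assert r1.intercept == pytest.approx(r2.intercept)

    def test_too_few_instruments(self):
        hs = make_set(bx=[0.2, 0.3], by=[0.02, 0.03], sy=[0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            egger(hs)


def brute_force_weighted_median(theta, weights):
    """Independent oracle: linear interpolation over the sorted
    cumulative-weight grid at probability 0.5."""
    order = np.argsort(theta)
    theta = np.asarray(theta)[order]
    w = np.asarray(weights)[order] / np.sum(weights)
    grid = np.cumsum(w) - w / 2
    return float(np.interp(0.5, grid, theta))


class TestWeightedMedian:
    def from_ratios(self, ratios, weights):
        """Build a set whose per-SNP ratios and IVW weights are as given."""
        bx = np.sqrt(np.asarray(weights, dtype=float))  # se_out = 1 => w = bx^2
        by = np.asarray(ratios) * bx
        return make_set(bx=list(bx), by=list(by), sy=[1.0] * len(bx))

    def test_symmetric_median(self):
        hs = self.from_ratios([0.1, 0.2, 0.3], [1, 1, 1])
        res = weighted_median(hs, seed=7)
        assert res.beta == pytest.approx(0.2)

    def test_majority_valid_robustness(self):
        hs = self.from_ratios([0.1, 0.1, 0.1, 5.0], [1, 1, 1, 1])
        res = weighted_median(hs, seed=7)
        assert res.beta == pytest.approx(0.1)

    def test_unequal_weights_match_interpolation_oracle(self):
        ratios = [0.05, 0.12, 0.2, 0.4]
        weights = [4.0, 1.0, 2.0, 0.5]
        hs = self.from_ratios(ratios, weights)
        res = weighted_median(hs, seed=7)
        assert res.beta == pytest.approx(brute_force_weighted_median(ratios, weights))

    def test_bootstrap_se_is_seed_reproducible(self, toy_set):
        r1 = weighted_median(toy_set, seed=11)
        r2 = weighted_median(toy_set, seed=11)
        r3 = weighted_median(toy_set, seed=12)
        assert r1.se == r2.se
        assert r1.se != r3.se

    def test_seed_is_required(self, toy_set):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(toy_set)


class TestScaleToDoubling:
    def test_null_is_scale_invariant(self):
        hs = make_set(bx=[0.2, 0.4], by=[0.0, 0.0], sy=[0.01, 0.01])
        res = scale_to_doubling(ivw(hs))
        assert res.beta == 0.0
        assert res.odds_ratio == 1.0
        lo, hi = res.or_ci
        assert lo * hi == pytest.approx(1.0)  # symmetric on the log scale

    def test_multiplies_by_ln2(self):
        base = wald_ratio(make_pair(beta_exp=1.0, beta_out=0.1, se_out=0.05))
        res = scale_to_doubling(base)
        assert res.beta == pytest.approx(0.0693147, abs=1e-7)
        assert res.se == pytest.approx(0.0346574, abs=1e-7)

    def test_odds_ratio_surface_closed_form(self):
        base = wald_ratio(make_pair(beta_exp=1.0, beta_out=0.1, se_out=0.05))
        res = scale_to_doubling(base)
        beta, se = 0.1 * math.log(2), 0.05 * math.log(2)
        assert res.odds_ratio == pytest.approx(math.exp(beta), rel=1e-9)
        lo, hi = res.or_ci
        assert lo == pytest.approx(math.exp(beta - 1.96 * se), rel=1e-9)
        assert hi == pytest.approx(math.exp(beta + 1.96 * se), rel=1e-9)
        assert (round(res.odds_ratio, 4), round(lo, 4), round(hi, 4)) == (
            1.0718, 1.0014, 1.1471,
        )

    def test_pvalue_invariant_under_scaling(self, toy_set):
        base = ivw(toy_set)
        assert scale_to_doubling(base).pval == pytest.approx(base.pval, rel=1e-12)

    def test_double_scaling_is_a_state_error(self, toy_set):
        scaled = scale_to_doubling(ivw(toy_set))
        with pytest.raises(ValueError, match="already"):
            scale_to_doubling(scaled)


class TestEstimatorFamilyProperties:
    def test_homogeneous_ratios_agree_across_estimators(self):
        bx = [0.2, 0.3, 0.4, 0.5]
        hs = make_set(bx=bx, by=[0.07 * b for b in bx], sy=[0.01, 0.02, 0.01, 0.03])
        assert ivw(hs).beta == pytest.approx(0.07)
        assert egger(hs).beta == pytest.approx(0.07)
        assert weighted_median(hs, seed=3).beta == pytest.approx(0.07)
        assert ivw(hs).q == pytest.approx(0.0, abs=1e-20)

    @given(
        seed=st.integers(0, 500),
        k=st.integers(3, 8),
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_negating_outcomes_negates_estimates_fixes_se_and_q(self, seed, k):
        rng = np.random.default_rng(seed)
        bx = list(rng.uniform(0.1, 0.6, k))
        by = list(rng.normal(0, 0.05, k))
        sy = list(rng.uniform(0.005, 0.03, k))
        hs = make_set(bx=bx, by=by, sy=sy)
        neg = make_set(bx=bx, by=[-b for b in by], sy=sy)
        r, rn = ivw(hs), ivw(neg)
        assert rn.beta == pytest.approx(-r.beta, rel=1e-9, abs=1e-12)
        assert rn.se == pytest.approx(r.se, rel=1e-9)
        assert rn.q == pytest.approx(r.q, rel=1e-9, abs=1e-12)
        e, en = egger(hs), egger(neg)
        assert en.beta == pytest.approx(-e.beta, rel=1e-9, abs=1e-12)
        assert en.intercept == pytest.approx(-e.intercept, rel=1e-9, abs=1e-12)
        assert en.se == pytest.approx(e.se, rel=1e-9)

    @given(seed=st.integers(0, 500), k=st.integers(2, 10))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_ivw_matches_zero_intercept_wls_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.6, k)
        by = rng.normal(0, 0.05, k)
        sy = rng.uniform(0.005, 0.03, k)
        hs = make_set(bx=list(bx), by=list(by), sy=list(sy))
        fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert ivw(hs).beta == pytest.approx(float(fit.params[0]), rel=1e-9)
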