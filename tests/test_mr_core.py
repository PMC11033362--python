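"""Causal estimators: Wald ratio, IVW, MR-Egger, weighted median."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from targetmr import (
    DomainError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
    egger,
    ivw,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from targetmr.mr_core import _weighted_median, _weighted_median_batch

from conftest import PUBLISHED_FNTA_CI, PUBLISHED_IVW_OR, make_hset


class TestWaldRatio:
    def test_closed_form(self):
        est = wald_ratio(0.5, 0.01, 0.1, 0.05)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.n_snp == 1

    def test_zero_outcome_effect_gives_unit_or(self):
        est = wald_ratio(0.5, 0.01, 0.0, 0.05)
        assert est.beta == 0.0
        assert est.or_ == 1.0

    def test_bundled_fnta_instrument_ratio(self, fnta):
        row = fnta.rows.set_index("snp_id").loc["rs1648121"]
        est = wald_ratio(row["beta_exposure"], row["se_exposure"],
                         row["beta_outcome"], row["se_outcome"])
        assert est.beta == pytest.approx(0.05521 / -0.126149, abs=0)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)


def _ivw_normal_equations(bx, by, sy):
    """Independent oracle: weighted least squares through the origin."""
    W = np.diag(1.0 / np.asarray(sy) ** 2)
    X = np.asarray(bx)[:, None]
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ np.asarray(by))
    return float(beta[0])


class TestIvw:
    def test_reproduces_published_fnta_estimate(self, fnta):
        est = ivw(fnta)
        assert est.or_ == pytest.approx(PUBLISHED_IVW_OR["FNTA"], rel=1e-8)
        assert est.pval == pytest.approx(0.000226306, rel=1e-4)

    def test_hmgcr_floor_inflates_p_relative_to_fixed(self, all_sets):
        """Heterogeneous instruments: the floored SE must enlarge the p."""
        hmgcr = all_sets["HMGCR"]
        floored = ivw(hmgcr, mode="mre_floor")
        fixed = ivw(hmgcr, mode="fixed")
        assert floored.pval == pytest.approx(0.011753459, rel=1e-6)
        assert fixed.pval < floored.pval

    def test_homogeneous_set_floor_equals_fixed(self, fnta):
        """FNTA's Q/(L-1) < 1, so the floor leaves the fixed SE untouched."""
        assert ivw(fnta, mode="mre_floor").se == ivw(fnta, mode="fixed").se
        assert ivw(fnta, mode="mre").se < ivw(fnta, mode="fixed").se

    def test_all_zero_outcome_betas(self):
        h = make_hset([0.2, 0.3, 0.4], [0.0, 0.0, 0.0], [0.05, 0.05, 0.05])
        est = ivw(h)
        assert est.beta == 0.0
        assert est.or_ == 1.0

    def test_single_snp_delegates_to_wald(self):
        h = make_hset([0.5], [0.1], [0.05])
        est = ivw(h)
        ref = wald_ratio(0.5, 0.01, 0.1, 0.05)
        assert est.method == "ivw"
        assert (est.beta, est.se) == (ref.beta, ref.se)

    def test_matches_normal_equations_oracle(self, all_sets):
        for hset in all_sets.values():
            oracle = _ivw_normal_equations(hset.bx, hset.by, hset.sy)
            assert ivw(hset).beta == pytest.approx(oracle, rel=1e-12)

    @given(flips=st.lists(st.booleans(), min_size=4, max_size=4))
    def test_invariant_under_per_snp_sign_flips(self, flips):
        bx = np.array([0.2, -0.3, 0.15, 0.4])
        by = np.array([0.05, 0.02, -0.01, 0.03])
        sy = np.array([0.05, 0.04, 0.06, 0.05])
        sgn = np.where(flips, -1.0, 1.0)
        est0 = ivw(make_hset(bx, by, sy))
        est1 = ivw(make_hset(bx * sgn, by * sgn, sy))
        assert est1.beta == pytest.approx(est0.beta, rel=1e-12)
        assert est1.se == pytest.approx(est0.se, rel=1e-12)


def _egger_normal_equations(bx, by, sy):
    """Independent oracle: explicit 2x2 weighted normal equations."""
    w = 1.0 / np.asarray(sy) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * by)
    a_hat, slope_hat = np.linalg.solve(A, b)
    return float(a_hat), float(slope_hat)


class TestEgger:
    def test_noise_free_data_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        theta = -0.7
        h = make_hset(bx, theta * bx, np.full(4, 0.05))
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(theta, abs=1e-12)
        assert intercept["estimate"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_two_by_two_solve_on_fnta(self, fnta):
        a_hat, slope_hat = _egger_normal_equations(fnta.bx, fnta.by, fnta.sy)
        slope, intercept = egger(fnta)
        assert slope.beta == pytest.approx(slope_hat, rel=1e-10)
        assert intercept["estimate"] == pytest.approx(a_hat, rel=1e-10)

    def test_global_sign_flip_negates_intercept_only(self, fnta):
        flipped = make_hset(-fnta.bx, -fnta.by, fnta.sy, sx=fnta.sx)
        s0, i0 = egger(fnta)
        s1, i1 = egger(flipped)
        assert s1.beta == pytest.approx(s0.beta, rel=1e-12)
        assert i1["estimate"] == pytest.approx(-i0["estimate"], rel=1e-12)

    def test_zero_intercept_fit_reproduces_ivw(self, all_sets):
        """Forcing the intercept to zero must collapse Egger onto IVW."""
        import statsmodels.api as sm

        for hset in all_sets.values():
            fit = sm.WLS(hset.by, hset.bx[:, None], weights=1.0 / hset.sy**2).fit()
            assert float(fit.params[0]) == pytest.approx(ivw(hset).beta, rel=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.0, 0.0], [0.1, 0.1]))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        assert _weighted_median(np.array([1.0, 9.0, 2.0]), np.ones(3)) == 2.0

    def test_hand_oracle_interpolation(self):
        """Weights (.5,.25,.25) on sorted ratios (0,1,2): the cumulative
        positions are (.25,.625,.875), so the half-weight point sits 2/3 of
        the way between the first two ratios."""
        val = _weighted_median(np.array([0.0, 1.0, 2.0]),
                               np.array([0.5, 0.25, 0.25]))
        assert val == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(7)
        V = rng.normal(size=(50, 5))
        W = rng.uniform(0.1, 1, size=(50, 5))
        batch = _weighted_median_batch(V, W)
        scalar = [_weighted_median(V[i], W[i]) for i in range(50)]
        np.testing.assert_allclose(batch, scalar, rtol=1e-12)

    @given(
        ratios=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=3, max_size=9,
        ).filter(lambda v: len(v) % 2 == 1)
    )
    def test_equal_weight_convergence_to_median(self, ratios):
        v = np.asarray(ratios)
        assert _weighted_median(v, np.ones_like(v)) == pytest.approx(
            float(np.median(v)), rel=1e-12, abs=1e-12
        )

    def test_seeded_bootstrap_is_deterministic(self, fnta):
        a = weighted_median(fnta, n_boot=500, seed=11)
        b = weighted_median(fnta, n_boot=500, seed=11)
        c = weighted_median(fnta, n_boot=500, seed=12)
        assert a.se == b.se
        assert a.se != c.se
        assert a.beta == b.beta == c.beta  # the point estimate has no noise

    def test_rejects_bad_n_boot(self, fnta):
        from targetmr import ConfigurationError

        with pytest.raises(ConfigurationError):
            weighted_median(fnta, n_boot=0)


class TestToOddsRatio:
    def test_null_beta_multiplicatively_symmetric_ci(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.3)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_published_fnta_ci_endpoints(self, fnta):
        est = ivw(fnta)
        lo, hi = PUBLISHED_FNTA_CI
        assert est.ci_low == pytest.approx(lo, rel=1e-8)
        assert est.ci_high == pytest.approx(hi, rel=1e-8)

    def test_ci_collapses_as_se_vanishes(self):
        or_, lo, hi = to_odds_ratio(np.log(2), 1e-12)
        assert lo == pytest.approx(or_, rel=1e-9)
        assert hi == pytest.approx(or_, rel=1e-9)

    def test_bad_level(self):
        with pytest.raises(DomainError):
            to_odds_ratio(0.1, 0.1, level=1.5)


def test_all_estimators_agree_on_collinear_data():
    """On noise-free proportional effects every method returns theta."""
    bx = np.array([0.1, -0.25, 0.3, 0.45, 0.2])
    theta = 0.42
    h = make_hset(bx, theta * bx, np.full(5, 0.04))
    assert ivw(h).beta == pytest.approx(theta, abs=1e-12)
    assert egger(h)[0].beta == pytest.approx(theta, abs=1e-12)
    assert weighted_median(h, n_boot=200, seed=0).beta == pytest.approx(theta, abs=1e-12)
    ratios = h.by / h.bx
    assert np.allclose(ratios, theta)
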