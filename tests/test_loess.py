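"""The local-linear smoother: windows, kernel, fits, edf, BIC, span search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glp import (
    DEFAULT_SPAN_GRID,
    DegenerateFitError,
    LoessFit,
    ValidationError,
    compute_bic,
    local_window,
    loess_fit,
    select_span,
    tricube_weight,
)
from oracles import loess_fitted_oracle, span_grid_oracle, wls_window_oracle


class TestLocalWindow:
    @pytest.mark.parametrize("span,expected_q", [(0.1, 2000), (0.01, 200)])
    def test_genome_scale_window_sizes(self, span, expected_q):
        """20,000 genes: span 0.1 -> 2,000-gene windows, 0.01 -> 200."""
        x = np.linspace(0, 1, 20_000)
        idx, _ = local_window(x, 10_000, span)
        assert idx.size == expected_q

    def test_minimum_window_of_four(self):
        x = np.linspace(0, 1, 10)
        idx, _ = local_window(x, 5, 0.01)
        assert idx.size == 4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            local_window(np.array([0.0, 1.0, 2.0]), 0, 0.5)

    def test_matches_sort_by_distance_then_index(self):
        rng = np.random.default_rng(11)
        x = np.sort(np.round(rng.uniform(0, 1, 60), 2))  # rounded => many ties
        for j in (0, 17, 30, 59):
            idx, h = local_window(x, j, 0.2)
            oidx, oh = wls_window_oracle(x, j, 0.2)
            np.testing.assert_array_equal(np.sort(idx), np.sort(oidx))
            assert h == pytest.approx(oh)


class TestTricube:
    def test_closed_form_values(self):
        assert tricube_weight(0.0, 1.0) == 1.0
        assert tricube_weight(1.0, 1.0) == 0.0
        assert tricube_weight(0.5, 1.0) == pytest.approx((1 - 1 / 8) ** 3)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValidationError):
            tricube_weight(0.5, 0.0)

    @given(st.floats(0, 10), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_monotone_in_distance(self, d, h):
        w = tricube_weight(d, h)
        assert 0 <= w <= 1
        assert tricube_weight(min(d + 0.1, h), h) <= w + 1e-12


class TestLoessFit:
    def test_reproduces_constants(self):
        x = np.linspace(0, 1, 50)
        for span in (0.1, 0.5, 1.0):
            fit = loess_fit(x, np.full(50, 7.0), span)
            np.testing.assert_allclose(fit.fitted, 7.0, atol=1e-12)
        fit = loess_fit(x, np.zeros(50), 0.5)
        assert fit.rss == 0.0 and fit.bic is None  # exact interpolation

    def test_reproduces_affine_functions(self):
        x = np.linspace(0, 2, 100)
        y = 2 * x + 1
        for span in (0.05, 0.3, 1.0):
            fit = loess_fit(x, y, span)
            np.testing.assert_allclose(fit.fitted, y, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_point_wls_oracle(self, seed):
        """Each fitted value equals an independent per-point WLS solve."""
        rng = np.random.default_rng(seed)
        n = 80
        x = np.sort(rng.uniform(0, 1, n))
        y = x**2 + rng.normal(0, 0.05, n)
        fit = loess_fit(x, y, 0.5)
        oracle_fitted, oracle_hat = loess_fitted_oracle(x, y, 0.5)
        np.testing.assert_allclose(fit.fitted, oracle_fitted, atol=1e-10)
        np.testing.assert_allclose(fit.edf, oracle_hat.sum(), atol=1e-10)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_oracle_with_ties_and_masking(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        x = np.sort(np.round(rng.uniform(0, 1, n), 2))  # heavy ties, like f = k/c
        y = np.exp(x) + rng.normal(0, 0.1, n)
        w = (rng.uniform(size=n) > 0.2).astype(float)
        w[:4] = 1.0
        fit = loess_fit(x, y, 0.3, obs_weights=w)
        oracle_fitted, oracle_hat = loess_fitted_oracle(x, y, 0.3, obs_weights=w)
        np.testing.assert_allclose(fit.fitted, oracle_fitted, atol=1e-10)
        np.testing.assert_allclose(fit.edf, oracle_hat.sum(), atol=1e-10)

    def test_residuals_and_rss_consistent(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 1, 60))
        y = np.sin(3 * x) + rng.normal(0, 0.1, 60)
        w = np.ones(60)
        w[10:15] = 0
        fit = loess_fit(x, y, 0.4, obs_weights=w)
        np.testing.assert_allclose(fit.residuals, y - fit.fitted)
        np.testing.assert_allclose(fit.rss, np.sum(fit.residuals[w > 0] ** 2))

    def test_hat_diagonal_in_unit_interval_and_edf_decreasing(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.uniform(0, 1, 100))
        y = x + rng.normal(0, 0.1, 100)
        edfs = []
        for span in (0.1, 0.3, 0.6, 1.0):
            fit = loess_fit(x, y, span)
            assert np.all(fit.hat_diag >= -1e-12) and np.all(fit.hat_diag <= 1 + 1e-12)
            edfs.append(fit.edf)
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))

    def test_zero_weight_points_are_inert_but_fitted(self):
        """Perturbing a masked observation's y changes no fitted value."""
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 1, 50))
        y = x**2 + rng.normal(0, 0.02, 50)
        w = np.ones(50)
        w[25] = 0.0
        fit_a = loess_fit(x, y, 0.5, obs_weights=w)
        y2 = y.copy()
        y2[25] += 100.0
        fit_b = loess_fit(x, y2, 0.5, obs_weights=w)
        np.testing.assert_array_equal(fit_a.fitted, fit_b.fitted)
        assert np.isfinite(fit_a.fitted[25])
        assert fit_a.hat_diag[25] == 0.0

    def test_identical_x_window_falls_back_to_mean(self):
        x = np.zeros(6)
        y = np.array([1.0, 2, 3, 4, 5, 6])
        fit = loess_fit(x, y, 1.0)
        np.testing.assert_allclose(fit.fitted, y.mean())

    def test_fewer_than_four_positive_weights_rejected(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(ValidationError):
            loess_fit(x, x, 0.5, obs_weights=np.r_[np.ones(3), np.zeros(7)])

    def test_unsorted_x_rejected(self):
        with pytest.raises(ValidationError):
            loess_fit(np.array([0.5, 0.1, 0.9, 0.2]), np.ones(4), 0.5)

    def test_agrees_with_statsmodels_lowess(self):
        """Independent cross-check against the reference lowess smoother.

        Window bookkeeping differs slightly between implementations, so the
        comparison is loose; it guards against gross kernel/weighting bugs.
        """
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(0, 1, 300))
        y = np.sin(2 * x) + rng.normal(0, 0.05, 300)
        fit = loess_fit(x, y, 0.3)
        ref = sm.nonparametric.lowess(y, x, frac=0.3, it=0, return_sorted=False)
        assert np.max(np.abs(fit.fitted - ref)) < 0.05


class TestBic:
    def _fit(self, n_obs, rss, edf):
        z = np.zeros(n_obs)
        return LoessFit(span=0.1, x=z, y=z, obs_weights=np.ones(n_obs),
                        fitted=z, residuals=z, rss=rss, edf=edf, bic=None)

    @pytest.mark.parametrize(
        "n_obs,rss,edf,expected",
        [
            (100, 100.0, 5.0, 5 * math.log(100)),           # ln(RSS/n) = 0
            (10, 20.0, 3.0, 10 * math.log(2) + 3 * math.log(10)),
        ],
    )
    def test_closed_form(self, n_obs, rss, edf, expected):
        assert compute_bic(self._fit(n_obs, rss, edf)) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_edf(self):
        assert compute_bic(self._fit(50, 10.0, 6.0)) > compute_bic(self._fit(50, 10.0, 5.0))

    def test_zero_rss_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            compute_bic(self._fit(50, 0.0, 5.0))

    def test_stored_bic_matches_formula(self):
        rng = np.random.default_rng(10)
        x = np.sort(rng.uniform(0, 1, 80))
        y = x + rng.normal(0, 0.1, 80)
        fit = loess_fit(x, y, 0.4)
        assert fit.bic == pytest.approx(
            fit.n_obs * math.log(fit.rss / fit.n_obs) + fit.edf * math.log(fit.n_obs),
            abs=1e-12,
        )


class TestSelectSpan:
    def test_singleton_grid(self):
        rng = np.random.default_rng(12)
        x = np.sort(rng.uniform(0, 1, 50))
        y = x + rng.normal(0, 0.1, 50)
        span, bics = select_span(x, y, grid=(0.05,))
        assert span == 0.05 and set(bics) == {0.05}

    def test_default_grid_has_ten_candidates(self):
        assert len(DEFAULT_SPAN_GRID) == 10
        assert DEFAULT_SPAN_GRID[0] == 0.01 and DEFAULT_SPAN_GRID[-1] == 0.10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_grid_oracle(self, seed):
        """Selected span equals an independent refit-everything argmin."""
        rng = np.random.default_rng(seed)
        n = 150
        x = np.sort(rng.uniform(0, 1, n))
        y = np.sin(4 * x) + rng.normal(0, 0.2, n)
        grid = (0.1, 0.2, 0.3, 0.5)
        span, _ = select_span(x, y, grid=grid)
        assert span == span_grid_oracle(x, y, grid)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            select_span(np.linspace(0, 1, 10), np.ones(10), grid=())
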