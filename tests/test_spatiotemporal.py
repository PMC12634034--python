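import numpy as np
import pytest

from ksrv import (
    ValidationError,
    binned_variance,
    cubic_fit,
    distance_from_origin,
    estimate_omega,
    mean_nonzero_expression,
    percentile_trends,
    simulate_omega_data,
    spatiotemporal_profile,
)
from ksrv.spatiotemporal import _minmax


class TestDistance:
    @pytest.mark.parametrize(
        "point,origin,expected",
        [((0.0, 0.0), (0.0, 0.0), 0.0), ((3.0, 4.0), (0.0, 0.0), 5.0),
         ((4.0, 5.0), (1.0, 1.0), 5.0)],
    )
    def test_known_distances(self, point, origin, expected):
        assert distance_from_origin(np.array([point]), origin)[0] == expected

    def test_matches_loop_oracle(self, rng):
        coords = rng.normal(size=(20, 2))
        d = distance_from_origin(coords, (0.5, -0.2))
        oracle = [np.hypot(x - 0.5, y + 0.2) for x, y in coords]
        assert np.max(np.abs(d - oracle)) < 1e-12


class TestBinnedVariance:
    def test_constant_distances_have_zero_variance(self, rng):
        t = rng.uniform(0, 1, 50)
        prof = binned_variance(np.full(50, 2.0), t)
        occupied = prof.bin_counts >= 2
        np.testing.assert_allclose(prof.variances[occupied], 0.0, atol=1e-15)

    def test_population_variance_hand_case(self):
        # one bin holding d = (1, 3): mean 2, population variance 1
        d = np.array([1.0, 3.0, 5.0, 5.0])
        t = np.array([0.0, 0.05, 0.95, 1.0])
        prof = binned_variance(d, t, n_bins=2)
        assert prof.variances[0] == pytest.approx(1.0)
        assert prof.variances[1] == pytest.approx(0.0)

    def test_default_binning_yields_ten_intervals(self, rng):
        prof = binned_variance(rng.uniform(size=200), rng.uniform(size=200))
        assert len(prof.bin_edges) == 11
        assert len(prof.variances) == 10
        assert prof.bin_counts.sum() == 200

    def test_equal_width_bins(self, rng):
        prof = binned_variance(rng.uniform(size=50), rng.uniform(size=50))
        widths = np.diff(prof.bin_edges)
        np.testing.assert_allclose(widths, widths[0])

    def test_pooled_variance_dominates_within_bin_mean(self, rng):
        d = rng.normal(5, 2, 500)
        t = rng.uniform(0, 1, 500)
        prof = binned_variance(d, t)
        pooled = np.mean((d - d.mean()) ** 2)
        occupied = prof.bin_counts >= 2
        within = np.average(
            prof.variances[occupied], weights=prof.bin_counts[occupied]
        )
        assert pooled >= within - 1e-12


class TestCubicFit:
    def test_recovers_generating_coefficients(self):
        x = np.linspace(-1, 2, 10)
        a, b, c, d = 1.0, -2.0, 0.5, 3.0
        y = a * x**3 + b * x**2 + c * x + d
        coef, rss = cubic_fit(x, y)
        np.testing.assert_allclose(coef, (a, b, c, d), atol=1e-8)
        assert rss < 1e-16

    def test_constant_series(self):
        coef, _ = cubic_fit(np.arange(6.0), np.full(6, 7.0))
        np.testing.assert_allclose(coef, (0, 0, 0, 7.0), atol=1e-10)

    def test_four_points_interpolated_exactly(self, rng):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = rng.normal(size=4)
        coef, rss = cubic_fit(x, y)
        assert rss < 1e-18

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            cubic_fit(np.arange(3.0), np.arange(3.0))

    def test_duplicated_x_warns_minimum_norm(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0])
        y = np.array([1.0, 1.0, 2.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="rank-deficient"):
            cubic_fit(x[:4], y[:4])


class TestPercentiles:
    def test_identical_values_collapse(self):
        d = np.full(30, 4.2)
        t = np.linspace(0, 1, 30)
        prof = percentile_trends(d, t, n_bins=3)
        occ = prof.bin_counts >= 2
        np.testing.assert_allclose(prof.p10[occ], 4.2)
        np.testing.assert_allclose(prof.p90[occ], 4.2)

    def test_linear_interpolation_on_integer_grid(self):
        # first bin holds the integers 0..100: p10 = 10, p90 = 90
        d = np.concatenate([np.arange(101.0), [7.0, 9.0]])
        t = np.concatenate([np.zeros(101), [1.0, 1.0]])
        prof = percentile_trends(d, t, n_bins=2)
        assert prof.p10[0] == pytest.approx(10.0)
        assert prof.p90[0] == pytest.approx(90.0)

    def test_order_property(self, rng):
        prof = percentile_trends(rng.normal(size=300), rng.uniform(size=300))
        occ = np.isfinite(prof.p10)
        assert np.all(prof.p10[occ] <= prof.p90[occ])


class TestMeanNonzero:
    @pytest.mark.parametrize(
        "row,expected", [((0.0, 2.0, 4.0), 3.0), ((5.0, 5.0, 5.0), 5.0),
                         ((0.0, 0.0, 0.0), 0.0)]
    )
    def test_row_values(self, row, expected):
        assert mean_nonzero_expression(np.array([row]))[0] == expected


class TestOmega:
    def test_pure_temporal_signal(self, rng):
        T = rng.uniform(0, 1, 100)
        D = rng.uniform(0, 1, 100)
        est = estimate_omega(T, D, T.copy(), np.full(100, "t", dtype=object),
                             rescale=False)
        assert est.per_type_omega["t"] == pytest.approx(1.0)
        assert est.per_type_loss["t"] == pytest.approx(0.0, abs=1e-20)

    def test_pure_spatial_signal(self, rng):
        T = rng.uniform(0, 1, 100)
        D = rng.uniform(0, 1, 100)
        est = estimate_omega(T, D, D.copy(), np.full(100, "d", dtype=object),
                             rescale=False)
        assert est.per_type_omega["d"] == pytest.approx(0.0)

    def test_recovery_and_grid_search_agreement(self):
        T, D, Y, types = simulate_omega_data({"m": 0.7}, 500, 0.01, seed=8)
        est = estimate_omega(T, D, Y, types)
        assert abs(est.per_type_omega["m"] - 0.7) < 0.05
        Tn, Dn, Yn = _minmax(T), _minmax(D), _minmax(Y)
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-4)
        losses = [np.sum((w * Tn + (1 - w) * Dn - Yn) ** 2) for w in grid]
        w_grid = grid[int(np.argmin(losses))]
        assert abs(est.per_type_omega["m"] - w_grid) <= 1e-4

    def test_swap_symmetry(self, rng):
        T, D, Y, types = simulate_omega_data({"s": 0.3}, 200, 0.02, seed=5)
        w = estimate_omega(T, D, Y, types, rescale=False).per_type_omega["s"]
        w_swapped = estimate_omega(D, T, Y, types, rescale=False).per_type_omega["s"]
        assert w_swapped == pytest.approx(1.0 - w, abs=1e-10)

    def test_degenerate_type_reported_missing(self):
        T = np.full(10, 0.5)
        est = estimate_omega(T, T.copy(), T.copy(),
                             np.full(10, "x", dtype=object), rescale=False)
        assert "x" in est.missing and "x" not in est.per_type_omega


class TestProfileComposition:
    def test_full_profile_has_cubic_trends(self, rng):
        coords = rng.uniform(0, 10, size=(400, 2))
        t = rng.uniform(0, 1, 400)
        prof = spatiotemporal_profile(coords, t)
        assert prof.cubic_coeffs_variance is not None
        assert prof.cubic_coeffs_p10 is not None
        assert len(prof.cubic_coeffs_variance) == 4
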