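"""KDE core: dwell profiles, pooling, bandwidths, densities, masking.

The vectorised estimators are checked against brute-force nested-loop
oracles and, independently, against scipy's Gaussian KDE with a matched
bandwidth.
"""

import math

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from tidkde.kde_core import (
    DegenerateDataError,
    bandwidth_1d,
    bandwidth_2d,
    cap_and_mask,
    dominant_intensity_modes,
    dwell_profile,
    grid_1d,
    kde2d_dwell,
    kde_1d,
    kde_2d,
    pool_points,
    trapezoid_integral_1d,
    trapezoid_integral_2d,
)

SQRT_2PI = math.sqrt(2 * math.pi)


def brute_kde_1d(values, grid, h, weights=None):
    """O(n*m) reference: literal sum of Gaussian bumps."""
    n = len(values)
    w = weights if weights is not None else [1.0 / n] * n
    out = []
    for g in grid:
        acc = 0.0
        for x, wi in zip(values, w):
            z = (g - x) / h
            acc += wi * math.exp(-0.5 * z * z) / (h * SQRT_2PI)
        out.append(acc)
    return np.array(out)


def brute_kde_2d(points, grid_x, grid_y, h_x, h_y, weights=None):
    """O(n*m) reference: literal product-kernel triple loop."""
    n = len(points)
    w = weights if weights is not None else [1.0 / n] * n
    out = np.zeros((len(grid_y), len(grid_x)))
    for iy, gy in enumerate(grid_y):
        for ix, gx in enumerate(grid_x):
            acc = 0.0
            for (x, y), wi in zip(points, w):
                zx = (gx - x) / h_x
                zy = (gy - y) / h_y
                acc += (
                    wi
                    * math.exp(-0.5 * zx * zx)
                    * math.exp(-0.5 * zy * zy)
                    / (h_x * h_y * 2 * math.pi)
                )
            out[iy, ix] = acc
    return out


class TestDwellProfile:
    def test_single_value(self, rel_factory):
        p = dwell_profile(rel_factory([70] * 100))
        assert p.seconds == {70: 100}
        assert p.shares == {70: 100.0}

    def test_even_split(self, rel_factory):
        p = dwell_profile(rel_factory([70] * 50 + [80] * 50))
        assert p.shares == {70: 50.0, 80: 50.0}

    def test_shares_sum_to_100(self, rel_factory):
        rng = np.random.default_rng(1)
        p = dwell_profile(rel_factory(rng.integers(50, 100, 777)))
        assert sum(p.shares.values()) == pytest.approx(100.0, abs=1e-9)


class TestPooling:
    def test_point_count(self, rel_factory):
        p = dwell_profile(rel_factory([60, 70, 80]))
        points, weights = pool_points([p])
        assert points.shape == (3, 2)
        assert weights.sum() == pytest.approx(1.0)

    def test_duplication_invariance(self, rel_factory):
        """Pooling a profile with itself leaves the uniform-weight KDE
        unchanged."""
        p = dwell_profile(rel_factory([60] * 30 + [70] * 50 + [75] * 20))
        pts1, w1 = pool_points([p])
        pts2, w2 = pool_points([p, p])
        grid_x = np.linspace(0, 60, 50)
        grid_y = np.linspace(50, 85, 50)
        d1 = kde_2d(pts1, grid_x, grid_y, 5.0, 3.0, w1).density
        d2 = kde_2d(pts2, grid_x, grid_y, 5.0, 3.0, w2).density
        np.testing.assert_allclose(d1, d2, atol=1e-14)

    def test_per_session_weights_sum_to_one_per_session(self, rel_factory):
        p_small = dwell_profile(rel_factory([60, 70], session_id="a"))
        p_big = dwell_profile(
            rel_factory(list(range(60, 70)), session_id="b")
        )
        pts, w = pool_points([p_small, p_big], weighting="per_session")
        assert w[:2].sum() == pytest.approx(0.5)
        assert w[2:].sum() == pytest.approx(0.5)


class TestBandwidths:
    def test_silverman_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=1)  # exact sigma = 1
        assert bandwidth_1d(x) == pytest.approx((4 / 300) ** 0.2, abs=1e-12)

    def test_silverman_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        assert bandwidth_1d(2 * x) == pytest.approx(2 * bandwidth_1d(x))

    def test_scott_closed_form(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(64, 2))
        for d in range(2):
            pts[:, d] = (pts[:, d] - pts[:, d].mean()) / pts[:, d].std(ddof=1)
        hx, hy = bandwidth_2d(pts)
        assert hx == pytest.approx(0.5, abs=1e-12)  # 64**(-1/6) = 1/2
        assert hy == pytest.approx(0.5, abs=1e-12)

    def test_scott_axis_swap_symmetry(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(40, 2)) * [1.0, 3.0]
        hx, hy = bandwidth_2d(pts)
        hy2, hx2 = bandwidth_2d(pts[:, ::-1])
        assert (hx, hy) == (hx2, hy2)

    def test_bandwidth_shrinks_with_n(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=2000)
        hs = [bandwidth_1d(base[:n]) for n in (100, 500, 2000)]
        assert hs[0] > hs[1] > hs[2]

    def test_constant_data_raises_degenerate(self):
        with pytest.raises(DegenerateDataError):
            bandwidth_1d(np.full(10, 3.0))
        with pytest.raises(DegenerateDataError):
            bandwidth_2d(np.column_stack([np.full(10, 1.0), np.arange(10.0)]))


class TestKde1d:
    def test_single_point_peak(self):
        res = kde_1d(np.array([0.0]), np.array([0.0]), 1.0)
        assert res.density[0] == pytest.approx(1 / SQRT_2PI, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            n = rng.integers(2, 50)
            x = rng.uniform(0, 100, n)
            w = rng.uniform(0.1, 1.0, n)
            w /= w.sum()
            grid = np.linspace(-20, 120, 173)
            res = kde_1d(x, grid, 4.0, weights=w)
            np.testing.assert_allclose(
                res.density, brute_kde_1d(x, grid, 4.0, w), atol=1e-12
            )

    def test_matches_scipy_gaussian_kde(self):
        """Independent implementation cross-check with matched bandwidth."""
        rng = np.random.default_rng(6)
        x = rng.normal(70, 8, 40)
        h = 3.0
        grid = np.linspace(40, 100, 101)
        res = kde_1d(x, grid, h)
        ref = gaussian_kde(x, bw_method=h / x.std(ddof=1))(grid)
        np.testing.assert_allclose(res.density, ref, atol=1e-12)

    def test_symmetry_about_centre(self):
        x = np.array([60.0, 80.0])
        res = kde_1d(x, np.array([65.0, 75.0]), 2.5)
        assert res.density[0] == pytest.approx(res.density[1], abs=1e-15)

    def test_normalizes_on_wide_grid(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(50, 90, 30)
        h = bandwidth_1d(x)
        res = kde_1d(x, grid_1d(x, h, pad_bandwidths=6, num=512), h)
        assert trapezoid_integral_1d(res) == pytest.approx(1.0, abs=0.01)

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            kde_1d(np.array([1.0]), np.array([0.0]), 0.0)

    def test_h_to_zero_concentrates_at_datum(self):
        """As h shrinks with one data point, density at the point diverges
        and density elsewhere vanishes."""
        at_point, away = [], []
        for h in (1.0, 0.1, 0.01):
            res = kde_1d(np.array([5.0]), np.array([5.0, 6.0]), h)
            at_point.append(res.density[0])
            away.append(res.density[1])
        assert at_point[0] < at_point[1] < at_point[2]
        assert away[0] > away[1] > away[2]
        assert away[2] < 1e-300 or away[2] == 0.0


class TestKde2d:
    def test_single_point_peak(self):
        res = kde_2d(
            np.array([[0.0, 0.0]]), np.array([0.0]), np.array([0.0]), 1.0, 1.0
        )
        assert res.density[0, 0] == pytest.approx(
            1 / (2 * math.pi), abs=1e-12
        )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        n = 37
        pts = np.column_stack(
            [rng.uniform(0, 40, n), rng.uniform(50, 100, n)]
        )
        w = rng.uniform(0.5, 2.0, n)
        w /= w.sum()
        gx = np.linspace(0, 40, 19)
        gy = np.linspace(50, 100, 21)
        res = kde_2d(pts, gx, gy, 3.0, 4.0, weights=w)
        np.testing.assert_allclose(
            res.density, brute_kde_2d(pts, gx, gy, 3.0, 4.0, w), atol=1e-12
        )

    def test_caps_are_observed_maxima(self):
        pts = np.array([[1.0, 60.0], [7.5, 88.0], [3.0, 71.0]])
        res = kde_2d(pts, np.linspace(0, 10, 5), np.linspace(50, 95, 5), 1, 1)
        assert res.x_cap == 7.5 and res.y_cap == 88.0

    def test_normalizes_on_wide_grid(self):
        rng = np.random.default_rng(9)
        pts = np.column_stack(
            [rng.uniform(0, 20, 25), rng.uniform(55, 95, 25)]
        )
        hx, hy = bandwidth_2d(pts)
        gx = np.linspace(pts[:, 0].min() - 6 * hx, pts[:, 0].max() + 6 * hx, 301)
        gy = np.linspace(pts[:, 1].min() - 6 * hy, pts[:, 1].max() + 6 * hy, 301)
        res = kde_2d(pts, gx, gy, hx, hy)
        assert trapezoid_integral_2d(res) == pytest.approx(1.0, abs=0.01)


class TestCapAndMask:
    def _result(self):
        rng = np.random.default_rng(10)
        pts = np.column_stack(
            [rng.uniform(0, 10, 30), rng.uniform(60, 90, 30)]
        )
        gx = np.linspace(-5, 20, 64)
        gy = np.linspace(40, 110, 64)
        return kde_2d(pts, gx, gy, 1.5, 3.0)

    def test_grid_truncated_to_caps(self):
        res = cap_and_mask(self._result(), 1e-3)
        assert res.grid_x[0] >= 0 and res.grid_x[-1] <= res.x_cap
        assert res.grid_y[-1] <= res.y_cap

    def test_mask_rule(self):
        res = cap_and_mask(self._result(), 1e-2)
        thresh = 1e-2 * res.density.max()
        np.testing.assert_array_equal(res.mask, res.density < thresh)

    def test_mask_grows_with_eps(self):
        base = self._result()
        small = cap_and_mask(base, 1e-4).mask
        large = cap_and_mask(base, 1e-1).mask
        assert large.sum() >= small.sum()
        assert np.all(large[small])  # masked set grows monotonically

    def test_uniform_density_nothing_masked(self):
        # equal-density construction: symmetric single point, tiny grid
        one = kde_2d(
            np.array([[1.0, 70.0]]), np.array([0.5, 1.0]), np.array([70.0]),
            5.0, 5.0,
        )
        masked = cap_and_mask(one, 1e-3)
        assert masked.mask.sum() == 0

    def test_eps_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cap_and_mask(self._result(), 0.0)
        with pytest.raises(ValueError):
            cap_and_mask(self._result(), 1.0)


class TestModes:
    def test_bimodal_dwell_clusters_recovered(self, rel_factory):
        """Two dwell clusters at known %HRmax surface as the two dominant
        modes of the 2D density, within one bandwidth."""
        rng = np.random.default_rng(11)
        low = rng.integers(60, 65, 400)
        high = rng.integers(88, 93, 300)
        p = dwell_profile(rel_factory(np.concatenate([low, high])))
        res = kde2d_dwell(p.points)
        modes = dominant_intensity_modes(res, k=2)
        assert len(modes) == 2
        for centre in (62.0, 90.0):
            assert np.min(np.abs(modes - centre)) <= res.h_y + 2.0
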