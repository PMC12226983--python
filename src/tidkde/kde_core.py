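"""Gaussian kernel density estimation over dwell-time profiles.

The statistical heart of the toolkit.  A session's per-second %HRmax
series is first collapsed to a *dwell profile*: for each unique integer
%HRmax value, the share of total session time spent at that value.  Each
(share, %HRmax) pair is one point in the plane of %-session-time (x) vs
%HRmax (y); a 2D product-Gaussian KDE over those points yields the density
heatmap, and a 1D Gaussian KDE over %HRmax values (time-weighted) gives
the marginal intensity distribution.

Bandwidths default to normal-reference rules — Silverman's
``sigma * (4 / (3 n))**(1/5)`` in 1D and per-dimension Scott
``sigma_d * n**(-1/6)`` in 2D — both overridable.  Heatmap axes are capped
at the maximum observed value on each axis, and cells whose density falls
below a relative floor of the peak are masked (rendered white) to mark
combinations that did not occur.

No boundary correction is applied at 0 or 100 %HRmax; the Gaussian kernel
has unbounded support, a known smoothing artefact near axis limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import EmptyInputError
from .preprocessing import RelativeIntensitySeries

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Default evaluation grid resolution per axis.
DEFAULT_GRID_SIZE = 256

#: Default relative density floor below which heatmap cells are masked.
DEFAULT_EPS_REL = 1e-3


class DegenerateDataError(ValueError):
    """Raised when a normal-reference bandwidth cannot be computed
    (constant data); callers should fall back to an explicit minimum
    bandwidth."""


@dataclass(frozen=True)
class DwellProfile:
    """Share of one session's time spent at each observed integer %HRmax.

    ``seconds`` maps each observed value to its dwell seconds; ``shares``
    to its percentage of total retained session time (sums to 100).
    """

    session_id: str
    seconds: dict[int, int]
    total_seconds: int

    def __post_init__(self) -> None:
        if not self.seconds:
            raise EmptyInputError("dwell profile with no observations")
        if any(s <= 0 for s in self.seconds.values()):
            raise ValueError("dwell seconds must be positive")
        if sum(self.seconds.values()) != self.total_seconds:
            raise ValueError("dwell seconds do not sum to total")

    @property
    def shares(self) -> dict[int, float]:
        return {
            v: 100.0 * s / self.total_seconds
            for v, s in self.seconds.items()
        }

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (x = % session time share, y = %HRmax)."""
        shares = self.shares
        vs = sorted(self.seconds)
        return np.array([[shares[v], float(v)] for v in vs])

    @property
    def time_weights(self) -> np.ndarray:
        """Per-point weights proportional to dwell seconds (sum to 1).

        The unweighted dwell-point cloud gives every observed %HRmax value
        equal mass regardless of how long it was held; time weighting makes
        the density reflect where training time accumulated, which is what
        mode-recovery analyses of work/recovery levels need.
        """
        vs = sorted(self.seconds)
        w = np.array([self.seconds[v] for v in vs], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class KDE1DResult:
    """1D Gaussian KDE evaluated on an ordered grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int


@dataclass(frozen=True)
class KDE2DResult:
    """2D product-Gaussian KDE on a rectangular grid.

    ``density`` has shape ``(len(grid_y), len(grid_x))`` (row = %HRmax,
    column = % session time).  ``x_cap``/``y_cap`` are the maximum observed
    values on each axis; ``mask`` (after :func:`cap_and_mask`) marks cells
    whose density is below ``eps_rel`` times the peak.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray
    h_x: float
    h_y: float
    x_cap: float
    y_cap: float
    n_points: int
    mask: np.ndarray | None = None
    eps_rel: float | None = None


# ---------------------------------------------------------------------------
# Dwell profiles and pooling


def dwell_profile(rel: RelativeIntensitySeries) -> DwellProfile:
    """Collapse a per-second %HRmax series to its dwell-time profile."""
    values, counts = np.unique(rel.values, return_counts=True)
    return DwellProfile(
        session_id=rel.session_id,
        seconds={int(v): int(c) for v, c in zip(values, counts)},
        total_seconds=rel.n_seconds,
    )


def pool_points(
    profiles: list[DwellProfile], weighting: str = "none"
) -> tuple[np.ndarray, np.ndarray]:
    """Pool dwell points from several sessions for a group-level KDE.

    ``weighting="none"`` concatenates all (share, %HRmax) points with
    uniform weights — the straightforward pooling in which sessions
    contributing more distinct intensity values carry more weight.
    ``weighting="per_session"`` normalises each session to total weight 1,
    countering that imbalance.  Returns ``(points, weights)`` with
    ``points`` of shape (n, 2) and weights summing to 1.
    """
    if not profiles:
        raise EmptyInputError("no dwell profiles to pool")
    if weighting not in ("none", "per_session"):
        raise ValueError(f"unknown weighting {weighting!r}")
    chunks = [p.points for p in profiles]
    points = np.vstack(chunks)
    if weighting == "none":
        weights = np.full(len(points), 1.0 / len(points))
    else:
        parts = [
            np.full(len(c), 1.0 / (len(profiles) * len(c))) for c in chunks
        ]
        weights = np.concatenate(parts)
    return points, weights


# ---------------------------------------------------------------------------
# Bandwidth selection


def bandwidth_1d(values: np.ndarray) -> float:
    """Silverman's normal-reference bandwidth ``sigma * (4/(3n))**(1/5)``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for bandwidth selection")
    sigma = float(np.std(values, ddof=1))
    if sigma == 0.0:
        raise DegenerateDataError(
            "sample standard deviation is zero; supply an explicit "
            "fallback bandwidth h_min"
        )
    return sigma * (4.0 / (3.0 * n)) ** 0.2


def bandwidth_2d(points: np.ndarray) -> tuple[float, float]:
    """Per-dimension Scott bandwidths ``sigma_d * n**(-1/6)`` for d=2."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points for bandwidth selection")
    factor = n ** (-1.0 / 6.0)
    hs = []
    for d in range(2):
        sigma = float(np.std(points[:, d], ddof=1))
        if sigma == 0.0:
            raise DegenerateDataError(
                f"marginal standard deviation in dimension {d} is zero; "
                "supply an explicit fallback bandwidth"
            )
        hs.append(sigma * factor)
    return hs[0], hs[1]


# ---------------------------------------------------------------------------
# Density evaluation


def _normalise_weights(n: int, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError("weights must match the number of data points")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not sum to zero")
    return weights / total


def kde_1d(
    values: np.ndarray,
    grid: np.ndarray,
    h: float,
    weights: np.ndarray | None = None,
) -> KDE1DResult:
    """Weighted Gaussian KDE: ``f(g) = sum_i w_i phi((g - x_i)/h) / h``."""
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("evaluation grid must be ordered")
    w = _normalise_weights(values.size, weights)
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z * z) @ w / (h * _SQRT_2PI)
    return KDE1DResult(
        grid=grid, density=density, bandwidth=float(h), n=values.size
    )


def kde_2d(
    points: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    h_x: float,
    h_y: float,
    weights: np.ndarray | None = None,
) -> KDE2DResult:
    """Product-Gaussian KDE:
    ``f(gx, gy) = sum_i w_i phi((gx-x_i)/h_x) phi((gy-y_i)/h_y) / (h_x h_y)``.

    The density matrix has shape ``(len(grid_y), len(grid_x))``.  Axis caps
    are set to the maximum observed coordinate on each axis; masking is
    applied separately by :func:`cap_and_mask`.
    """
    if h_x <= 0 or h_y <= 0:
        raise ValueError("bandwidths must be positive")
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    w = _normalise_weights(len(points), weights)
    zx = (grid_x[:, None] - points[None, :, 0]) / h_x
    zy = (grid_y[:, None] - points[None, :, 1]) / h_y
    kx = np.exp(-0.5 * zx * zx) / (h_x * _SQRT_2PI)  # (nx, n)
    ky = np.exp(-0.5 * zy * zy) / (h_y * _SQRT_2PI)  # (ny, n)
    density = ky @ (w[:, None] * kx.T)  # (ny, nx)
    return KDE2DResult(
        grid_x=grid_x,
        grid_y=grid_y,
        density=density,
        h_x=float(h_x),
        h_y=float(h_y),
        x_cap=float(points[:, 0].max()),
        y_cap=float(points[:, 1].max()),
        n_points=len(points),
    )


def cap_and_mask(
    result: KDE2DResult, eps_rel: float = DEFAULT_EPS_REL
) -> KDE2DResult:
    """Truncate the grid at the observed axis caps and mask low density.

    The grid is restricted to ``[0, x_cap] x [y_floor, y_cap]`` (``y_floor``
    being the lowest grid ordinate already present) and cells with density
    below ``eps_rel`` times the truncated peak are flagged in the mask —
    these render white, marking combinations that did not occur.
    """
    if not (0.0 < eps_rel < 1.0):
        raise ValueError("eps_rel must lie in (0, 1)")
    keep_x = (result.grid_x >= 0.0) & (result.grid_x <= result.x_cap)
    keep_y = result.grid_y <= result.y_cap
    grid_x = result.grid_x[keep_x]
    grid_y = result.grid_y[keep_y]
    density = result.density[np.ix_(keep_y, keep_x)]
    peak = density.max()
    mask = density < eps_rel * peak
    return KDE2DResult(
        grid_x=grid_x,
        grid_y=grid_y,
        density=density,
        h_x=result.h_x,
        h_y=result.h_y,
        x_cap=result.x_cap,
        y_cap=result.y_cap,
        n_points=result.n_points,
        mask=mask,
        eps_rel=float(eps_rel),
    )


# ---------------------------------------------------------------------------
# Convenience pipelines


def grid_1d(
    values: np.ndarray,
    h: float,
    pad_bandwidths: float = 5.0,
    num: int = DEFAULT_GRID_SIZE,
) -> np.ndarray:
    """Uniform grid spanning the data range plus ``pad_bandwidths * h``."""
    values = np.asarray(values, dtype=float)
    lo = values.min() - pad_bandwidths * h
    hi = values.max() + pad_bandwidths * h
    return np.linspace(lo, hi, num)


def kde2d_dwell(
    points: np.ndarray,
    weights: np.ndarray | None = None,
    h_x: float | None = None,
    h_y: float | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    eps_rel: float = DEFAULT_EPS_REL,
) -> KDE2DResult:
    """Full heatmap pipeline for pooled dwell points.

    Selects Scott bandwidths unless overridden, evaluates on a
    ``grid_size x grid_size`` grid over ``[0, x_cap] x [y_floor, y_cap]``
    with ``y_floor = max(0, min observed %HRmax - 2 h_y)``, then applies
    the low-density mask.
    """
    points = np.asarray(points, dtype=float)
    if h_x is None or h_y is None:
        sx, sy = bandwidth_2d(points)
        h_x = h_x if h_x is not None else sx
        h_y = h_y if h_y is not None else sy
    x_cap = float(points[:, 0].max())
    y_cap = float(points[:, 1].max())
    y_floor = max(0.0, float(points[:, 1].min()) - 2.0 * h_y)
    grid_x = np.linspace(0.0, x_cap, grid_size)
    grid_y = np.linspace(y_floor, y_cap, grid_size)
    result = kde_2d(points, grid_x, grid_y, h_x, h_y, weights=weights)
    return cap_and_mask(result, eps_rel=eps_rel)


def dominant_intensity_modes(result: KDE2DResult, k: int = 2) -> np.ndarray:
    """The %HRmax positions of the ``k`` strongest local maxima of the
    density profile along the intensity axis (profile = max over the
    session-time axis).  Used to check that work/recovery clusters of an
    interval session surface as separate modes."""
    profile = result.density.max(axis=1)
    interior = np.arange(1, profile.size - 1)
    is_max = (profile[interior] >= profile[interior - 1]) & (
        profile[interior] >= profile[interior + 1]
    )
    idx = interior[is_max]
    if profile[0] > profile[1]:
        idx = np.append(idx, 0)
    if profile[-1] > profile[-2]:
        idx = np.append(idx, profile.size - 1)
    order = idx[np.argsort(profile[idx])[::-1]]
    # Greedy selection with a minimum separation of one bandwidth, so a
    # flat or noisy plateau cannot claim more than one mode.
    chosen: list[float] = []
    for i in order:
        y = float(result.grid_y[i])
        if all(abs(y - c) >= result.h_y for c in chosen):
            chosen.append(y)
        if len(chosen) == k:
            break
    return np.array(chosen)


def trapezoid_integral_1d(result: KDE1DResult) -> float:
    """Trapezoidal integral of a 1D density over its grid."""
    return float(np.trapezoid(result.density, result.grid))


def trapezoid_integral_2d(result: KDE2DResult) -> float:
    """Trapezoidal double integral of a 2D density over its grid."""
    inner = np.trapezoid(result.density, result.grid_x, axis=1)
    return float(np.trapezoid(inner, result.grid_y))
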