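"""Figure rendering: KDE heatmaps, histogram+KDE overlays, TIZ bar charts.

Rendering is pure presentation — every number drawn here is recomputable
from the exported KDE matrices and TIZ tables; no statistics are computed
in this module beyond axis bookkeeping and the aggregation of comparison
tables into bar heights.

Heatmaps use a perceptually ordered warm-to-cool colormap with white
reserved for masked (did-not-occur) cells, dashed horizontal lines at the
configured zone lower bounds, and axes ending at the observed caps.  Under
the ``paper`` axis-label policy the x-axis tick numbers are suppressed, the
convention for proportional-time axes whose limits differ between panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .kde_core import KDE1DResult, KDE2DResult, kde_1d  # noqa: E402
from .zones_tiz import DEFAULT_ZONE_MODEL, ZoneModel  # noqa: E402

#: Histogram bin width in %HRmax for the 1D marginal panels.
HIST_BIN_WIDTH = 10.0


@dataclass(frozen=True)
class FigureSpec:
    """Presentation options shared by all panels of one figure set."""

    level: str = "individual"  # individual | session_type | programme
    colormap: str = "turbo"
    axis_label_policy: str = "paper"  # "paper" hides x tick numbers on heatmaps
    dpi: int = 300
    formats: tuple[str, ...] = ("png", "svg")
    title: str | None = None
    zone_model: ZoneModel = field(default=DEFAULT_ZONE_MODEL)


def _save(fig, out_base: str | Path, spec: FigureSpec) -> list[Path]:
    paths = []
    for fmt in spec.formats:
        p = Path(f"{out_base}.{fmt}")
        fig.savefig(p, dpi=spec.dpi, bbox_inches="tight")
        paths.append(p)
    return paths


def plot_kde2d(
    result: KDE2DResult,
    model: ZoneModel | None = None,
    spec: FigureSpec = FigureSpec(),
    out_base: str | Path | None = None,
    ax=None,
):
    """Render a capped-and-masked 2D KDE heatmap.

    Masked cells are white; dashed horizontal lines mark every zone lower
    bound within the y-range; axes end at the observed caps.
    """
    if result.mask is None:
        raise ValueError("result must be capped and masked before plotting")
    model = model or spec.zone_model
    fig = None
    if ax is None:
        fig, ax = plt.subplots(figsize=(4.2, 3.6))
    else:
        fig = ax.get_figure()
    cmap = plt.get_cmap(spec.colormap).copy()
    cmap.set_bad("white")
    data = np.ma.masked_where(result.mask, result.density)
    ax.pcolormesh(
        result.grid_x, result.grid_y, data, cmap=cmap, shading="auto",
        rasterized=True,
    )
    for bound in model.lower_bounds:
        if result.grid_y[0] <= bound <= result.grid_y[-1]:
            ax.axhline(bound, color="black", linestyle="--", linewidth=0.8)
    ax.set_xlim(result.grid_x[0], result.grid_x[-1])
    ax.set_ylim(result.grid_y[0], result.grid_y[-1])
    ax.set_xlabel("Session time (%)")
    ax.set_ylabel("%HRmax")
    if spec.axis_label_policy == "paper":
        ax.tick_params(axis="x", labelbottom=False)
    if spec.title:
        ax.set_title(spec.title)
    paths = _save(fig, out_base, spec) if out_base else []
    return fig, paths


def plot_hist_kde1d(
    values: np.ndarray,
    seconds: np.ndarray | None = None,
    model: ZoneModel | None = None,
    spec: FigureSpec = FigureSpec(),
    bandwidth: float | None = None,
    out_base: str | Path | None = None,
    ax=None,
):
    """Histogram of accumulated time per %HRmax bin with a 1D KDE overlay.

    ``values`` are %HRmax levels and ``seconds`` the dwell time at each
    (defaults to 1 s per value, i.e. a raw per-second series).  Bars show
    minutes per 10-%HRmax bin; the KDE density is rescaled by
    (total time x bin width) so curve and bars share units.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to plot")
    if seconds is None:
        seconds = np.ones_like(values)
    seconds = np.asarray(seconds, dtype=float)
    model = model or spec.zone_model
    fig = None
    if ax is None:
        fig, ax = plt.subplots(figsize=(4.2, 3.0))
    else:
        fig = ax.get_figure()
    lo = np.floor(values.min() / HIST_BIN_WIDTH) * HIST_BIN_WIDTH
    hi = np.ceil((values.max() + 1e-9) / HIST_BIN_WIDTH) * HIST_BIN_WIDTH
    bins = np.arange(lo, hi + HIST_BIN_WIDTH, HIST_BIN_WIDTH)
    total_min = seconds.sum() / 60.0
    ax.hist(
        values,
        bins=bins,
        weights=seconds / 60.0,
        color="#9ecae1",
        edgecolor="white",
    )
    if bandwidth is None:
        from .kde_core import bandwidth_1d

        bandwidth = bandwidth_1d(np.repeat(values, seconds.astype(int)))
    grid = np.linspace(lo - 5 * bandwidth, hi + 5 * bandwidth, 512)
    kde = kde_1d(values, grid, bandwidth, weights=seconds / seconds.sum())
    ax.plot(
        kde.grid,
        kde.density * total_min * HIST_BIN_WIDTH,
        color="#d7301f",
        linewidth=1.5,
    )
    ax.set_xlabel("%HRmax")
    ax.set_ylabel("Time (min)")
    if spec.title:
        ax.set_title(spec.title)
    paths = _save(fig, out_base, spec) if out_base else []
    return fig, paths, kde


def plot_tiz_bars(
    comparisons: list[pd.DataFrame],
    spec: FigureSpec = FigureSpec(),
    out_base: str | Path | None = None,
    ax=None,
):
    """Grouped planned (blue) vs performed (red) TIZ bars per zone.

    When several sessions are aggregated, bar heights are means and error
    bars show the standard deviation across sessions.
    """
    if not comparisons:
        raise ValueError("need at least one comparison table")
    zones = list(comparisons[0]["zone"])
    planned = np.array([df["planned_min"].to_numpy() for df in comparisons])
    performed = np.array(
        [df["performed_min"].to_numpy() for df in comparisons]
    )
    fig = None
    if ax is None:
        fig, ax = plt.subplots(figsize=(4.2, 3.0))
    else:
        fig = ax.get_figure()
    x = np.arange(len(zones))
    width = 0.38
    n = len(comparisons)
    p_err = planned.std(axis=0, ddof=0) if n > 1 else None
    q_err = performed.std(axis=0, ddof=0) if n > 1 else None
    ax.bar(
        x - width / 2,
        planned.mean(axis=0),
        width,
        yerr=p_err,
        capsize=2,
        color="#2171b5",
        label="Planned",
    )
    ax.bar(
        x + width / 2,
        performed.mean(axis=0),
        width,
        yerr=q_err,
        capsize=2,
        color="#cb181d",
        label="Performed",
    )
    ax.set_xticks(x, zones)
    ax.set_ylabel("Time (min)")
    ax.legend(frameon=False, fontsize=8)
    if spec.title:
        ax.set_title(spec.title)
    paths = _save(fig, out_base, spec) if out_base else []
    return fig, paths


def plot_session_panel(
    kde2d: KDE2DResult,
    values: np.ndarray,
    seconds: np.ndarray,
    comparisons: list[pd.DataFrame],
    spec: FigureSpec = FigureSpec(),
    out_base: str | Path | None = None,
):
    """Three-row composite: heatmap on top, histogram+KDE in the middle,
    planned-vs-performed bars at the bottom."""
    fig, axes = plt.subplots(3, 1, figsize=(4.6, 9.5))
    plot_kde2d(kde2d, spec=spec, ax=axes[0])
    plot_hist_kde1d(values, seconds, spec=spec, ax=axes[1])
    plot_tiz_bars(comparisons, spec=spec, ax=axes[2])
    fig.tight_layout()
    paths = _save(fig, out_base, spec) if out_base else []
    return fig, paths
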