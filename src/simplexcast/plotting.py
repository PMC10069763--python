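"""Static four-panel dashboard rendering.

Panels: (a) the chronological series with the forecast origin, weight-
shaded neighbor markers, the gradient forecast area and an optional
dashed point-forecast line; (b) the offset view overlaying the query
vector with every neighbor's embedded vector and future on a common
relative-time axis; (c) the phase-space scatter with neighbors
highlighted; (d) the neighbor-distance bar chart with a dashed line at
the historical mean neighbor distance.

All quantitative content is assembled first into :class:`DashboardData`
(testable without rendering); rendering is a thin matplotlib layer over
it.  Interactivity of the original dashboard concept (time slider,
right-click disabling) maps onto the ``current_t`` argument and
``set_neighbor_enabled``.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # headless-safe; selected before pyplot import
import matplotlib.pyplot as plt
import numpy as np

from .density import DensityGrid
from .embedding import phase_space_coords
from .forecast import PointForecast
from .neighbors import NeighborSet, mean_distance_history
from .params import Hyperparameters
from .series import TimeSeries

__all__ = ["PlotStyle", "DashboardData", "build_dashboard_data", "render_dashboard"]


@dataclass(frozen=True)
class PlotStyle:
    """Visual options for the dashboard.

    Neighbor markers use a monotone red scale (darker = larger weight);
    the forecast area uses a monotone purple scale mapped from opacity.
    """

    neighbor_colormap: str = "Reds"
    forecast_colormap: str = "Purples"
    show_point_forecast: bool = True
    figsize: tuple[float, float] = (12.0, 9.0)
    dpi: int = 100


@dataclass(frozen=True)
class DashboardData:
    """Exact data arrays handed to the renderer for each panel."""

    origin_t: int
    series_values: np.ndarray
    # panel a: one (t_i, y_{t_i}, w_i, d_i) row per enabled neighbor
    neighbor_markers: np.ndarray
    forecast_steps: list[DensityGrid]
    point_forecast: np.ndarray | None
    # panel b: offsets k = -E+1..tp; query values for k <= 0; per-neighbor
    # rows over the full offset range
    offsets: np.ndarray
    query_trace: np.ndarray
    neighbor_traces: dict[int, np.ndarray]
    # panel c
    phase_points: np.ndarray
    phase_lag: int
    neighbor_phase_points: np.ndarray
    # panel d
    bar_t: np.ndarray
    bar_d: np.ndarray
    mean_distance: float


def build_dashboard_data(
    series: TimeSeries,
    ns: NeighborSet,
    pf: PointForecast | None,
    grids: list[DensityGrid],
    hp: Hyperparameters,
) -> DashboardData:
    """Assemble panel data, validating that all inputs share one run."""
    origin = ns.query.t
    if pf is not None and pf.origin_t != origin:
        raise ValueError(
            f"point forecast origin {pf.origin_t} != neighbor-set origin {origin}"
        )
    if len(grids) != hp.tp:
        raise ValueError(f"expected {hp.tp} density grids, got {len(grids)}")
    if ns.query.E != hp.E:
        raise ValueError("query vector dimension inconsistent with hyperparameters")

    enabled = ns.enabled_neighbors
    if any(nb.w_i is None for nb in enabled):
        raise ValueError("weights not computed")
    markers = np.array(
        [[nb.t_i, series.value_at(nb.t_i), nb.w_i, nb.d_i] for nb in enabled]
    ).reshape(-1, 4)

    offsets = np.arange(-hp.E + 1, hp.tp + 1)
    query_trace = np.array(
        [series.value_at(origin + k) for k in range(-hp.E + 1, 1)]
    )
    traces = {
        nb.t_i: np.array([series.value_at(nb.t_i + k) for k in offsets])
        for nb in enabled
    }

    phase = phase_space_coords(series, hp.phase_lag)
    nb_phase = np.array(
        [
            [series.value_at(nb.t_i - hp.phase_lag), series.value_at(nb.t_i)]
            for nb in enabled
            if nb.t_i > hp.phase_lag
        ]
    ).reshape(-1, 2)

    return DashboardData(
        origin_t=origin,
        series_values=series.values,
        neighbor_markers=markers,
        forecast_steps=grids,
        point_forecast=None if pf is None else pf.values,
        offsets=offsets,
        query_trace=query_trace,
        neighbor_traces=traces,
        phase_points=phase,
        phase_lag=hp.phase_lag,
        neighbor_phase_points=nb_phase,
        bar_t=markers[:, 0].astype(int),
        bar_d=markers[:, 3],
        mean_distance=mean_distance_history(series, hp, origin),
    )


def _draw_gradient(ax, x0: float, grids: list[DensityGrid], cmap) -> None:
    for dg in grids:
        col = dg.opacity[::-1][:, None]  # imshow draws top-down
        ax.imshow(
            col,
            extent=(x0 + dg.step_r - 0.5, x0 + dg.step_r + 0.5,
                    dg.grid_v[0], dg.grid_v[-1]),
            cmap=cmap,
            vmin=0.0,
            vmax=1.0,
            aspect="auto",
            interpolation="bilinear",
            zorder=0,
        )


def render_dashboard(
    series: TimeSeries,
    ns: NeighborSet,
    pf: PointForecast | None,
    grids: list[DensityGrid],
    hp: Hyperparameters,
    path: str,
    style: PlotStyle | None = None,
) -> DashboardData:
    """Render the four-panel dashboard to ``path`` (PNG/SVG by extension).

    Returns the :class:`DashboardData` actually drawn.
    """
    style = style or PlotStyle()
    data = build_dashboard_data(series, ns, pf, grids, hp)
    ncmap = plt.get_cmap(style.neighbor_colormap)
    fcmap = plt.get_cmap(style.forecast_colormap)

    fig, axes = plt.subplots(2, 2, figsize=style.figsize, dpi=style.dpi)
    ax_a, ax_b, ax_c, ax_d = axes.ravel()

    # (a) chronological series
    t_axis = np.arange(1, data.series_values.size + 1)
    ax_a.plot(t_axis, data.series_values, color="0.4", lw=0.8, zorder=1)
    if data.neighbor_markers.size:
        # offset the ramp so even low weights remain visible; ordering preserved
        colors = ncmap(0.3 + 0.7 * data.neighbor_markers[:, 2])
        ax_a.scatter(
            data.neighbor_markers[:, 0], data.neighbor_markers[:, 1],
            c=colors, zorder=3, s=30,
        )
    ax_a.scatter(
        [data.origin_t], [series.value_at(data.origin_t)],
        color="tab:blue", marker="o", s=60, zorder=4, label="current",
    )
    _draw_gradient(ax_a, data.origin_t, data.forecast_steps, fcmap)
    if style.show_point_forecast and data.point_forecast is not None:
        ax_a.plot(
            data.origin_t + np.arange(1, hp.tp + 1), data.point_forecast,
            "--", color="purple", zorder=3,
        )
    ax_a.set_title("series, neighbors and forecast area")
    ax_a.set_xlabel("t")

    # (b) offset view
    for t_i, trace in data.neighbor_traces.items():
        w = ns.neighbor_by_t(t_i).w_i
        ax_b.plot(data.offsets, trace, color=ncmap(0.3 + 0.7 * w), lw=1)
    ax_b.plot(
        data.offsets[: hp.E], data.query_trace, color="tab:blue", lw=2,
        label="query",
    )
    _draw_gradient(ax_b, 0.0, data.forecast_steps, fcmap)
    if style.show_point_forecast and data.point_forecast is not None:
        ax_b.plot(np.arange(1, hp.tp + 1), data.point_forecast, "--", color="purple")
    ax_b.axvline(0, color="0.8", lw=0.5)
    ax_b.set_title("neighbors, offset-aligned")
    ax_b.set_xlabel("offset from origin")

    # (c) phase space
    ax_c.plot(
        data.phase_points[:, 0], data.phase_points[:, 1],
        color="0.7", lw=0.5, zorder=1,
    )
    if data.neighbor_phase_points.size:
        ax_c.scatter(
            data.neighbor_phase_points[:, 0], data.neighbor_phase_points[:, 1],
            color="tab:red", zorder=3, s=25,
        )
    ax_c.set_title(f"phase space (lag {data.phase_lag})")
    ax_c.set_xlabel(f"y(t-{data.phase_lag})")
    ax_c.set_ylabel("y(t)")

    # (d) distance bars
    if data.bar_t.size:
        order = np.argsort(data.bar_d)
        labels = [str(t) for t in data.bar_t[order]]
        ax_d.bar(labels, data.bar_d[order], color="tab:red")
    ax_d.axhline(data.mean_distance, ls="--", color="0.3")
    ax_d.set_title("neighbor distances (dashed: historical mean)")
    ax_d.set_xlabel("neighbor t")
    ax_d.set_ylabel("euclidean distance")

    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return data
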