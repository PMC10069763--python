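"""Simplex point forecasting: normalized weighted mean of neighbor futures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neighbors import NeighborSet

__all__ = ["PointForecast", "simplex_point_forecast"]


@dataclass(frozen=True)
class PointForecast:
    """Point forecasts for steps origin_t+1 .. origin_t+tp."""

    origin_t: int
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def tp(self) -> int:
        return int(self.values.size)


def simplex_point_forecast(ns: NeighborSet, tp: int) -> PointForecast:
    """Weighted average of the enabled neighbors' future vectors.

    forecast_r = sum_i w_i * z_{i,r} / sum_i w_i over enabled neighbors,
    for each horizon step r = 1..tp.  Being a convex combination, each
    forecast value lies within the range of the neighbors' values at that
    step.
    """
    enabled = ns.enabled_neighbors
    if not enabled:
        raise ValueError("all neighbors disabled")
    if any(nb.w_i is None for nb in enabled):
        raise ValueError("weights not computed; call compute_weights first")
    futures = np.stack([nb.z_i[:tp] for nb in enabled])
    if futures.shape[1] < tp:
        raise ValueError(
            f"neighbor futures shorter than requested horizon tp={tp}"
        )
    w = np.array([nb.w_i for nb in enabled])
    # anchored form of the weighted mean: exact when neighbor values coincide
    base = futures[0]
    values = base + (w @ (futures - base)) / w.sum()
    return PointForecast(origin_t=ns.query.t, values=values)
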