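"""Nearest-dynamic-neighbor search and exponential distance weighting.

A dynamic neighbor is a past delay vector close (in Euclidean distance) to
the query vector at the forecast origin.  Each neighbor carries the tp
observations that immediately followed it — its "future vector" — which is
the raw material for both the simplex point forecast and the shaded
forecast area.

Eligibility is lookahead-safe: a candidate at time t_i requires
t_i + tp <= current_t, so every neighbor's future is fully observed before
the forecast origin.  No further temporal exclusion window is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .embedding import DelayVector, delay_vector_at
from .params import Hyperparameters
from .series import TimeSeries

__all__ = [
    "Neighbor",
    "NeighborSet",
    "find_neighbors",
    "compute_weights",
    "set_neighbor_enabled",
    "mean_distance_history",
]

logger = logging.getLogger(__name__)


@dataclass
class Neighbor:
    """A single dynamic neighbor of the query vector.

    Attributes
    ----------
    t_i : int
        1-based time index of the neighbor's delay vector.
    x_i : DelayVector
        The neighbor's delay vector.
    d_i : float
        Euclidean distance to the query vector.
    z_i : ndarray
        Future vector [y_{t_i+1}, ..., y_{t_i+tp}].
    w_i : float or None
        Weight exp(-theta * d_i / d_bar); None until weights are computed
        or while the neighbor is disabled.
    enabled : bool
        Disabled neighbors are excluded from d_bar, weights, forecasts and
        the shaded area.
    """

    t_i: int
    x_i: DelayVector
    d_i: float
    z_i: np.ndarray
    w_i: float | None = None
    enabled: bool = True


@dataclass
class NeighborSet:
    """The n nearest dynamic neighbors of a query vector, sorted by distance.

    ``d_bar`` is the mean distance over *enabled* neighbors and is kept in
    sync whenever the enabled set changes.  ``theta`` records the weighting
    exponent last used so that toggling a neighbor re-derives consistent
    weights.
    """

    query: DelayVector
    neighbors: list[Neighbor]
    theta: float | None = None

    @property
    def d_bar(self) -> float:
        d = [nb.d_i for nb in self.neighbors if nb.enabled]
        return float(np.mean(d)) if d else 0.0

    @property
    def enabled_neighbors(self) -> list[Neighbor]:
        return [nb for nb in self.neighbors if nb.enabled]

    def neighbor_by_t(self, t_i: int) -> Neighbor:
        for nb in self.neighbors:
            if nb.t_i == t_i:
                return nb
        raise KeyError(f"no neighbor with t_i={t_i}")


def find_neighbors(
    series: TimeSeries, hp: Hyperparameters, current_t: int
) -> NeighborSet:
    """Find the n nearest eligible delay vectors to the one at ``current_t``.

    Candidates are delay vectors at times t_i with E <= t_i,
    t_i != current_t and t_i + tp <= current_t (complete, lookahead-free
    futures).  Ties in distance are broken by earlier t_i.  If fewer than n
    candidates exist, all are returned with a logged warning.
    """
    if current_t < hp.E:
        raise ValueError(
            f"insufficient history for E/tp at current_t: need current_t >= E={hp.E}"
        )
    query = delay_vector_at(series, current_t, hp.E)

    t_max = min(current_t - hp.tp, series.T)
    cand_t = [t for t in range(hp.E, t_max + 1) if t != current_t]
    if not cand_t:
        raise ValueError(
            f"insufficient history for E/tp at current_t={current_t} "
            f"(E={hp.E}, tp={hp.tp})"
        )

    vals = series.values
    # vectorized distance over the candidate block
    cand_arr = np.array([t for t in cand_t])
    coords = np.stack([vals[t - hp.E : t] for t in cand_t])
    dists = np.linalg.norm(coords - query.coords, axis=1)

    order = np.lexsort((cand_arr, dists))  # distance ascending, then t_i
    chosen = order[: hp.n]
    if len(cand_t) < hp.n:
        logger.warning(
            "only %d eligible neighbors available (requested n=%d) at t=%d",
            len(cand_t), hp.n, current_t,
        )

    neighbors = []
    for idx in chosen:
        t_i = int(cand_arr[idx])
        neighbors.append(
            Neighbor(
                t_i=t_i,
                x_i=DelayVector(t=t_i, coords=coords[idx]),
                d_i=float(dists[idx]),
                z_i=vals[t_i : t_i + hp.tp].copy(),
            )
        )
    return NeighborSet(query=query, neighbors=neighbors)


def compute_weights(ns: NeighborSet, theta: float) -> NeighborSet:
    """Assign w_i = exp(-theta * d_i / d_bar) to each enabled neighbor.

    d_bar is the mean distance over enabled neighbors only.  When d_bar is
    zero (every enabled neighbor is an exact repeat of the query) all
    enabled weights are 1, the limit of equal distances.  Disabled
    neighbors carry no weight.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    ns.theta = float(theta)
    d_bar = ns.d_bar
    for nb in ns.neighbors:
        if not nb.enabled:
            nb.w_i = None
        elif theta == 0 or d_bar == 0:
            nb.w_i = 1.0
        else:
            nb.w_i = math.exp(-theta * nb.d_i / d_bar)
    return ns


def set_neighbor_enabled(ns: NeighborSet, t_i: int, enabled: bool) -> NeighborSet:
    """Enable or disable the neighbor at time t_i.

    Disabling removes the neighbor from d_bar, the point forecast and the
    shaded area; weights of the remaining enabled neighbors are recomputed
    over the new enabled subset.
    """
    nb = ns.neighbor_by_t(t_i)
    nb.enabled = bool(enabled)
    if ns.theta is not None:
        compute_weights(ns, ns.theta)
    return ns


def mean_distance_history(
    series: TimeSeries, hp: Hyperparameters, current_t: int
) -> float:
    """Mean over prior origins of the mean neighbor distance.

    For each eligible origin t' < current_t the neighbor search is re-run
    and its mean distance d_bar(t') recorded; the returned value is the
    mean of those means — the dashed reference line on the distance bar
    plot.
    """
    first = hp.E + hp.tp  # earliest origin with at least one candidate
    origins = range(first, current_t)
    d_bars = []
    for t in origins:
        ns = find_neighbors(series, hp, t)
        d_bars.append(ns.d_bar)
    if not d_bars:
        raise ValueError(
            f"no eligible prior origin before t={current_t} (E={hp.E}, tp={hp.tp})"
        )
    return float(np.mean(d_bars))
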