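"""Time-delay embedding and phase-space coordinates.

The delay vector at time t collects the E most recent observations
[y_{t-E+1}, ..., y_t]; the set of such vectors is the reconstructed state
space in which dynamic neighbors are sought.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import TimeSeries

__all__ = ["DelayVector", "delay_embed", "euclidean_distance", "phase_space_coords"]


@dataclass(frozen=True)
class DelayVector:
    """A point in the reconstructed state space.

    ``t`` is the 1-based ordinal index of the vector's most recent value;
    ``coords`` holds [y_{t-E+1}, ..., y_t].
    """

    t: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))

    @property
    def E(self) -> int:
        return int(self.coords.size)


def delay_embed(series: TimeSeries, E: int) -> list[DelayVector]:
    """Embed the series with dimension E.

    Returns T - E + 1 vectors; the vector indexed by its most recent time t
    exists for t = E..T.
    """
    if E < 1:
        raise ValueError("E must be >= 1")
    if series.T < E:
        raise ValueError(
            f"series too short to embed: T={series.T} < E={E}"
        )
    vals = series.values
    return [
        DelayVector(t=t, coords=vals[t - E : t]) for t in range(E, series.T + 1)
    ]


def delay_vector_at(series: TimeSeries, t: int, E: int) -> DelayVector:
    """The single delay vector whose most recent value is y_t."""
    if t < E:
        raise ValueError(f"no delay vector at t={t} for E={E}")
    if t > series.T:
        raise IndexError(f"t={t} beyond series end T={series.T}")
    return DelayVector(t=t, coords=series.values[t - E : t])


def euclidean_distance(a: DelayVector, b: DelayVector) -> float:
    """L2 distance between two delay vectors of equal dimension."""
    if a.E != b.E:
        raise ValueError(f"dimension mismatch: {a.E} != {b.E}")
    return float(np.linalg.norm(a.coords - b.coords))


def phase_space_coords(series: TimeSeries, phase_lag: int = 1) -> np.ndarray:
    """Lagged coordinate pairs (y_{t-lag}, y_t) for t = lag+1..T.

    Returned as an array of shape (T - lag, 2), ordered by t.  Cycles in the
    data appear as closed loops; a regime shift populates a new region.
    """
    if phase_lag < 1:
        raise ValueError("phase_lag must be >= 1")
    if series.T <= phase_lag:
        raise ValueError(
            f"series too short for phase-space view: T={series.T} <= lag={phase_lag}"
        )
    v = series.values
    return np.column_stack([v[:-phase_lag], v[phase_lag:]])
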