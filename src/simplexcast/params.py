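"""Hyperparameters for simplex forecasting and the shaded forecast area."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Hyperparameters"]


@dataclass(frozen=True)
class Hyperparameters:
    """Forecasting hyperparameters.

    Attributes
    ----------
    E : int
        Embedding dimension: number of values per delay vector (>= 1).
    n : int
        Number of nearest dynamic neighbors (>= 1).
    tp : int
        Forecast horizon in steps (>= 1).
    theta : float
        Weighting exponent; 0 gives equal weights of 1 for all neighbors.
    kw : float
        Relative kernel width multiplier; the kernel width in data units is
        alpha = sigma_ref * kw where sigma_ref is the series sd.
    c : float
        Kernel edge density: the kernel width alpha is the interval over
        which the standardized Gaussian stays above density c.
    grid_points : int
        Resolution of each horizon step's density grid.
    phase_lag : int
        Lag used by the phase-space view.
    alpha : float, optional
        Explicit kernel width in data units, overriding sigma_ref * kw.
    """

    E: int = 5
    n: int = 10
    tp: int = 8
    theta: float = 1.0
    kw: float = 1.0
    c: float = 0.0001
    grid_points: int = 256
    phase_lag: int = 1
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.E < 1:
            raise ValueError("E must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.tp < 1:
            raise ValueError("tp must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.kw <= 0:
            raise ValueError("kw must be > 0")
        if not 0 < self.c < 0.3989:  # upper bound f(0) of the standard normal
            raise ValueError("c must lie in (0, f(0))")
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")
        if self.phase_lag < 1:
            raise ValueError("phase_lag must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha override must be > 0")
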