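"""Synthetic series generators used as fixtures and exemplars.

``gen_seasonal`` emulates weekly all-cause mortality counts: a baseline
with annual winter peaks whose heights vary from cycle to cycle, a mild
upward trend, observation noise, and an optional sustained level shift
emulating a pandemic-style regime change that carries the dynamics into a
previously unpopulated region of phase space.  ``gen_logistic_map``
provides a canonical deterministic nonlinear system for skill checks.

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import TimeSeries

__all__ = ["SyntheticSpec", "gen_seasonal", "gen_logistic_map"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the seasonal (mortality-like) generator.

    Defaults describe a weekly series spanning nine years: baseline about
    55,000 deaths/week, winter peaks about 4,000 above baseline with
    ±15% cycle-to-cycle variation, a slow upward drift from population
    growth, and observation noise of a few hundred counts.
    """

    length: int = 468  # 9 years of weekly data
    period: int = 52
    base: float = 55_000.0
    amplitude: float = 4_000.0
    amplitude_jitter: float = 0.15  # sd of per-cycle multiplicative jitter
    trend: float = 5.0  # per-step drift
    noise_sd: float = 600.0
    shock_at: int | None = None  # 1-based index of regime shift
    shock_magnitude: float = 8_000.0
    seed: int = 0


def gen_seasonal(spec: SyntheticSpec) -> TimeSeries:
    """Seasonal series with per-cycle amplitude jitter and optional shock.

    y_t = base + trend*t + A_cycle * sin(2*pi*t/period) + eps_t, with
    A_cycle = amplitude * (1 + jitter) redrawn once per cycle and
    eps ~ Normal(0, noise_sd).  If ``shock_at`` is set, a sustained level
    shift of ``shock_magnitude`` is added from that index onward.
    """
    if spec.length < 1:
        raise ValueError("length must be >= 1")
    if spec.period < 2:
        raise ValueError("period must be >= 2")
    if spec.shock_at is not None and not 1 <= spec.shock_at <= spec.length:
        raise ValueError("shock_at outside series range")

    rng = np.random.default_rng(spec.seed)
    t = np.arange(1, spec.length + 1, dtype=float)
    n_cycles = int(np.ceil(spec.length / spec.period))
    cycle_amp = spec.amplitude * (
        1.0 + spec.amplitude_jitter * rng.standard_normal(n_cycles)
    )
    amp_per_step = cycle_amp[((t - 1) // spec.period).astype(int)]
    y = (
        spec.base
        + spec.trend * t
        + amp_per_step * np.sin(2.0 * np.pi * t / spec.period)
        + spec.noise_sd * rng.standard_normal(spec.length)
    )
    if spec.shock_at is not None:
        y[spec.shock_at - 1 :] += spec.shock_magnitude
    labels = tuple(f"t{int(i):04d}" for i in t)
    return TimeSeries(values=y, labels=labels)


def gen_logistic_map(length: int, r_param: float = 3.9, x0: float = 0.5) -> TimeSeries:
    """Iterate x_{t+1} = r * x_t * (1 - x_t); chaotic for r near 4."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie in (0, 1)")
    if not 0.0 < r_param <= 4.0:
        raise ValueError("r_param must lie in (0, 4]")
    x = np.empty(length)
    x[0] = x0
    for i in range(1, length):
        x[i] = r_param * x[i - 1] * (1.0 - x[i - 1])
    return TimeSeries(values=x)
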