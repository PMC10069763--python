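"""Rolling-origin forecast evaluation against naive benchmarks.

Point forecasts (simplex and the naive benchmarks) are scored by mean
absolute error per horizon step; the distributional forecast (the kernel
mixture behind the shaded area, renormalized to a pdf) is scored by the
continuous ranked probability score (CRPS).  All scores are in data units.

Every quantity used for a forecast from origin t is computed from
observations at or before t — including the kernel reference width, which
is derived from the series prefix up to the origin — so evaluation is
strictly lookahead-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .density import density_grid, derive_kernel_params, normalized_predictive_pdf
from .forecast import PointForecast, simplex_point_forecast
from .neighbors import compute_weights, find_neighbors
from .params import Hyperparameters
from .series import TimeSeries

__all__ = [
    "EvaluationReport",
    "naive_forecast",
    "seasonal_naive_forecast",
    "crps_numeric",
    "rolling_origin_evaluate",
    "default_origins",
]

METHODS = ("edm_simplex", "edm_density", "naive_last", "seasonal_naive")


def naive_forecast(series: TimeSeries, origin_t: int, tp: int) -> PointForecast:
    """Last-value persistence: every horizon step forecasts y_{origin_t}."""
    y0 = series.value_at(origin_t)
    return PointForecast(origin_t=origin_t, values=np.full(tp, y0))


def seasonal_naive_forecast(
    series: TimeSeries, origin_t: int, tp: int, period: int
) -> PointForecast:
    """Forecast step r with the observation one season earlier, y_{origin_t+r-period}."""
    if period < 1:
        raise ValueError("period must be >= 1")
    if origin_t < period:
        raise ValueError(
            f"origin_t={origin_t} < period={period}: no prior season observed"
        )
    vals = np.array(
        [series.value_at(origin_t + r - period) for r in range(1, tp + 1)]
    )
    return PointForecast(origin_t=origin_t, values=vals)


def crps_numeric(pdf: np.ndarray | Sequence, observation: float) -> float:
    """CRPS of a gridded predictive pdf against a scalar observation.

    ``pdf`` is a sequence of (v, pdf) pairs on an ascending grid that
    integrates to approximately 1.  The score is the integral of
    (CDF(v) - 1{v >= obs})^2, computed by trapezoidal quadrature with the
    grid extended to cover the observation.
    """
    arr = np.asarray(pdf, dtype=float)
    v, p = arr[:, 0], arr[:, 1]
    obs = float(observation)
    if obs < v[0]:
        v = np.concatenate([[obs], v])
        p = np.concatenate([[0.0], p])
    if obs > v[-1]:
        v = np.concatenate([v, [obs]])
        p = np.concatenate([p, [0.0]])
    F = cumulative_trapezoid(p, v, initial=0.0)
    # split the integral at the observation to respect the CDF-step discontinuity
    F_obs = np.interp(obs, v, F)
    idx = int(np.searchsorted(v, obs))
    v2 = np.insert(v, idx, obs)
    F2 = np.insert(F, idx, F_obs)
    left = v2 <= obs
    right = v2 >= obs
    lower = float(np.trapezoid(F2[left] ** 2, v2[left]))
    upper = float(np.trapezoid((F2[right] - 1.0) ** 2, v2[right]))
    return lower + upper


@dataclass(frozen=True)
class EvaluationReport:
    """Per-method, per-horizon accuracy from a rolling-origin evaluation."""

    origins: tuple[int, ...]
    horizon: int
    point_scores: dict[str, np.ndarray]  # method -> MAE per horizon step
    dist_scores: dict[str, np.ndarray]  # method -> mean CRPS per horizon step

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns (method, horizon, metric, value)."""
        rows = []
        for method, scores in self.point_scores.items():
            for r, val in enumerate(scores, start=1):
                rows.append((method, r, "mae", float(val)))
        for method, scores in self.dist_scores.items():
            for r, val in enumerate(scores, start=1):
                rows.append((method, r, "crps", float(val)))
        return pd.DataFrame(rows, columns=["method", "horizon", "metric", "value"])

    def to_json_dict(self) -> dict:
        return {
            "origins": list(self.origins),
            "horizon": self.horizon,
            "point_scores": {k: list(map(float, v)) for k, v in self.point_scores.items()},
            "dist_scores": {k: list(map(float, v)) for k, v in self.dist_scores.items()},
        }


def default_origins(
    series: TimeSeries, hp: Hyperparameters, period: int
) -> list[int]:
    """Every eligible forecast origin in the final third of the series.

    An origin t must leave room for the query vector and at least one
    lookahead-free candidate (t >= E + tp), have a prior season
    (t >= period), and have tp observed outcomes (t + tp <= T).
    """
    start = max(series.T - series.T // 3, hp.E + hp.tp, period)
    return [t for t in range(start, series.T - hp.tp + 1)]


def rolling_origin_evaluate(
    series: TimeSeries,
    hp: Hyperparameters,
    origins: Sequence[int],
    period: int,
) -> EvaluationReport:
    """Score simplex, kernel-density and naive forecasts over rolling origins."""
    if len(origins) == 0:
        raise ValueError("empty origins")
    if period < hp.tp:
        raise ValueError(
            f"period={period} < tp={hp.tp}: the seasonal-naive benchmark would "
            "read observations after the forecast origin"
        )
    for t in origins:
        if t < hp.E + hp.tp:
            raise ValueError(f"origin {t} too early for E={hp.E}, tp={hp.tp}")
        if t < period:
            raise ValueError(f"origin {t} has no prior season (period={period})")
        if t + hp.tp > series.T:
            raise ValueError(f"origin {t} has unobserved outcomes beyond T={series.T}")

    abs_err = {m: [] for m in ("edm_simplex", "naive_last", "seasonal_naive")}
    crps_rows = []
    for t in origins:
        actual = series.window(t + 1, t + hp.tp)
        ns = find_neighbors(series, hp, t)
        compute_weights(ns, hp.theta)
        pf = simplex_point_forecast(ns, hp.tp)
        abs_err["edm_simplex"].append(np.abs(pf.values - actual))
        abs_err["naive_last"].append(
            np.abs(naive_forecast(series, t, hp.tp).values - actual)
        )
        abs_err["seasonal_naive"].append(
            np.abs(seasonal_naive_forecast(series, t, hp.tp, period).values - actual)
        )
        # kernel width from the prefix only: no information after the origin
        prefix = TimeSeries(values=series.values[:t])
        kp = derive_kernel_params(prefix, hp)
        grids = density_grid(ns, hp.tp, kp, hp.grid_points)
        crps_rows.append(
            [
                crps_numeric(normalized_predictive_pdf(dg, ns, kp), actual[dg.step_r - 1])
                for dg in grids
            ]
        )

    point_scores = {m: np.mean(np.stack(v), axis=0) for m, v in abs_err.items()}
    dist_scores = {"edm_density": np.mean(np.array(crps_rows), axis=0)}
    return EvaluationReport(
        origins=tuple(int(t) for t in origins),
        horizon=hp.tp,
        point_scores=point_scores,
        dist_scores=dist_scores,
    )
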