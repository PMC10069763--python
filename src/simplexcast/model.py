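"""Model/results interface for simplex-projection forecasting.

:class:`SimplexEDM` is constructed from a series plus hyperparameters;
``fit()`` runs embedding, neighbor search, weighting, the simplex point
forecast and the kernel density of the shaded forecast area, and returns
a :class:`SimplexResults` carrying all of them with a ``summary()``
table.  Neighbor disabling (the interactive tool's right-click) is
exposed as ``SimplexResults.set_neighbor_enabled``.

Example
-------
>>> from simplexcast import SimplexEDM
>>> from simplexcast.synthetic import SyntheticSpec, gen_seasonal
>>> res = SimplexEDM(gen_seasonal(SyntheticSpec(seed=7)), E=5, n=10, tp=8).fit()
>>> res.predicted.shape
(8,)
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .density import (
    DensityGrid,
    KernelParams,
    density_grid,
    derive_kernel_params,
    normalized_predictive_pdf,
)
from .forecast import PointForecast, simplex_point_forecast
from .neighbors import (
    NeighborSet,
    compute_weights,
    find_neighbors,
    set_neighbor_enabled,
)
from .params import Hyperparameters
from .series import TimeSeries, validate_series

__all__ = ["SimplexEDM", "SimplexResults"]


class SimplexEDM:
    """Simplex-projection forecaster over a univariate series.

    Parameters
    ----------
    series : TimeSeries or sequence
        The observed series; raw sequences are validated.
    E, n, tp, theta, kw, c, grid_points, phase_lag, alpha
        See :class:`~simplexcast.params.Hyperparameters`.
    """

    def __init__(self, series, **hyperparams) -> None:
        if not isinstance(series, TimeSeries):
            series = validate_series(series)
        self.series = series
        self.hp = Hyperparameters(**hyperparams)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, value_col: str = "value",
        label_col: str | None = None, **hyperparams,
    ) -> "SimplexEDM":
        values = df[value_col].to_numpy(dtype=float)
        ts = validate_series(values)
        if label_col is not None:
            ts = TimeSeries(
                values=ts.values,
                labels=tuple(str(x) for x in df[label_col]),
            )
        return cls(ts, **hyperparams)

    @property
    def default_origin(self) -> int:
        """The last time index (the tool's default "current" point)."""
        return self.series.T

    def fit(
        self, origin: int | None = None, disabled: Sequence[int] = ()
    ) -> "SimplexResults":
        """Run the full forecasting pipeline from ``origin``.

        ``origin`` defaults to the series end; ``disabled`` lists neighbor
        time indices to exclude (re-weighting the rest).
        """
        origin = self.default_origin if origin is None else int(origin)
        ns = find_neighbors(self.series, self.hp, origin)
        compute_weights(ns, self.hp.theta)
        for t_i in disabled:
            set_neighbor_enabled(ns, t_i, False)
        # kernel scale from data up to the origin only (lookahead-free)
        prefix = (
            self.series
            if origin == self.series.T
            else TimeSeries(values=self.series.values[:origin])
        )
        kp = derive_kernel_params(prefix, self.hp)
        return SimplexResults(self, origin, ns, kp)


class SimplexResults:
    """Fitted simplex forecast: neighbors, weights, point and density forecasts."""

    def __init__(
        self, model: SimplexEDM, origin: int, ns: NeighborSet, kp: KernelParams
    ) -> None:
        self.model = model
        self.origin = origin
        self.neighbor_set = ns
        self.kernel_params = kp
        self._grids: list[DensityGrid] | None = None
        self._pf: PointForecast | None = None

    # -- core products -------------------------------------------------
    @property
    def point_forecast(self) -> PointForecast:
        if self._pf is None:
            self._pf = simplex_point_forecast(self.neighbor_set, self.model.hp.tp)
        return self._pf

    @property
    def predicted(self) -> np.ndarray:
        """Point forecasts for steps origin+1 .. origin+tp."""
        return self.point_forecast.values

    @property
    def density_grids(self) -> list[DensityGrid]:
        """Shaded-area density K_r per horizon step."""
        if self._grids is None:
            self._grids = density_grid(
                self.neighbor_set, self.model.hp.tp,
                self.kernel_params, self.model.hp.grid_points,
            )
        return self._grids

    def predictive_pdf(self, step: int) -> np.ndarray:
        """Normalized predictive pdf (v, pdf) pairs at horizon ``step``."""
        if not 1 <= step <= self.model.hp.tp:
            raise ValueError(f"step must lie in 1..{self.model.hp.tp}")
        return normalized_predictive_pdf(
            self.density_grids[step - 1], self.neighbor_set, self.kernel_params
        )

    # -- interaction ---------------------------------------------------
    def set_neighbor_enabled(self, t_i: int, enabled: bool) -> "SimplexResults":
        """Toggle a neighbor and invalidate cached forecasts."""
        set_neighbor_enabled(self.neighbor_set, t_i, enabled)
        self._grids = None
        self._pf = None
        return self

    # -- reporting -----------------------------------------------------
    def neighbor_table(self) -> pd.DataFrame:
        """One row per neighbor: t_i, distance, weight, enabled flag."""
        rows = [
            (nb.t_i, nb.d_i, nb.w_i if nb.enabled else np.nan, nb.enabled)
            for nb in self.neighbor_set.neighbors
        ]
        return pd.DataFrame(rows, columns=["t_i", "distance", "weight", "enabled"])

    def forecast_frame(self) -> pd.DataFrame:
        """Point forecast per step with the neighbor value range."""
        enabled = self.neighbor_set.enabled_neighbors
        futures = np.stack([nb.z_i for nb in enabled])
        return pd.DataFrame(
            {
                "step": np.arange(1, self.model.hp.tp + 1),
                "t": self.origin + np.arange(1, self.model.hp.tp + 1),
                "forecast": self.predicted,
                "neighbor_min": futures.min(axis=0),
                "neighbor_max": futures.max(axis=0),
            }
        )

    def summary(self) -> str:
        hp = self.model.hp
        lines = [
            "Simplex projection forecast",
            "=" * 54,
            f"observations: {self.model.series.T}    origin t: {self.origin}",
            f"E={hp.E}  n={hp.n}  tp={hp.tp}  theta={hp.theta}  kw={hp.kw}",
            f"kernel alpha={self.kernel_params.alpha:.6g} "
            f"(sigma_ref={self.kernel_params.sigma_ref:.6g}, q={self.kernel_params.q:.6g})",
            f"mean neighbor distance d_bar={self.neighbor_set.d_bar:.6g}",
            "",
            "Neighbors",
            self.neighbor_table().to_string(index=False),
            "",
            "Forecast",
            self.forecast_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------
    def plot_dashboard(self, path: str, style=None):
        """Render the four-panel dashboard; see :mod:`simplexcast.plotting`."""
        from .plotting import render_dashboard

        return render_dashboard(
            self.model.series, self.neighbor_set, self.point_forecast,
            self.density_grids, self.model.hp, path, style,
        )
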