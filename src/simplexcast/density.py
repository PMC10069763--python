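"""The shaded forecast area: weighted Gaussian kernel sums per horizon step.

At each horizon step r a Gaussian kernel is centred on every enabled
neighbor's future value z_{i,r}, with height proportional to the
neighbor's weight and width alpha in data units:

    K_{i,r}(v) = s * w_i * f((v - z_{i,r}) / (alpha * q))

where f is the standard normal pdf.  The height scale s = 1 / (f(0) * n)
makes the kernel peaks sum to 1 when all n neighbors have weight 1, so the
summed density K_r(v) = sum_i K_{i,r}(v) lies in [0, 1] and maps linearly
(identity, clamped) onto the opacity of the rendered gradient.  The width
scale q makes alpha the full width of the standardized kernel at density
c: f(1/(2q)) = c, i.e. q = 1 / (2 * sqrt(-2 * ln(c * sqrt(2*pi)))).

K_r is a visual density; ``normalized_predictive_pdf`` rescales it into a
proper probability density for scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .neighbors import NeighborSet
from .params import Hyperparameters
from .series import TimeSeries

__all__ = [
    "KernelParams",
    "DensityGrid",
    "derive_kernel_params",
    "kernel_value",
    "density_grid",
    "normalized_predictive_pdf",
]

_F0 = float(norm.pdf(0.0))  # 1/sqrt(2*pi)


@dataclass(frozen=True)
class KernelParams:
    """Derived kernel constants for the shaded forecast area.

    ``s`` scales height so that s * n * f(0) == 1; ``q`` scales width so
    that the standardized kernel falls to density ``c`` exactly alpha/2
    from its centre; ``alpha = sigma_ref * kw`` is the kernel width in
    data units, with ``sigma_ref`` the sample standard deviation of the
    input series (unless an explicit alpha override is supplied).
    """

    alpha: float
    q: float
    s: float
    c: float
    kw: float
    sigma_ref: float
    n_neighbors: int


def _q_from_c(c: float) -> float:
    # half-width x of the standard normal at density c: f(x) = c
    x = math.sqrt(-2.0 * math.log(c * math.sqrt(2.0 * math.pi)))
    return 1.0 / (2.0 * x)


def derive_kernel_params(series: TimeSeries, hp: Hyperparameters) -> KernelParams:
    """Derive s, q and alpha from the series scale and hyperparameters."""
    sigma_ref = float(np.std(series.values, ddof=1)) if series.T > 1 else 0.0
    if hp.alpha is not None:
        alpha = float(hp.alpha)
    else:
        if sigma_ref == 0.0:
            raise ValueError(
                "series has zero variance; supply an explicit alpha override"
            )
        alpha = sigma_ref * hp.kw
    return KernelParams(
        alpha=alpha,
        q=_q_from_c(hp.c),
        s=1.0 / (_F0 * hp.n),
        c=hp.c,
        kw=hp.kw,
        sigma_ref=sigma_ref,
        n_neighbors=hp.n,
    )


def kernel_value(
    v: float | np.ndarray, neighbor_value: float, w: float, kp: KernelParams
) -> float | np.ndarray:
    """Evaluate one neighbor's kernel at value(s) v.

    The peak, at v == neighbor_value, equals w / n; the density falls to
    c / f(0) / n at v == neighbor_value +/- alpha/2.
    """
    z = (np.asarray(v, dtype=float) - neighbor_value) / (kp.alpha * kp.q)
    out = kp.s * w * norm.pdf(z)
    return float(out) if np.isscalar(v) else out


@dataclass(frozen=True)
class DensityGrid:
    """K_r evaluated on a grid covering all kernels at one horizon step."""

    step_r: int
    grid_v: np.ndarray
    density_K: np.ndarray

    @property
    def opacity(self) -> np.ndarray:
        """Linear (identity) map of density onto [0, 1] opacity."""
        return np.clip(self.density_K, 0.0, 1.0)


def density_grid(
    ns: NeighborSet, tp: int, kp: KernelParams, grid_points: int = 256
) -> list[DensityGrid]:
    """Summed kernel density K_r on a per-step grid, for r = 1..tp.

    The grid at step r spans [min_i z_{i,r} - alpha, max_i z_{i,r} + alpha]
    over enabled neighbors, which covers every kernel down to well below
    the edge density c.
    """
    enabled = ns.enabled_neighbors
    if not enabled:
        raise ValueError("all neighbors disabled")
    if any(nb.w_i is None for nb in enabled):
        raise ValueError("weights not computed; call compute_weights first")
    grids = []
    for r in range(1, tp + 1):
        centers = np.array([nb.z_i[r - 1] for nb in enabled])
        weights = np.array([nb.w_i for nb in enabled])
        lo = centers.min() - kp.alpha
        hi = centers.max() + kp.alpha
        v = np.linspace(lo, hi, grid_points)
        z = (v[:, None] - centers[None, :]) / (kp.alpha * kp.q)
        K = (kp.s * norm.pdf(z) * weights[None, :]).sum(axis=1)
        grids.append(DensityGrid(step_r=r, grid_v=v, density_K=K))
    return grids


def normalized_predictive_pdf(
    dg: DensityGrid, ns: NeighborSet, kp: KernelParams
) -> np.ndarray:
    """Rescale K_r into a probability density for scoring.

    Each kernel integrates to s * w_i * alpha * q, so dividing K_r by
    s * alpha * q * sum_i w_i yields a Gaussian mixture pdf that
    integrates to 1 analytically.  Returns an array of (v, pdf) pairs with
    shape (grid_points, 2).
    """
    w_total = sum(nb.w_i for nb in ns.enabled_neighbors)
    if w_total <= 0:
        raise ValueError("zero total weight")
    pdf = dg.density_K / (kp.s * kp.alpha * kp.q * w_total)
    return np.column_stack([dg.grid_v, pdf])
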