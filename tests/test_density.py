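import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.signal import argrelmax
from scipy.stats import norm

from simplexcast import (
    Hyperparameters,
    TimeSeries,
    compute_weights,
    density_grid,
    derive_kernel_params,
    find_neighbors,
    kernel_value,
    normalized_predictive_pdf,
    set_neighbor_enabled,
    simplex_point_forecast,
)
from simplexcast.embedding import DelayVector
from simplexcast.neighbors import Neighbor, NeighborSet

F0 = 1.0 / math.sqrt(2.0 * math.pi)

# frozen from the independent root-finding oracle below (c = 1e-4)
Q_AT_DEFAULT_C = 0.12278378717447201


def q_oracle(c):
    """Independent derivation of q: solve f(x) = c for the standard normal
    half-width x by bracketed root finding, then q = 1/(2x)."""
    x = brentq(lambda x: norm.pdf(x) - c, 1e-9, 50.0)
    return 1.0 / (2.0 * x)


def _ns_from(futures, weights):
    neighbors = [
        Neighbor(t_i=10 + i, x_i=DelayVector(t=10 + i, coords=np.zeros(2)),
                 d_i=float(i), z_i=np.asarray(f, dtype=float), w_i=w)
        for i, (f, w) in enumerate(zip(futures, weights))
    ]
    return NeighborSet(query=DelayVector(t=99, coords=np.zeros(2)),
                       neighbors=neighbors, theta=1.0)


def _kp(n=1, alpha=1.0, c=1e-4, kw=1.0):
    ts = TimeSeries(values=np.arange(50.0))
    return derive_kernel_params(ts, Hyperparameters(n=n, alpha=alpha, c=c, kw=kw))


class TestKernelParams:
    def test_s_single_neighbor(self):
        kp = _kp(n=1)
        assert kp.s == pytest.approx(math.sqrt(2 * math.pi), rel=1e-12)
        assert kp.s * 1 * F0 == pytest.approx(1.0, rel=1e-12)

    def test_q_closed_form_matches_root_finding(self):
        kp = _kp()
        assert kp.q == pytest.approx(Q_AT_DEFAULT_C, abs=1e-12)
        assert kp.q == pytest.approx(q_oracle(1e-4), rel=1e-10)
        # the defining property: standardized kernel falls to c at half-width
        assert norm.pdf(1.0 / (2.0 * kp.q)) == pytest.approx(1e-4, rel=1e-9)

    @pytest.mark.parametrize("c", [1e-6, 1e-4, 1e-2])
    def test_q_property_general_c(self, c):
        kp = _kp(c=c)
        assert kp.q == pytest.approx(q_oracle(c), rel=1e-10)

    def test_kw_scales_alpha_only(self, mortality_series):
        hp1 = Hyperparameters(kw=1.0)
        hp2 = Hyperparameters(kw=2.0)
        kp1 = derive_kernel_params(mortality_series, hp1)
        kp2 = derive_kernel_params(mortality_series, hp2)
        assert kp2.alpha == pytest.approx(2 * kp1.alpha, rel=1e-12)
        assert kp2.s == kp1.s and kp2.q == kp1.q

    def test_sigma_ref_is_sample_sd(self, mortality_series):
        kp = derive_kernel_params(mortality_series, Hyperparameters())
        assert kp.sigma_ref == pytest.approx(
            float(np.std(mortality_series.values, ddof=1)), rel=1e-12
        )

    def test_constant_series_needs_override(self):
        ts = TimeSeries(values=np.full(20, 7.0))
        with pytest.raises(ValueError, match="alpha override"):
            derive_kernel_params(ts, Hyperparameters())
        kp = derive_kernel_params(ts, Hyperparameters(alpha=2.0))
        assert kp.alpha == 2.0


class TestKernelValue:
    def test_peak_is_w_over_n(self):
        kp = _kp(n=1)
        assert kernel_value(5.0, 5.0, 1.0, kp) == pytest.approx(1.0, abs=1e-12)
        kp2 = _kp(n=2)
        assert kernel_value(5.0, 5.0, 0.5, kp2) == pytest.approx(0.25, abs=1e-12)

    def test_edge_density_at_half_alpha(self):
        """At +/- alpha/2 from the centre the kernel equals c/f(0)."""
        kp = _kp(n=1, alpha=3.0)
        expected = 1e-4 / F0
        for v in (5.0 + 1.5, 5.0 - 1.5):
            assert kernel_value(v, 5.0, 1.0, kp) == pytest.approx(expected, rel=1e-9)

    def test_monotone_width_in_kw(self):
        """Doubling kw widens the half-maximum interval, same peak height."""
        ts = TimeSeries(values=np.arange(50.0))
        kp1 = derive_kernel_params(ts, Hyperparameters(n=1, kw=1.0))
        kp2 = derive_kernel_params(ts, Hyperparameters(n=1, kw=2.0))
        assert kernel_value(0.0, 0.0, 1.0, kp1) == pytest.approx(
            kernel_value(0.0, 0.0, 1.0, kp2), rel=1e-12
        )

        def half_width(kp):
            # solve k(v) = peak/2
            return brentq(lambda v: kernel_value(v, 0.0, 1.0, kp) - 0.5, 0, 100 * kp.alpha)

        assert half_width(kp2) == pytest.approx(2 * half_width(kp1), rel=1e-9)


class TestDensityGrid:
    def test_single_neighbor_unit_peak(self):
        ns = _ns_from([[3.0, 4.0]], [1.0])
        grids = density_grid(ns, 2, _kp(n=1), 501)
        for dg, center in zip(grids, [3.0, 4.0]):
            assert dg.density_K.max() == pytest.approx(1.0, abs=1e-6)
            assert dg.grid_v[np.argmax(dg.density_K)] == pytest.approx(center, abs=0.01)

    def test_identical_futures_add_to_one(self):
        ns = _ns_from([[2.0], [2.0]], [1.0, 1.0])
        grids = density_grid(ns, 1, _kp(n=2), 501)
        assert grids[0].density_K.max() == pytest.approx(1.0, abs=1e-6)

    def test_grid_span_covers_kernels(self):
        ns = _ns_from([[0.0], [10.0]], [1.0, 0.5])
        kp = _kp(n=2, alpha=2.0)
        dg = density_grid(ns, 1, kp, 100)[0]
        assert dg.grid_v[0] == pytest.approx(-2.0)
        assert dg.grid_v[-1] == pytest.approx(12.0)

    def test_additivity_oracle(self):
        """density_grid equals the elementwise sum of kernel_value calls."""
        rng = np.random.default_rng(7)
        ns = _ns_from(rng.normal(0, 5, (4, 3)), rng.uniform(0.1, 1.0, 4))
        kp = _kp(n=4, alpha=1.3)
        for dg in density_grid(ns, 3, kp, 64):
            manual = sum(
                kernel_value(dg.grid_v, nb.z_i[dg.step_r - 1], nb.w_i, kp)
                for nb in ns.neighbors
            )
            np.testing.assert_allclose(dg.density_K, manual, rtol=1e-12)

    def test_peak_sum_bound_random(self):
        """max K_r <= sum(w)/n <= 1 across random configurations."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            tp = int(rng.integers(1, 5))
            futures = rng.normal(0, 10, (n, tp))
            ns = _ns_from(futures, np.ones(n))
            compute_distances = rng.uniform(0.1, 5.0, n)
            for nb, d in zip(ns.neighbors, sorted(compute_distances)):
                nb.d_i = float(d)
            compute_weights(ns, float(rng.uniform(0, 3)))
            kp = _kp(n=n, alpha=float(rng.uniform(0.5, 5.0)))
            w_sum = sum(nb.w_i for nb in ns.neighbors)
            assert w_sum / n <= 1.0 + 1e-12
            for dg in density_grid(ns, tp, kp, 128):
                assert dg.density_K.max() <= w_sum / n + 1e-9

    def test_disabled_neighbor_never_raises_density(self):
        ns = _ns_from([[0.0], [1.0], [5.0]], [1.0, 0.7, 0.4])
        kp = _kp(n=3, alpha=1.0)
        before = density_grid(ns, 1, kp, 200)[0]
        ns.neighbor_by_t(11).enabled = False  # freeze weights: no recompute
        after = density_grid(ns, 1, kp, 200)[0]
        interp = np.interp(before.grid_v, after.grid_v, after.density_K)
        assert np.all(interp <= before.density_K + 1e-9)

    def test_bimodal_futures(self):
        """Two neighbor-future clusters separated by > 4 alpha give exactly
        two local maxima while the point forecast falls between them."""
        kp = _kp(n=4, alpha=0.5)
        # intra-cluster spacing below the kernel sd (alpha*q ~ 0.06) so each
        # cluster merges into a single mode
        ns = _ns_from([[0.0], [0.04], [10.0], [10.04]], [1.0, 0.9, 0.8, 0.7])
        dg = density_grid(ns, 1, kp, 1001)[0]
        n_peaks = len(argrelmax(dg.density_K)[0])
        assert n_peaks == 2
        pf = simplex_point_forecast(ns, 1)
        assert 0.04 < pf.values[0] < 10.0

    def test_opacity_identity_clamped(self):
        ns = _ns_from([[1.0]], [1.0])
        dg = density_grid(ns, 1, _kp(n=1), 100)[0]
        np.testing.assert_array_equal(dg.opacity, np.clip(dg.density_K, 0, 1))


class TestNormalizedPdf:
    def test_integrates_to_one_random(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(1, 7))
            ns = _ns_from(rng.normal(0, 3, (n, 1)), rng.uniform(0.05, 1.0, n))
            kp = _kp(n=n, alpha=float(rng.uniform(0.3, 4.0)))
            dg = density_grid(ns, 1, kp, 512)[0]
            pdf = normalized_predictive_pdf(dg, ns, kp)
            # extend beyond kernel extremes before quadrature
            centers = np.array([nb.z_i[0] for nb in ns.neighbors])
            lo = centers.min() - 6 * kp.alpha * kp.q - kp.alpha
            hi = centers.max() + 6 * kp.alpha * kp.q + kp.alpha
            v = np.linspace(lo, hi, 4096)
            dens = np.interp(v, pdf[:, 0], pdf[:, 1], left=0.0, right=0.0)
            integral = np.trapezoid(dens, v)
            assert 0.999 <= integral <= 1.001

    def test_single_kernel_is_gaussian(self):
        """One kernel normalizes to N(center, (alpha*q)^2)."""
        kp = _kp(n=1, alpha=2.0)
        ns = _ns_from([[3.0]], [0.6])
        dg = density_grid(ns, 1, kp, 512)[0]
        pdf = normalized_predictive_pdf(dg, ns, kp)
        expected = norm.pdf(pdf[:, 0], loc=3.0, scale=kp.alpha * kp.q)
        np.testing.assert_allclose(pdf[:, 1], expected, rtol=1e-9)

    def test_equal_weight_mass_split(self):
        kp = _kp(n=2, alpha=0.5)
        ns = _ns_from([[0.0], [100.0]], [0.5, 0.5])
        dg = density_grid(ns, 1, kp, 2001)[0]
        pdf = normalized_predictive_pdf(dg, ns, kp)
        mid = pdf[:, 0] < 50.0
        lower = np.trapezoid(pdf[mid, 1], pdf[mid, 0])
        assert lower == pytest.approx(0.5, abs=1e-3)

    def test_zero_weight_error(self):
        ns = _ns_from([[1.0]], [1.0])
        dg = density_grid(ns, 1, _kp(), 50)[0]
        ns.neighbors[0].enabled = False
        with pytest.raises(ValueError, match="zero total weight"):
            normalized_predictive_pdf(dg, ns, _kp())
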