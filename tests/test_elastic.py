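"""Elastic shape analysis: SRVF, warping, alignment and distances.

Analytic oracles:
* f(t) = t vs 2t: q1 = 1, q2 = sqrt(2); for any warp the alignment cost
  is 3 - 2*sqrt(2)*integral(sqrt(gamma')), minimized at the identity
  (Cauchy-Schwarz), so d_amp = sqrt(3 - 2 sqrt 2) = sqrt(2) - 1 and
  d_phs = 0.
* aligning f o gamma back to f for gamma(t) = t^2 recovers sqrt(t);
  integral sqrt(d/dt sqrt(t)) dt = 2 sqrt(2) / 3, so
  d_phs = arccos(2 sqrt 2 / 3) ~ 0.3398.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actimotif.curves import (
    DistanceWeights,
    FunctionalCurve,
    InvalidCurveError,
    WarpingFunction,
    uniform_grid,
)
from actimotif.elastic import (
    align,
    amplitude_distance,
    amplitude_phase_distance,
    elastic_distance,
    phase_distance,
    srvf_transform,
    warp_curve,
)

from conftest import random_boundary_warp, random_smooth_curve


class TestSRVFTransform:
    def test_linear_curve_constant_srvf(self):
        g = uniform_grid(101)
        q = srvf_transform(FunctionalCurve(g, g.copy()))
        assert np.allclose(q.qvalues, 1.0, atol=1e-12)

    def test_constant_curve_zero_srvf(self):
        g = uniform_grid(101)
        q = srvf_transform(FunctionalCurve(g, np.full(101, 3.7)))
        assert np.all(q.qvalues == 0.0)

    def test_quadratic_matches_closed_form(self):
        # f = t^2 -> q = 2t / sqrt(2t) = sqrt(2t)
        g = uniform_grid(101)
        q = srvf_transform(FunctionalCurve(g, g**2))
        interior = slice(1, -1)
        assert np.max(np.abs(q.qvalues[interior] - np.sqrt(2 * g[interior]))) < 1e-3


class TestWarpCurve:
    def test_identity_returns_input_exactly(self):
        g = uniform_grid(64)
        f = FunctionalCurve(g, np.sin(2 * np.pi * g))
        from actimotif.curves import identity_warp

        assert np.array_equal(warp_curve(f, identity_warp(g)).values, f.values)

    def test_composition_with_linear_curve_returns_gamma(self):
        g = uniform_grid(64)
        f = FunctionalCurve(g, g.copy())
        gamma = WarpingFunction(g, g**2)
        assert np.allclose(warp_curve(f, gamma).values, gamma.gamma, atol=1e-12)

    def test_square_after_sqrt_is_identity_curve(self):
        g = uniform_grid(201)
        f = FunctionalCurve(g, g**2)
        gamma = WarpingFunction(g, np.sqrt(g))
        assert np.max(np.abs(warp_curve(f, gamma).values - g)) < 1e-6

    def test_rejects_mismatched_grid(self):
        f = FunctionalCurve(uniform_grid(32), np.zeros(32))
        gamma = WarpingFunction(uniform_grid(64), uniform_grid(64))
        with pytest.raises(InvalidCurveError):
            warp_curve(f, gamma)


class TestAlign:
    def test_self_alignment_is_identity(self):
        g = uniform_grid(101)
        f = FunctionalCurve(g, np.sin(2 * np.pi * g))
        assert align(f, f).is_identity(tol=1e-8)

    def test_linear_pair_alignment_is_identity(self):
        # warping cannot reduce ||1 - sqrt(2) sqrt(gamma')||
        g = uniform_grid(101)
        w = align(FunctionalCurve(g, g.copy()), FunctionalCurve(g, 2 * g))
        assert w.is_identity(tol=1e-6)

    def test_recovers_warp_to_small_amplitude_residual(self):
        g = uniform_grid(201)
        f = FunctionalCurve(g, np.sin(2 * np.pi * g))
        fw = warp_curve(f, WarpingFunction(g, g**2))
        assert amplitude_distance(f, fw) <= 0.02

    def test_degenerate_zero_curves_return_identity(self):
        g = uniform_grid(32)
        f = FunctionalCurve(g, np.zeros(32))
        assert align(f, f).is_identity(tol=0.0)

    def test_dp_matches_exhaustive_path_search(self):
        """DP optimum equals brute-force enumeration over the same lattice."""
        from actimotif.elastic import _dp_core, _backtrack

        steps = np.array(
            [(1, 1), (1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2)], dtype=np.int64
        )
        g = uniform_grid(9)
        rng = np.random.default_rng(3)
        q1 = rng.normal(0, 1, 9)
        q2 = rng.normal(0, 1, 9)
        dt = g[1] - g[0]
        D, _ = _dp_core(q1, q2, dt, steps)

        def seg_cost(ip, jp, i, j):
            di, dj = i - ip, j - jp
            slope = dj / di
            nsub = max(di, dj)
            h1, h2 = di / nsub, dj / nsub
            c = 0.0
            for m in range(nsub):
                x1 = ip + h1 * (m + 0.5)
                x2 = jp + h2 * (m + 0.5)
                q1v = np.interp(x1, np.arange(9), q1)
                q2v = np.interp(x2, np.arange(9), q2)
                c += (q1v - np.sqrt(slope) * q2v) ** 2
            return c * dt * h1

        best = [np.inf]

        def enumerate_paths(i, j, cost):
            if i == 0 and j == 0:
                best[0] = min(best[0], cost)
                return
            for p, q in steps:
                if i - p >= 0 and j - q >= 0:
                    enumerate_paths(i - p, j - q, cost + seg_cost(i - p, j - q, i, j))

        enumerate_paths(8, 8, 0.0)
        assert D[8, 8] == pytest.approx(best[0], abs=1e-9)


class TestAmplitudeDistance:
    def test_self_distance_is_zero(self):
        g = uniform_grid(101)
        f = FunctionalCurve(g, np.cos(2 * np.pi * g))
        assert amplitude_distance(f, f) < 1e-8

    def test_linear_pair_closed_form(self):
        g = uniform_grid(201)
        d = amplitude_distance(FunctionalCurve(g, g.copy()), FunctionalCurve(g, 2 * g))
        assert d == pytest.approx(np.sqrt(2) - 1, abs=1e-2)

    def test_reparameterization_invariance(self):
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(10):
            f = random_smooth_curve(rng)
            gamma = random_boundary_warp(rng)
            d = amplitude_distance(f, warp_curve(f, gamma))
            ratios.append(d / srvf_transform(f).norm())
        assert np.median(ratios) <= 0.02

    def test_symmetry_within_tolerance(self):
        # symmetry is identifiable when the two curves share a common
        # shape (warp + amplitude scale + small perturbation); for
        # strongly dissimilar pairs the discrete alignment can pinch
        rng = np.random.default_rng(5)
        gaps = []
        for _ in range(10):
            f1 = random_smooth_curve(rng, n=101)
            gamma = random_boundary_warp(rng, n=101)
            scale = 1.0 + rng.normal(0, 0.1)
            f2 = FunctionalCurve(f1.grid, scale * warp_curve(f1, gamma).values)
            gaps.append(abs(amplitude_distance(f1, f2) - amplitude_distance(f2, f1)))
        assert np.median(gaps) <= 1e-2


class TestPhaseDistance:
    def test_identical_curves_zero_phase(self):
        g = uniform_grid(101)
        f = FunctionalCurve(g, np.sin(2 * np.pi * g))
        assert phase_distance(f, f) == pytest.approx(0.0, abs=1e-10)

    def test_monotone_curve_quadratic_warp(self):
        # recovered warp ~ sqrt(t); arccos(2 sqrt2/3) ~ 0.3398
        g = uniform_grid(201)
        f = FunctionalCurve(g, np.sin(2 * np.pi * g))
        fw = warp_curve(f, WarpingFunction(g, g**2))
        assert phase_distance(f, fw) == pytest.approx(np.arccos(2 * np.sqrt(2) / 3), abs=5e-2)

    def test_symmetry_and_range_on_random_pairs(self):
        rng = np.random.default_rng(7)
        gaps = []
        for _ in range(10):
            f = random_smooth_curve(rng, n=101)
            fw = warp_curve(f, random_boundary_warp(rng, n=101))
            d12 = phase_distance(f, fw)
            d21 = phase_distance(fw, f)
            assert 0.0 <= d12 <= np.pi / 2
            gaps.append(abs(d12 - d21))
        assert np.median(gaps) <= 1e-2


class TestElasticDistance:
    def test_weight_degeneracy_equalities_exact(self):
        g = uniform_grid(101)
        f1 = FunctionalCurve(g, np.sin(2 * np.pi * g))
        f2 = FunctionalCurve(g, 0.5 + np.cos(2 * np.pi * g))
        only_amp = DistanceWeights.single_axis(0.0, 1.0)
        only_phs = DistanceWeights.single_axis(1.0, 0.0)
        assert elastic_distance(f1, f2, only_amp) == amplitude_distance(f1, f2)
        assert elastic_distance(f1, f2, only_phs) == phase_distance(f1, f2)

    def test_identical_curves_zero_for_any_weights(self):
        g = uniform_grid(101)
        f = FunctionalCurve(g, np.sin(2 * np.pi * g))
        for wp in (0.0, 0.3, 1.0):
            w = DistanceWeights.single_axis(wp, 1.0 - wp)
            assert elastic_distance(f, f, w) < 1e-8

    def test_multi_axis_weighted_sum_is_linear(self):
        g = uniform_grid(101)
        axes1 = [
            FunctionalCurve(g, np.sin(2 * np.pi * g)),
            FunctionalCurve(g, g.copy()),
            FunctionalCurve(g, g**2),
        ]
        axes2 = [
            FunctionalCurve(g, np.cos(2 * np.pi * g)),
            FunctionalCurve(g, 2 * g),
            FunctionalCurve(g, np.full(101, 0.3)),
        ]
        w = DistanceWeights.equal(3)
        expected = sum(
            (amplitude_phase_distance(a, b)[1] + amplitude_phase_distance(a, b)[0]) / 6
            for a, b in zip(axes1, axes2)
        )
        assert elastic_distance(axes1, axes2, w) == pytest.approx(expected, abs=1e-10)

    def test_axis_count_mismatch_raises(self):
        g = uniform_grid(101)
        f = FunctionalCurve(g, g.copy())
        with pytest.raises(InvalidCurveError):
            elastic_distance([f, f], [f], DistanceWeights.equal(2))


@given(st.integers(min_value=0, max_value=10_000))
@settings(derandomize=True, max_examples=15, deadline=None)
def test_distance_ranges_hold_for_random_curves(seed):
    """Amplitude >= 0 and phase within [0, pi/2] for arbitrary smooth pairs."""
    rng = np.random.default_rng(seed)
    f1 = random_smooth_curve(rng, n=64)
    f2 = random_smooth_curve(rng, n=64)
    d_amp, d_phs = amplitude_phase_distance(f1, f2)
    assert d_amp >= 0.0
    assert 0.0 <= d_phs <= np.pi / 2
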