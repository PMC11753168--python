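"""Shared fixtures: numba warm-up and small synthetic curve factories."""

from __future__ import annotations

import numpy as np
import pytest

from actimotif.cluster import ActivitySegment
from actimotif.curves import FunctionalCurve, WarpingFunction, uniform_grid
from actimotif.elastic import amplitude_phase_distance, warp_curve


@pytest.fixture(scope="session", autouse=True)
def warm_numba():
    """Compile the DP/refinement kernels once so timed tests see steady state."""
    g = uniform_grid(16)
    f = FunctionalCurve(g, np.sin(2 * np.pi * g))
    amplitude_phase_distance(f, FunctionalCurve(g, g.copy()))


def random_smooth_curve(rng: np.random.Generator, n: int = 201, n_harmonics: int = 4) -> FunctionalCurve:
    """Random low-frequency Fourier curve on the unit interval."""
    g = uniform_grid(n)
    vals = np.zeros(n)
    for k in range(n_harmonics):
        vals += rng.normal(0, 1) * np.sin((k + 1) * np.pi * g + rng.uniform(0, 2 * np.pi))
    return FunctionalCurve(g, vals)


def random_boundary_warp(rng: np.random.Generator, n: int = 201, concentration: float = 20.0) -> WarpingFunction:
    """Dirichlet-style random warp: normalized cumulative positive increments."""
    inc = rng.gamma(concentration, size=n - 1)
    gamma = np.concatenate(([0.0], np.cumsum(inc)))
    gamma /= gamma[-1]
    return WarpingFunction(uniform_grid(n), gamma)


def template_value(name: str, t: np.ndarray) -> np.ndarray:
    """Two clearly distinct motif shapes for planted-cluster tests."""
    if name == "sine":
        return 1.0 + 0.8 * np.sin(np.pi * t)
    if name == "double":
        return 1.0 + 0.8 * np.sign(np.sin(2 * np.pi * t)) * np.sin(2 * np.pi * t) ** 2
    if name == "flat":
        return np.full_like(t, 0.1)
    raise KeyError(name)


def planted_segments(
    template_names: list[str],
    n_segments: int,
    seed: int,
    n_points: int = 30,
    jitter_sd: float = 0.1,
    noise_sd: float = 0.05,
    warp_concentration: float = 25.0,
) -> tuple[list[ActivitySegment], np.ndarray]:
    """Segments drawn round-robin from warped, jittered templates."""
    rng = np.random.default_rng(seed)
    g = uniform_grid(n_points)
    segments, truth = [], []
    for i in range(n_segments):
        name = template_names[i % len(template_names)]
        gamma = random_boundary_warp(rng, n_points, warp_concentration)
        amp = 1.0 + rng.normal(0, jitter_sd)
        vals = amp * template_value(name, gamma.gamma) + rng.normal(0, noise_sd, n_points)
        segments.append(
            ActivitySegment(
                subject_id=f"s{i % 5}",
                day_index=1 + i // 48,
                window_index=i,
                axes=(FunctionalCurve(g, vals),),
            )
        )
        truth.append(template_names.index(name))
    return segments, np.array(truth)
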