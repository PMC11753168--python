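"""Functional-curve containers used throughout the package.

Activity curves are represented as real-valued functions sampled on a
uniform grid over the normalized time interval [0, 1].  Timing
differences between curves are expressed through boundary-preserving
monotone reparameterizations (warping functions) of the same interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FunctionalCurve",
    "SRVFCurve",
    "WarpingFunction",
    "DistanceWeights",
    "uniform_grid",
    "identity_warp",
]

#: tolerance on grid uniformity
_GRID_TOL = 1e-12
#: minimum number of samples for a curve
_MIN_POINTS = 8


class InvalidCurveError(ValueError):
    """Raised when a curve violates the grid or value contract."""


class InvalidWarpError(ValueError):
    """Raised when a warping function is not monotone/boundary-preserving."""


class InvalidWeightsError(ValueError):
    """Raised when phase/amplitude weights do not sum to one."""


def uniform_grid(n_points: int) -> np.ndarray:
    """Uniform grid of ``n_points`` samples spanning [0, 1]."""
    if n_points < _MIN_POINTS:
        raise InvalidCurveError(f"need at least {_MIN_POINTS} samples, got {n_points}")
    return np.linspace(0.0, 1.0, n_points)


def _check_grid(grid: np.ndarray) -> None:
    if grid.ndim != 1 or grid.size < _MIN_POINTS:
        raise InvalidCurveError(
            f"grid must be 1-d with at least {_MIN_POINTS} points, got shape {grid.shape}"
        )
    if abs(grid[0]) > _GRID_TOL or abs(grid[-1] - 1.0) > _GRID_TOL:
        raise InvalidCurveError("grid must span [0, 1]")
    steps = np.diff(grid)
    if np.any(steps <= 0):
        raise InvalidCurveError("grid must be strictly increasing")
    if np.ptp(steps) > _GRID_TOL * max(1.0, grid.size):
        raise InvalidCurveError("grid must be uniformly spaced")


@dataclass(frozen=True)
class FunctionalCurve:
    """A scalar function f : [0, 1] -> R sampled on a uniform grid.

    Parameters
    ----------
    grid
        Strictly increasing uniform sample times, grid[0] = 0, grid[-1] = 1.
    values
        Finite samples of f at the grid points (scaled activity counts).
    """

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        _check_grid(grid)
        if values.shape != grid.shape:
            raise InvalidCurveError("values and grid must have the same shape")
        if not np.all(np.isfinite(values)):
            raise InvalidCurveError("curve values must be finite")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def n_points(self) -> int:
        return self.grid.size

    @classmethod
    def from_values(cls, values: np.ndarray) -> "FunctionalCurve":
        """Curve from samples alone, on the implied uniform grid."""
        values = np.asarray(values, dtype=float)
        return cls(uniform_grid(values.size), values)


@dataclass(frozen=True)
class SRVFCurve:
    """Square-root velocity representation q(t) = f'(t)/sqrt(|f'(t)|).

    Constructed only through :func:`actimotif.elastic.srvf_transform`.
    """

    grid: np.ndarray
    qvalues: np.ndarray
    _token: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        from . import elastic  # local import to avoid a cycle

        if self._token is not elastic._SRVF_TOKEN:
            raise TypeError("SRVFCurve must be constructed via srvf_transform()")
        grid = np.asarray(self.grid, dtype=float)
        q = np.asarray(self.qvalues, dtype=float)
        _check_grid(grid)
        if q.shape != grid.shape or not np.all(np.isfinite(q)):
            raise InvalidCurveError("qvalues must be finite and match the grid")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "qvalues", q)

    @property
    def n_points(self) -> int:
        return self.grid.size

    def norm(self) -> float:
        """L2 norm ||q|| under trapezoidal quadrature."""
        return float(np.sqrt(np.trapezoid(self.qvalues**2, self.grid)))


@dataclass(frozen=True)
class WarpingFunction:
    """A boundary-preserving monotone reparameterization gamma of [0, 1]."""

    grid: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        _check_grid(grid)
        if gamma.shape != grid.shape:
            raise InvalidWarpError("gamma and grid must have the same shape")
        if abs(gamma[0]) > 1e-10 or abs(gamma[-1] - 1.0) > 1e-10:
            raise InvalidWarpError("gamma must map 0 to 0 and 1 to 1")
        if np.any(np.diff(gamma) < -1e-12):
            raise InvalidWarpError("gamma must be nondecreasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "gamma", np.clip(gamma, 0.0, 1.0))

    @property
    def n_points(self) -> int:
        return self.grid.size

    def is_identity(self, tol: float = 1e-10) -> bool:
        return bool(np.max(np.abs(self.gamma - self.grid)) <= tol)

    def sqrt_derivative_integral(self) -> float:
        """integral of sqrt(gamma') over [0, 1], exact for the piecewise-linear gamma.

        Per cell of width dt, gamma' is constant, so the contribution is
        sqrt(dgamma * dt).
        """
        dg = np.diff(self.gamma)
        dt = np.diff(self.grid)
        return float(np.sum(np.sqrt(np.maximum(dg, 0.0) * dt)))


def identity_warp(grid: np.ndarray) -> WarpingFunction:
    """The identity reparameterization l(t) = t on ``grid`` (exact)."""
    grid = np.asarray(grid, dtype=float)
    return WarpingFunction(grid, grid.copy())


@dataclass(frozen=True)
class DistanceWeights:
    """Per-axis phase/amplitude weights (w_p,h, w_a,h), h = 1..H.

    All weights are nonnegative and sum to one across every term, so the
    elastic distance is a convex combination of per-axis phase and
    amplitude distances.
    """

    phase: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        wp = np.atleast_1d(np.asarray(self.phase, dtype=float))
        wa = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        if wp.shape != wa.shape or wp.ndim != 1:
            raise InvalidWeightsError("phase and amplitude weights must be 1-d and matching")
        if np.any(wp < 0) or np.any(wa < 0):
            raise InvalidWeightsError("weights must be nonnegative")
        total = float(np.sum(wp) + np.sum(wa))
        if abs(total - 1.0) > 1e-12:
            raise InvalidWeightsError(f"weights must sum to 1, got {total!r}")
        object.__setattr__(self, "phase", wp)
        object.__setattr__(self, "amplitude", wa)

    @property
    def n_axes(self) -> int:
        return self.phase.size

    @classmethod
    def equal(cls, n_axes: int = 1) -> "DistanceWeights":
        """Equal split across all phase/amplitude terms: w = 1/(2H)."""
        w = np.full(n_axes, 1.0 / (2 * n_axes))
        return cls(w, w.copy())

    @classmethod
    def single_axis(cls, w_phase: float, w_amplitude: float) -> "DistanceWeights":
        return cls(np.array([w_phase]), np.array([w_amplitude]))
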