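"""Elastic shape analysis for activity curves.

A curve f on [0, 1] is represented by its square-root velocity function
(SRVF) q(t) = f'(t) / sqrt(|f'(t)|).  Warping f by a monotone gamma maps
q to (q o gamma) * sqrt(gamma'), so the L2 distance between SRVFs after
optimizing over gamma is invariant to reparameterization.  The optimal
warp splits the discrepancy between two curves into

* an amplitude distance  d_amp = || q1 - (q2 o gamma*) sqrt(gamma*') ||,
  the shape/intensity difference net of timing, and
* a phase distance  d_phs = arccos( integral sqrt(gamma*') ),
  the timing difference, bounded by Cauchy-Schwarz to [0, pi/2].

The optimal warp is found in two stages: dynamic programming over
monotone lattice paths on the sample grid with a fixed set of admissible
segment slopes (coprime ratios p/q with p, q <= 7 by default), followed
by a continuous local refinement of the warp increments (L-BFGS on a
softmax parameterization, analytic gradient).  The DP provides a global
search; the refinement removes the lattice quantization of gamma', to
which the amplitude objective is highly sensitive.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .curves import (
    DistanceWeights,
    FunctionalCurve,
    InvalidCurveError,
    SRVFCurve,
    WarpingFunction,
    identity_warp,
)

__all__ = [
    "srvf_transform",
    "warp_curve",
    "align",
    "amplitude_distance",
    "phase_distance",
    "amplitude_phase_distance",
    "elastic_distance",
    "default_slope_steps",
]

#: construction token for SRVFCurve (no free construction)
_SRVF_TOKEN = object()

#: velocities below this magnitude map to q = 0 (the 0/0 limit of the SRVF)
EPS_DERIV = 1e-8

#: largest numerator/denominator in the admissible DP slope set
MAX_SLOPE_COMPONENT = 7


def default_slope_steps(max_component: int = MAX_SLOPE_COMPONENT) -> np.ndarray:
    """Admissible DP steps (di, dj) as coprime pairs with entries <= max_component.

    The unit-slope step (1, 1) comes first so that exact ties in the DP
    objective resolve toward the identity warp.
    """
    steps = [(1, 1)]
    for p in range(1, max_component + 1):
        for q in range(1, max_component + 1):
            if (p, q) != (1, 1) and math.gcd(p, q) == 1:
                steps.append((p, q))
    steps[1:] = sorted(steps[1:], key=lambda s: (abs(math.log(s[1] / s[0])), s[0] + s[1]))
    return np.asarray(steps, dtype=np.int64)


_DEFAULT_STEPS = default_slope_steps()


def srvf_transform(curve: FunctionalCurve) -> SRVFCurve:
    """Square-root velocity transform of a sampled curve.

    The derivative is estimated by second-order centered finite
    differences (one-sided at the boundaries).  Where |f'| < EPS_DERIV
    the transform is set to 0, its limiting value for vanishing velocity.
    """
    if not isinstance(curve, FunctionalCurve):
        raise InvalidCurveError("srvf_transform expects a FunctionalCurve")
    df = np.gradient(curve.values, curve.grid, edge_order=2)
    mag = np.abs(df)
    q = np.zeros_like(df)
    ok = mag >= EPS_DERIV
    q[ok] = df[ok] / np.sqrt(mag[ok])
    return SRVFCurve(curve.grid, q, _token=_SRVF_TOKEN)


def warp_curve(curve: FunctionalCurve, gamma: WarpingFunction) -> FunctionalCurve:
    """Compose f with gamma: returns f o gamma sampled on the common grid.

    Composition with the identity returns the input values exactly.
    """
    if not isinstance(gamma, WarpingFunction):
        raise InvalidCurveError("warp_curve expects a WarpingFunction")
    if gamma.n_points != curve.n_points:
        raise InvalidCurveError("curve and warp must share one grid")
    if gamma.is_identity(tol=0.0):
        return FunctionalCurve(curve.grid, curve.values.copy())
    from scipy.interpolate import CubicSpline

    warped = CubicSpline(curve.grid, curve.values)(np.clip(gamma.gamma, 0.0, 1.0))
    return FunctionalCurve(curve.grid, warped)


@njit(cache=True)
def _dp_core(q1, q2, dt, steps):  # pragma: no cover - exercised via align()
    """DP over monotone lattice paths; returns predecessor step table.

    Cost of a segment from (ip, jp) to (i, j): trapezoidal quadrature of
    (q1(t) - sqrt(s) * q2(gamma(t)))^2 over the q1 sample points it spans,
    with gamma linear of slope s = (j - jp)/(i - ip) and q2 linearly
    interpolated at fractional indices.
    """
    n = q1.shape[0]
    BIG = 1e30
    D = np.full((n, n), BIG)
    pred = np.full((n, n), -1, dtype=np.int64)
    D[0, 0] = 0.0
    n_steps = steps.shape[0]
    for i in range(1, n):
        for j in range(1, n):
            best = BIG
            barg = -1
            for s in range(n_steps):
                di = steps[s, 0]
                dj = steps[s, 1]
                ip = i - di
                jp = j - dj
                if ip < 0 or jp < 0:
                    continue
                d0 = D[ip, jp]
                if d0 >= BIG:
                    continue
                slope = dj / di
                sq = np.sqrt(slope)
                # midpoint quadrature refined along the steeper axis; midpoint
                # sampling keeps the 0*inf product q2(gamma)*sqrt(gamma')
                # finite where gamma is steep and q2 vanishes
                nsub = di if di >= dj else dj
                h1 = di / nsub
                h2 = dj / nsub
                c = 0.0
                for m in range(nsub):
                    x1 = ip + h1 * (m + 0.5)
                    k1 = int(x1)
                    if k1 > n - 2:
                        k1 = n - 2
                    f1r = x1 - k1
                    q1v = q1[k1] * (1.0 - f1r) + q1[k1 + 1] * f1r
                    x2 = jp + h2 * (m + 0.5)
                    k2 = int(x2)
                    if k2 > n - 2:
                        k2 = n - 2
                    f2r = x2 - k2
                    q2v = q2[k2] * (1.0 - f2r) + q2[k2 + 1] * f2r
                    diff = q1v - sq * q2v
                    c += diff * diff
                tot = d0 + c * dt * h1
                if tot < best - 1e-13:
                    best = tot
                    barg = s
            D[i, j] = best
            pred[i, j] = barg
    return D, pred


def _backtrack(pred: np.ndarray, steps: np.ndarray, grid: np.ndarray) -> np.ndarray:
    n = pred.shape[0]
    i, j = n - 1, n - 1
    nodes_i = [i]
    nodes_j = [j]
    while i > 0 or j > 0:
        s = pred[i, j]
        if s < 0:  # unreachable; cannot happen with (1, 1) in the step set
            raise RuntimeError("DP backtrack failed")
        i -= int(steps[s, 0])
        j -= int(steps[s, 1])
        nodes_i.append(i)
        nodes_j.append(j)
    nodes_i.reverse()
    nodes_j.reverse()
    return np.interp(grid, grid[np.array(nodes_i)], grid[np.array(nodes_j)])


def align(
    f1: FunctionalCurve,
    f2: FunctionalCurve,
    *,
    steps: np.ndarray | None = None,
    refine: bool = True,
) -> WarpingFunction:
    """Optimal warp gamma* aligning f2 to f1.

    Minimizes || q1 - (q2 o gamma) sqrt(gamma') || by a DP search over
    monotone lattice paths on the shared sample grid, optionally followed
    by continuous refinement of the warp increments.  Degenerate
    near-zero SRVF pairs return the identity.
    """
    if f1.n_points != f2.n_points:
        raise InvalidCurveError("curves must share one grid")
    q1 = srvf_transform(f1)
    q2 = srvf_transform(f2)
    return _align_srvf(q1.qvalues, q2.qvalues, f1.grid, steps, refine=refine)


def _align_srvf(
    q1: np.ndarray,
    q2: np.ndarray,
    grid: np.ndarray,
    steps: np.ndarray | None = None,
    *,
    refine: bool = True,
) -> WarpingFunction:
    if steps is None:
        steps = _DEFAULT_STEPS
    if np.max(np.abs(q1)) < EPS_DERIV and np.max(np.abs(q2)) < EPS_DERIV:
        return identity_warp(grid)
    dt = grid[1] - grid[0]
    _, pred = _dp_core(
        np.ascontiguousarray(q1, dtype=np.float64),
        np.ascontiguousarray(q2, dtype=np.float64),
        float(dt),
        steps,
    )
    gamma = _backtrack(pred, steps, grid)
    gamma[0] = 0.0
    gamma[-1] = 1.0
    if refine:
        gamma = _refine_warp(q1, q2, grid, gamma)
    return WarpingFunction(grid, gamma)


@njit(cache=True)
def _refine_core(q1, q2, dq2, grid, v, max_iter):  # pragma: no cover - via align()
    """Armijo gradient descent on softmax-parameterized warp increments."""
    n = grid.shape[0]
    dt = grid[1] - grid[0]
    nc = n - 1
    mid_t = np.empty(nc)
    for c in range(nc):
        mid_t[c] = 0.5 * (grid[c] + grid[c + 1])
    q1m = np.interp(mid_t, grid, q1)

    def _eval(vv):
        mx = vv.max()
        ex = np.exp(vv - mx)
        e = ex / ex.sum()
        gam = np.empty(n)
        gam[0] = 0.0
        for c in range(nc):
            gam[c + 1] = gam[c] + e[c]
        gm = np.empty(nc)
        for c in range(nc):
            gm[c] = 0.5 * (gam[c] + gam[c + 1])
        q2m = np.interp(gm, grid, q2)
        dq2m = np.interp(gm, grid, dq2)
        J = 0.0
        dJ_dg = np.zeros(n)
        for c in range(nc):
            s = e[c] / dt
            sq = np.sqrt(s)
            r = q1m[c] - sq * q2m[c]
            J += r * r
            # d(sqrt s_c)/d gam_c = -1/(2 sq dt); /d gam_{c+1} = +1/(2 sq dt)
            inv2sq = 1.0 / (2.0 * sq * dt) if sq > 1e-8 else 0.0
            dr_dgc = -(0.5 * sq * dq2m[c]) + q2m[c] * inv2sq
            dr_dgc1 = -(0.5 * sq * dq2m[c]) - q2m[c] * inv2sq
            dJ_dg[c] += 2.0 * dt * r * dr_dgc
            dJ_dg[c + 1] += 2.0 * dt * r * dr_dgc1
        J *= dt
        dJ_de = np.empty(nc)
        acc = 0.0
        for c in range(nc - 1, -1, -1):
            acc += dJ_dg[c + 1]
            dJ_de[c] = acc
        dot = 0.0
        for c in range(nc):
            dot += dJ_de[c] * e[c]
        dJ_dv = np.empty(nc)
        for c in range(nc):
            dJ_dv[c] = e[c] * (dJ_de[c] - dot)
        return J, dJ_dv

    J, gvec = _eval(v)
    step = 1.0
    for _it in range(max_iter):
        gn2 = 0.0
        for c in range(nc):
            gn2 += gvec[c] * gvec[c]
        if gn2 < 1e-22:
            break
        ok = False
        for _bt in range(40):
            vn = v - step * gvec
            Jn, gn = _eval(vn)
            if Jn <= J - 1e-4 * step * gn2:
                v = vn
                J = Jn
                gvec = gn
                step *= 1.6
                ok = True
                break
            step *= 0.5
        if not ok:
            break
    mx = v.max()
    ex = np.exp(v - mx)
    e = ex / ex.sum()
    gam = np.empty(n)
    gam[0] = 0.0
    for c in range(nc):
        gam[c + 1] = gam[c] + e[c]
    gam[n - 1] = 1.0
    return gam


def _refine_warp(
    q1: np.ndarray,
    q2: np.ndarray,
    grid: np.ndarray,
    gamma0: np.ndarray,
    max_iter: int = 600,
) -> np.ndarray:
    """Continuous local refinement of a DP warp.

    The lattice path quantizes gamma' to a coarse set of rationals; the
    amplitude objective depends on sqrt(gamma'), so that quantization
    dominates the residual.  This pass minimizes the same midpoint-rule
    objective over all monotone gammas near the DP solution, with the
    increments e_c = gamma_{c+1} - gamma_c parameterized through a
    softmax so monotonicity and the boundary conditions hold by
    construction.
    """
    dq2 = np.gradient(q2, grid, edge_order=2)
    v0 = np.log(np.maximum(np.diff(gamma0), 1e-9))
    return _refine_core(
        np.ascontiguousarray(q1, dtype=np.float64),
        np.ascontiguousarray(q2, dtype=np.float64),
        dq2,
        grid,
        v0,
        max_iter,
    )


def _amplitude_from_warp(
    q1: np.ndarray, q2: np.ndarray, grid: np.ndarray, gamma: WarpingFunction
) -> float:
    """|| q1 - (q2 o gamma) sqrt(gamma') || with per-cell constant slopes.

    Matches the piecewise-linear structure of the DP warp: within each
    grid cell gamma' is constant, and the integrand is evaluated by the
    midpoint rule.  Midpoint sampling keeps the product
    q2(gamma) * sqrt(gamma') finite in cells where gamma is steep and q2
    vanishes at the cell edge.
    """
    dt = grid[1] - grid[0]
    slopes = np.diff(gamma.gamma) / dt
    sq = np.sqrt(np.maximum(slopes, 0.0))
    mid_t = 0.5 * (grid[:-1] + grid[1:])
    mid_g = 0.5 * (gamma.gamma[:-1] + gamma.gamma[1:])
    q1m = np.interp(mid_t, grid, q1)
    q2m = np.interp(mid_g, grid, q2)
    total = dt * np.sum((q1m - sq * q2m) ** 2)
    return float(np.sqrt(max(total, 0.0)))


def amplitude_distance(
    f1: FunctionalCurve, f2: FunctionalCurve, *, steps: np.ndarray | None = None
) -> float:
    """Amplitude (shape) distance after optimal warping; nonnegative."""
    return amplitude_phase_distance(f1, f2, steps=steps)[0]


def phase_distance(
    f1: FunctionalCurve, f2: FunctionalCurve, *, steps: np.ndarray | None = None
) -> float:
    """Phase (timing) distance arccos(integral sqrt(gamma*')), in [0, pi/2]."""
    return amplitude_phase_distance(f1, f2, steps=steps)[1]


def amplitude_phase_distance(
    f1: FunctionalCurve, f2: FunctionalCurve, *, steps: np.ndarray | None = None
) -> tuple[float, float]:
    """Both elastic components from a single alignment of f2 to f1."""
    if f1.n_points != f2.n_points:
        raise InvalidCurveError("curves must share one grid")
    q1 = srvf_transform(f1).qvalues
    q2 = srvf_transform(f2).qvalues
    return _amplitude_phase_srvf(q1, q2, f1.grid, steps)


def _amplitude_phase_srvf(
    q1: np.ndarray,
    q2: np.ndarray,
    grid: np.ndarray,
    steps: np.ndarray | None = None,
    *,
    refine: bool = True,
) -> tuple[float, float]:
    gamma = _align_srvf(q1, q2, grid, steps, refine=refine)
    d_amp = _amplitude_from_warp(q1, q2, grid, gamma)
    inner = min(gamma.sqrt_derivative_integral(), 1.0)  # Cauchy-Schwarz overshoot clamp
    d_phs = float(np.arccos(max(inner, -1.0)))
    return d_amp, d_phs


def elastic_distance(
    x: list[FunctionalCurve] | FunctionalCurve,
    c: list[FunctionalCurve] | FunctionalCurve,
    weights: DistanceWeights,
    *,
    steps: np.ndarray | None = None,
) -> float:
    """Weighted multi-axis elastic distance.

    Sum over axes h of w_p,h * d_phs(x_h, c_h) + w_a,h * d_amp(x_h, c_h).
    Each axis is aligned independently; the per-axis distances are then
    combined by the weights, which must sum to one overall.
    """
    xs = [x] if isinstance(x, FunctionalCurve) else list(x)
    cs = [c] if isinstance(c, FunctionalCurve) else list(c)
    if len(xs) != len(cs) or len(xs) != weights.n_axes:
        raise InvalidCurveError(
            f"axis-count mismatch: {len(xs)} vs {len(cs)} curves, {weights.n_axes} weight pairs"
        )
    total = 0.0
    for h, (xh, ch) in enumerate(zip(xs, cs)):
        wp = weights.phase[h]
        wa = weights.amplitude[h]
        if wp == 0.0 and wa == 0.0:
            continue
        d_amp, d_phs = amplitude_phase_distance(xh, ch, steps=steps)
        total += wp * d_phs + wa * d_amp
    return total
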