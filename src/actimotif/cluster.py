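"""Elastic-distance K-means over short-window activity segments.

Motifs — recurring short-window activity patterns — are found by a
K-means-style alternation under the weighted elastic distance:

1. sample K segments from the data as initial cluster centers,
2. assign every segment to the center at smallest elastic distance,
3. recompute each center as the pointwise mean of the raw (unaligned)
   member curves,
4. repeat until the fraction of segments changing label drops below a
   tolerance or an iteration cap is reached.

Because the center update is a plain pointwise mean while the assignment
metric is elastic, monotone descent of the total within-cluster distance
is not guaranteed; the objective is recorded per iteration but descent
is not enforced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .curves import DistanceWeights, FunctionalCurve
from .elastic import _amplitude_phase_srvf, srvf_transform

__all__ = [
    "ActivitySegment",
    "MotifModel",
    "initialize_centers",
    "assign_labels",
    "update_centers",
    "fit_motifs",
    "cluster_diagnostics",
    "select_k",
    "pairwise_elastic_distances",
]

logger = logging.getLogger(__name__)


class InvalidKError(ValueError):
    """Raised when the requested number of clusters is infeasible."""


@dataclass(frozen=True)
class ActivitySegment:
    """One short-window activity curve (per axis) on a normalized grid."""

    subject_id: str
    day_index: int
    window_index: int
    axes: tuple[FunctionalCurve, ...]
    window_min: int | None = None

    def __post_init__(self) -> None:
        axes = tuple(self.axes)
        if not axes:
            raise ValueError("segment needs at least one axis")
        grid = axes[0].grid
        for ax in axes[1:]:
            if ax.n_points != grid.size or not np.array_equal(ax.grid, grid):
                raise ValueError("all axes of a segment must share one grid")
        object.__setattr__(self, "axes", axes)

    @property
    def n_axes(self) -> int:
        return len(self.axes)

    @property
    def grid(self) -> np.ndarray:
        return self.axes[0].grid


@dataclass
class MotifModel:
    """Fitted motif clustering: centers, labels and diagnostics."""

    K: int
    centers: list[tuple[FunctionalCurve, ...]]
    weights: DistanceWeights
    labels: np.ndarray
    n_iter: int
    objective_trace: list[float]
    seed: int

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)


def _segment_qvalues(segments: list[ActivitySegment]) -> list[tuple[np.ndarray, ...]]:
    return [tuple(srvf_transform(ax).qvalues for ax in s.axes) for s in segments]


def _distance_to_center(
    seg_q: tuple[np.ndarray, ...],
    center_q: tuple[np.ndarray, ...],
    grid: np.ndarray,
    weights: DistanceWeights,
) -> float:
    total = 0.0
    for h, (qx, qc) in enumerate(zip(seg_q, center_q)):
        wp = weights.phase[h]
        wa = weights.amplitude[h]
        if wp == 0.0 and wa == 0.0:
            continue
        d_amp, d_phs = _amplitude_phase_srvf(qx, qc, grid)
        total += wp * d_phs + wa * d_amp
    return total


def initialize_centers(
    segments: list[ActivitySegment], K: int, seed: int
) -> list[tuple[FunctionalCurve, ...]]:
    """K distinct segments drawn without replacement as initial centers.

    Deterministic given the segment order, K and seed.
    """
    if K < 1 or K > len(segments):
        raise InvalidKError(f"K={K} must be in 1..{len(segments)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(segments), size=K, replace=False)
    return [segments[i].axes for i in idx]


def assign_labels(
    segments: list[ActivitySegment],
    centers: list[tuple[FunctionalCurve, ...]],
    weights: DistanceWeights,
    *,
    _seg_q: list[tuple[np.ndarray, ...]] | None = None,
) -> np.ndarray:
    """Label each segment with the nearest center (elastic distance).

    Ties break toward the lowest cluster index.
    """
    if not centers:
        raise InvalidKError("need at least one center")
    dists = _distance_matrix(segments, centers, weights, _seg_q=_seg_q)
    return np.argmin(dists, axis=1)


def _distance_matrix(
    segments: list[ActivitySegment],
    centers: list[tuple[FunctionalCurve, ...]],
    weights: DistanceWeights,
    *,
    _seg_q: list[tuple[np.ndarray, ...]] | None = None,
) -> np.ndarray:
    grid = segments[0].grid
    seg_q = _seg_q if _seg_q is not None else _segment_qvalues(segments)
    cen_q = [tuple(srvf_transform(c).qvalues for c in cen) for cen in centers]
    out = np.empty((len(segments), len(centers)))
    for i, sq in enumerate(seg_q):
        for k, cq in enumerate(cen_q):
            out[i, k] = _distance_to_center(sq, cq, grid, weights)
    return out


def update_centers(
    segments: list[ActivitySegment],
    labels: np.ndarray,
    K: int,
) -> list[tuple[FunctionalCurve | None, ...] | None]:
    """Pointwise mean of the raw member curves per cluster and axis.

    Empty clusters yield ``None``; the caller reseeds them.
    """
    grid = segments[0].grid
    H = segments[0].n_axes
    centers: list[tuple[FunctionalCurve, ...] | None] = []
    for k in range(K):
        members = [s for s, lab in zip(segments, labels) if lab == k]
        if not members:
            centers.append(None)
            continue
        axes = []
        for h in range(H):
            mean_vals = np.mean([m.axes[h].values for m in members], axis=0)
            axes.append(FunctionalCurve(grid, mean_vals))
        centers.append(tuple(axes))
    return centers


def fit_motifs(
    segments: list[ActivitySegment],
    K: int,
    weights: DistanceWeights | None = None,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 0.0,
    n_restarts: int = 1,
) -> MotifModel:
    """Elastic K-means over activity segments.

    Stops when the fraction of segments that changed label is <= ``tol``
    (default 0: stop only on a fully stable labeling) or after
    ``max_iter`` iterations.  Empty clusters are reseeded with the
    segment farthest from the empty cluster's previous center.

    Random-segment initialization is sensitive to the draw; with
    ``n_restarts`` > 1 the fit is repeated from restart seeds derived
    from ``seed`` and the run with the smallest final within-cluster
    objective is returned (still fully deterministic given ``seed``).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if n_restarts > 1:
        runs = [
            fit_motifs(segments, K, weights, seed=seed + 7919 * r, max_iter=max_iter, tol=tol)
            for r in range(n_restarts)
        ]
        return min(runs, key=lambda m: m.objective_trace[-1])
    if not segments:
        raise ValueError("no segments to cluster")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if weights is None:
        weights = DistanceWeights.equal(segments[0].n_axes)
    if weights.n_axes != segments[0].n_axes:
        raise ValueError("weights axis count must match segments")

    seg_q = _segment_qvalues(segments)
    centers = initialize_centers(segments, K, seed)
    labels = np.full(len(segments), -1)
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dists = _distance_matrix(segments, centers, weights, _seg_q=seg_q)
        new_labels = np.argmin(dists, axis=1)
        trace.append(float(dists[np.arange(len(segments)), new_labels].sum()))
        changed = float(np.mean(new_labels != labels))
        labels = new_labels
        new_centers = update_centers(segments, labels, K)
        for k, cen in enumerate(new_centers):
            if cen is None:  # reseed from the farthest segment
                far = int(np.argmax(dists[:, k]))
                logger.warning("cluster %d empty; reseeding with segment %d", k, far)
                new_centers[k] = segments[far].axes
        centers = new_centers
        if changed <= tol and n_iter > 1:
            break
    return MotifModel(
        K=K,
        centers=centers,
        weights=weights,
        labels=labels,
        n_iter=n_iter,
        objective_trace=trace,
        seed=seed,
    )


def pairwise_elastic_distances(
    segments: list[ActivitySegment],
    weights: DistanceWeights | None = None,
) -> np.ndarray:
    """Symmetrized matrix of elastic distances between all segment pairs.

    Each pair is aligned once, in index order; the matrix is mirrored.
    """
    if weights is None:
        weights = DistanceWeights.equal(segments[0].n_axes)
    n = len(segments)
    grid = segments[0].grid
    seg_q = _segment_qvalues(segments)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _distance_to_center(seg_q[i], seg_q[j], grid, weights)
    return D


@dataclass
class ClusterDiagnostics:
    """Cluster-quality summaries for a fitted motif model."""

    K: int
    within_total: float
    between_total: float
    within_between_ratio: float  # NaN when K = 1
    silhouette: float  # NaN when K = 1
    cluster_sizes: np.ndarray = field(default_factory=lambda: np.array([]))


def cluster_diagnostics(
    segments: list[ActivitySegment],
    model: MotifModel,
    *,
    pairwise: np.ndarray | None = None,
) -> ClusterDiagnostics:
    """Within/between elastic variation ratio and mean silhouette width.

    The ratio divides the total within-cluster segment-to-center
    distance by the total center-to-center distance; the silhouette is
    computed on the pairwise elastic-distance matrix (passed in via
    ``pairwise`` to avoid recomputation across a K grid).
    """
    from sklearn.metrics import silhouette_score

    dists = _distance_matrix(segments, model.centers, model.weights)
    within = float(dists[np.arange(len(segments)), model.labels].sum())
    if model.K == 1:
        return ClusterDiagnostics(
            K=1,
            within_total=within,
            between_total=np.nan,
            within_between_ratio=np.nan,
            silhouette=np.nan,
            cluster_sizes=model.cluster_sizes,
        )
    between = 0.0
    grid = segments[0].grid
    cen_q = [tuple(srvf_transform(c).qvalues for c in cen) for cen in model.centers]
    for a in range(model.K):
        for b in range(a + 1, model.K):
            between += _distance_to_center(cen_q[a], cen_q[b], grid, model.weights)
    if pairwise is None:
        pairwise = pairwise_elastic_distances(segments, model.weights)
    if np.unique(model.labels).size < 2:
        sil = np.nan
    else:
        sil = float(silhouette_score(pairwise, model.labels, metric="precomputed"))
    ratio = within / between if between > 0 else np.inf
    return ClusterDiagnostics(
        K=model.K,
        within_total=within,
        between_total=float(between),
        within_between_ratio=float(ratio),
        silhouette=sil,
        cluster_sizes=model.cluster_sizes,
    )


def select_k(
    segments: list[ActivitySegment],
    k_grid: list[int],
    weights: DistanceWeights | None = None,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 0.0,
):
    """Fit every K in ``k_grid`` and tabulate diagnostics.

    Returns a pandas DataFrame with one row per K (columns: K, within,
    between, within_between_ratio, silhouette, n_iter).  The choice of K
    is left to the user; the table supports the usual multi-criteria
    reading (elbow in the ratio, peak silhouette).
    """
    import pandas as pd

    if any(k < 2 for k in k_grid):
        raise InvalidKError("k_grid entries must be >= 2")
    if weights is None:
        weights = DistanceWeights.equal(segments[0].n_axes)
    pairwise = pairwise_elastic_distances(segments, weights)
    rows = []
    models = {}
    for k in k_grid:
        model = fit_motifs(segments, k, weights, seed=seed, max_iter=max_iter, tol=tol)
        diag = cluster_diagnostics(segments, model, pairwise=pairwise)
        models[k] = model
        rows.append(
            {
                "K": k,
                "within": diag.within_total,
                "between": diag.between_total,
                "within_between_ratio": diag.within_between_ratio,
                "silhouette": diag.silhouette,
                "n_iter": model.n_iter,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["models"] = models
    return table
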