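"""Daily cluster-mean activity functions and FPCA digital biomarkers.

For each subject i, day d and motif (cluster) k, the daily cluster mean
A_id^(k)(t) is the pointwise average of the day's segments assigned to
that motif, or the zero function when the day has no such segments.
Functional principal component analysis of the sample {A_id^(k)} within
each cluster yields a mean function mu^(k), orthonormal eigenfunctions
phi_p^(k) and scores

    xi_idp^(k) = < A_id^(k) - mu^(k), phi_p^(k) >,

computed by trapezoidal quadrature on the common grid.  The truncated
score vectors are the digital biomarkers used downstream in association
and classification models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ActivitySegment, MotifModel
from .curves import FunctionalCurve

__all__ = [
    "DailyClusterMean",
    "FPCAModel",
    "BiomarkerTable",
    "daily_cluster_means",
    "fit_fpca",
    "extract_scores",
    "score_column",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DailyClusterMean:
    """Mean activity function of one (subject, day, cluster) cell."""

    subject_id: str
    day_index: int
    cluster_id: int
    mean_curve: FunctionalCurve
    n_members: int

    def __post_init__(self) -> None:
        if self.n_members == 0 and np.any(self.mean_curve.values != 0):
            raise ValueError("empty (subject, day, cluster) cells must carry the zero function")


@dataclass
class FPCAModel:
    """Truncated Karhunen-Loeve decomposition of one cluster's daily means."""

    cluster_id: int
    grid: np.ndarray
    mean_function: np.ndarray
    eigenfunctions: np.ndarray  # (P, n_grid), orthonormal under quadrature
    eigenvalues: np.ndarray  # (P,), nonincreasing
    explained_fraction: np.ndarray  # (P,), relative to total variance
    n_components: int

    def scores(self, curves: np.ndarray) -> np.ndarray:
        """Project curves (rows) onto the eigenfunctions by quadrature."""
        w = _trapezoid_weights(self.grid)
        centered = np.atleast_2d(curves) - self.mean_function
        return centered @ (self.eigenfunctions * w).T


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.full(grid.size, grid[1] - grid[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


def daily_cluster_means(
    segments: list[ActivitySegment],
    labels: np.ndarray,
    K: int,
    axis: int = 0,
) -> list[DailyClusterMean]:
    """A_id^(k) for every (subject, day) present and every cluster k.

    Days with no member segments in a cluster contribute the zero
    function with ``n_members = 0``.
    """
    if len(labels) != len(segments):
        raise ValueError("labels must match segments")
    grid = segments[0].grid
    by_day: dict[tuple[str, int], dict[int, list[np.ndarray]]] = {}
    for seg, lab in zip(segments, labels):
        day_key = (seg.subject_id, seg.day_index)
        by_day.setdefault(day_key, {}).setdefault(int(lab), []).append(seg.axes[axis].values)
    out = []
    for (subject, day), clusters in sorted(by_day.items()):
        for k in range(K):
            members = clusters.get(k, [])
            if members:
                curve = FunctionalCurve(grid, np.mean(members, axis=0))
            else:
                curve = FunctionalCurve(grid, np.zeros(grid.size))
            out.append(
                DailyClusterMean(
                    subject_id=subject,
                    day_index=day,
                    cluster_id=k,
                    mean_curve=curve,
                    n_members=len(members),
                )
            )
    return out


def fit_fpca(
    means: list[DailyClusterMean],
    variance_target: float = 0.80,
    n_components: int | None = None,
) -> FPCAModel:
    """FPCA of one cluster's daily mean functions.

    Eigendecomposition of the sample covariance about the cluster mean
    under trapezoidal quadrature.  The truncation order P is the
    smallest p whose cumulative explained fraction reaches
    ``variance_target`` (default 0.80), unless ``n_components`` fixes P
    explicitly (reduced with a warning if fewer informative components
    exist).  Eigenfunction signs are fixed so <phi_p, 1> >= 0, falling
    back to a positive largest-magnitude coordinate.
    """
    if len(means) < 3:
        raise ValueError("need at least 3 curves for FPCA")
    cluster_ids = {m.cluster_id for m in means}
    if len(cluster_ids) != 1:
        raise ValueError("fit_fpca expects the means of a single cluster")
    grid = means[0].mean_curve.grid
    X = np.vstack([m.mean_curve.values for m in means])
    mu = X.mean(axis=0)
    Xc = X - mu
    w = _trapezoid_weights(grid)
    sw = np.sqrt(w)
    # covariance operator in the quadrature-weighted coordinates
    M = (Xc * sw) .T @ (Xc * sw) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    tol = max(total, 1.0) * 1e-12
    n_pos = int(np.sum(evals > tol))
    if total <= tol:  # all curves identical: no variation to decompose
        return FPCAModel(
            cluster_id=means[0].cluster_id,
            grid=grid,
            mean_function=mu,
            eigenfunctions=np.empty((0, grid.size)),
            eigenvalues=np.empty(0),
            explained_fraction=np.empty(0),
            n_components=0,
        )
    fractions = evals / total
    if n_components is not None:
        P = n_components
        if P > n_pos:
            logger.warning("requested P=%d but only %d informative components; reducing", P, n_pos)
            P = n_pos
    else:
        P = int(np.searchsorted(np.cumsum(fractions), variance_target) + 1)
        P = min(P, n_pos)
    phi = (evecs[:, :P] / sw[:, None]).T
    for p in range(P):  # sign convention for reproducibility
        s = np.sum(phi[p] * w)
        if abs(s) < 1e-10:
            s = phi[p][np.argmax(np.abs(phi[p]))]
        if s < 0:
            phi[p] = -phi[p]
    return FPCAModel(
        cluster_id=means[0].cluster_id,
        grid=grid,
        mean_function=mu,
        eigenfunctions=phi,
        eigenvalues=evals[:P],
        explained_fraction=fractions[:P],
        n_components=P,
    )


def score_column(cluster_id: int, component: int) -> str:
    """Column name for the FPC score of motif k, component p (1-based p)."""
    return f"m{cluster_id + 1}_fpc{component}"


@dataclass
class BiomarkerTable:
    """FPC scores per (subject, day) with optional covariates and outcome.

    ``frame`` holds one row per (subject, day); ``score_cols`` name the
    K*P score columns, ``covariate_cols`` any subject covariates, and
    ``outcome_col`` the binary outcome when present.
    """

    frame: pd.DataFrame
    score_cols: list[str]
    covariate_cols: list[str]
    outcome_col: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.score_cols + self.covariate_cols if c not in self.frame]
        if missing:
            raise ValueError(f"columns missing from frame: {missing}")
        if self.outcome_col is not None and self.outcome_col not in self.frame:
            raise ValueError(f"outcome column {self.outcome_col!r} missing")

    def with_outcome(
        self, outcome_by_subject: dict[str, int], column: str = "y"
    ) -> "BiomarkerTable":
        frame = self.frame.copy()
        frame[column] = frame["subject"].map(outcome_by_subject)
        if frame[column].isna().any():
            raise ValueError("outcome missing for some subjects")
        frame[column] = frame[column].astype(int)
        return BiomarkerTable(frame, self.score_cols, self.covariate_cols, column)

    def with_covariates(
        self, covariates: pd.DataFrame, on: str = "subject"
    ) -> "BiomarkerTable":
        cols = [c for c in covariates.columns if c != on]
        frame = self.frame.merge(covariates, on=on, how="left")
        return BiomarkerTable(frame, self.score_cols, self.covariate_cols + cols, self.outcome_col)


def extract_scores(
    means: list[DailyClusterMean],
    fpca_models: dict[int, FPCAModel],
) -> BiomarkerTable:
    """Assemble the (subject, day) x (cluster, component) score table."""
    grid = means[0].mean_curve.grid
    for model in fpca_models.values():
        if model.grid.size != grid.size or not np.array_equal(model.grid, grid):
            raise ValueError("FPCA model grid does not match the daily means")
    rows: dict[tuple[str, int], dict[str, float]] = {}
    for m in means:
        model = fpca_models.get(m.cluster_id)
        if model is None:
            raise ValueError(f"no FPCA model for cluster {m.cluster_id}")
        key = (m.subject_id, m.day_index)
        rec = rows.setdefault(key, {})
        scores = model.scores(m.mean_curve.values[None, :])[0]
        for p in range(model.n_components):
            rec[score_column(m.cluster_id, p + 1)] = scores[p]
    frame = pd.DataFrame(
        [{"subject": s, "day": d, **rec} for (s, d), rec in sorted(rows.items())]
    )
    score_cols = [c for c in frame.columns if c not in ("subject", "day")]
    return BiomarkerTable(frame, score_cols, [])
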