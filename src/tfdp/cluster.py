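"""Two-parameter k-means (k = 2) on the (T1m, T2m) biomarker.

Subjects are clustered on raw, unstandardized degC coordinates (both axes are
temperatures on comparable scales).  The cluster with the lower T1m center is
named the glaucoma-like ("POAG-like") population, matching the observed
pattern that glaucomatous profiles shift T1m down and T2m up.

Lloyd's algorithm is run from multiple random two-point initialisations and
the lowest-inertia solution is kept; an empty cluster during iteration is
reseeded to the point farthest from its assigned center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidInputError

__all__ = ["ClusterResult", "kmeans_two", "cross_tab"]

_MAX_ITER = 300


@dataclass(frozen=True)
class ClusterResult:
    """Result of a 2-means run on (t1m, t2m) points.

    ``poag_like_cluster`` is the index of the lower-T1m center.
    """

    centers: np.ndarray  # (2, 2): rows are centers, columns (t1m, t2m)
    assignments: np.ndarray  # (n,) in {0, 1}
    inertia: float
    n_restarts: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.centers.shape != (2, 2):
            raise InvalidInputError("expected exactly 2 centers in 2 dimensions")
        if self.inertia < 0:
            raise InvalidInputError("inertia must be >= 0")

    @property
    def poag_like_cluster(self) -> int:
        return int(np.argmin(self.centers[:, 0]))

    def summary(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "inertia": float(self.inertia),
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "poag_like_cluster": self.poag_like_cluster,
            "cluster_sizes": np.bincount(self.assignments, minlength=2).tolist(),
        }


def _lloyd(pts: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    n = len(pts)
    assign = None
    for _ in range(_MAX_ITER):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new = d2.argmin(axis=1)
        for k in (0, 1):
            if not np.any(new == k):
                far = int(d2[np.arange(n), new].argmax())
                centers[k] = pts[far]
                d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
                new = d2.argmin(axis=1)
        if assign is not None and np.array_equal(new, assign):
            break
        assign = new
        for k in (0, 1):
            centers[k] = pts[assign == k].mean(axis=0)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2[np.arange(n), assign].sum())
    return centers, assign, inertia


def kmeans_two(
    points: np.ndarray | list,
    n_restarts: int = 50,
    seed: int | None = None,
    standardize: bool = False,
) -> ClusterResult:
    """Cluster (t1m, t2m) points into two groups with restarted Lloyd's k-means.

    Each restart initialises the centers with two distinct points sampled
    without replacement; the best-inertia restart wins.  Deterministic for a
    given seed.  ``standardize=True`` z-scores the two axes before clustering
    (centers are reported back in degC); the default clusters raw degC.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an (n, 2) array of (t1m, t2m)")
    if len(pts) < 2 or not np.all(np.isfinite(pts)):
        raise InvalidInputError("need >= 2 finite points")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 2:
        raise DegenerateInputError("all points are identical; 2-means is undefined")
    if n_restarts < 1:
        raise InvalidInputError("n_restarts must be >= 1")

    work = pts
    mu = sigma = None
    if standardize:
        mu = pts.mean(axis=0)
        sigma = pts.std(axis=0)
        sigma[sigma == 0] = 1.0
        work = (pts - mu) / sigma

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    n = len(work)
    for _ in range(n_restarts):
        for _ in range(100):
            i, j = rng.choice(n, size=2, replace=False)
            if not np.allclose(work[i], work[j]):
                break
        centers0 = work[[i, j]].copy()
        centers, assign, inertia = _lloyd(work, centers0)
        if best is None or inertia < best[2]:
            best = (centers, assign, inertia)
    centers, assign, inertia = best
    if standardize:
        centers = centers * sigma + mu
        inertia = float(((pts - centers[assign]) ** 2).sum())
    return ClusterResult(
        centers=centers, assignments=assign, inertia=inertia, n_restarts=n_restarts, seed=seed
    )


def cross_tab(result: ClusterResult, labels) -> tuple[pd.DataFrame, pd.Series]:
    """Contingency table of cluster x label, plus per-label positive fraction.

    "Positive" means assignment to the POAG-like (lower-T1m) cluster; the
    returned series gives, for each label, the fraction of its samples in
    that cluster (fractions over clusters sum to 1 within each label).
    """
    labels = np.asarray(labels)
    if len(labels) != len(result.assignments):
        raise InvalidInputError("labels and assignments lengths differ")
    table = pd.crosstab(
        pd.Series(result.assignments, name="cluster"), pd.Series(labels, name="label")
    )
    table = table.reindex(index=[0, 1], fill_value=0)
    positive = table.loc[result.poag_like_cluster] / table.sum(axis=0)
    positive.name = "positive_fraction"
    return table, positive
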