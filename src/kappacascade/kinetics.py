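"""Kinetic clustering of fold-change profiles.

Responsive genes' log2 fold-change profiles over 1/4/18 h (optionally
concatenated control+perturbed for contrast runs) are row z-scored and
clustered by MATLAB-style k-means with correlation distance
d(x, c) = 1 - Pearson(x, c): Lloyd iterations with a mean-then-restandardize
centroid update, k-means++ style seeding adapted to the correlation metric,
and the best of several restarts kept by total within-cluster distance.
Cluster centroids are then labeled with kinetic classes (transient-early /
intermediate / late and their down-regulated mirrors) from the
control-condition segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "ClusterResult",
    "zscore_profiles",
    "kmeans_corr",
    "label_clusters",
    "UP_CLASSES",
    "DOWN_CLASSES",
]

UP_CLASSES = ("transient_early", "intermediate", "late")
DOWN_CLASSES = ("down_transient_early", "down_intermediate", "down_late")


@dataclass
class ProfileMatrix:
    genes: pd.Index
    conditions: list[str]
    times: list[int]
    values: np.ndarray  # genes x (len(conditions)*len(times)), row z-scored
    zero_variance: np.ndarray  # bool per gene

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def condition_segment(self, condition: str) -> np.ndarray:
        i = self.conditions.index(condition)
        k = len(self.times)
        return self.values[:, i * k:(i + 1) * k]


def zscore_profiles(fc: pd.DataFrame, genes, conditions: list[str]) -> ProfileMatrix:
    """Row-standardized fold-change profiles, conditions concatenated.

    ``fc`` carries a (condition, time) column MultiIndex as produced by
    :func:`kappacascade.diffexpr.fold_changes`.  Zero-variance rows are set
    to all-zero and flagged.
    """
    times = sorted({t for c, t in fc.columns if c == conditions[0]})
    cols = [(c, t) for c in conditions for t in times]
    sub = fc.loc[list(genes), cols]
    vals = sub.values.astype(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    zero = sd[:, 0] == 0
    sd[zero] = 1.0
    z = (vals - mean) / sd
    z[zero] = 0.0
    return ProfileMatrix(genes=sub.index, conditions=list(conditions),
                         times=[int(t) for t in times], values=z, zero_variance=zero)


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # gene -> cluster index
    centroids: np.ndarray  # k x n_features (z-scored)
    total_distance: float
    restarts_used: int
    kinetic_class: dict[int, str] = field(default_factory=dict)
    seed: int | None = None

    def genes_in(self, cluster: int) -> pd.Index:
        return self.assignments.index[self.assignments == cluster]


def _row_standardize(x: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm so correlation = dot product."""
    c = x - x.mean(axis=1, keepdims=True)
    n = np.linalg.norm(c, axis=1, keepdims=True)
    zero = n[:, 0] == 0
    n[zero] = 1.0
    out = c / n
    out[zero] = 0.0
    return out


def _corr_dist(xn: np.ndarray, cn: np.ndarray) -> np.ndarray:
    """1 - Pearson for pre-standardized rows; zero rows -> distance 1."""
    d = 1.0 - xn @ cn.T
    zero_x = np.all(xn == 0, axis=1)
    zero_c = np.all(cn == 0, axis=1)
    d[zero_x, :] = 1.0
    d[:, zero_c] = 1.0
    return d


def _seed_centroids(xn: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding on the correlation metric."""
    n = len(xn)
    first = int(rng.integers(n))
    idx = [first]
    d = _corr_dist(xn, xn[[first]])[:, 0]
    for _ in range(1, k):
        w = np.maximum(d, 0.0) ** 2
        total = w.sum()
        if total <= 0:
            cand = int(rng.integers(n))
        else:
            cand = int(rng.choice(n, p=w / total))
        idx.append(cand)
        d = np.minimum(d, _corr_dist(xn, xn[[cand]])[:, 0])
    return xn[idx].copy()


def _lloyd(xn: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300):
    cn = _seed_centroids(xn, k, rng)
    assign = np.full(len(xn), -1)
    for _ in range(max_iter):
        d = _corr_dist(xn, cn)
        new_assign = d.argmin(axis=1)
        # empty cluster -> reseed at the point farthest from its centroid
        for c in range(k):
            if not np.any(new_assign == c):
                far = int(d[np.arange(len(xn)), new_assign].argmax())
                cn[c] = xn[far]
                new_assign[far] = c
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            members = xn[assign == c]
            if len(members):
                cn[c] = _row_standardize(members.mean(axis=0, keepdims=True))[0]
    d = _corr_dist(xn, cn)
    total = float(d[np.arange(len(xn)), assign].sum())
    return assign, cn, total


def kmeans_corr(profiles: ProfileMatrix, k: int, restarts: int = 5,
                seed: int = 0, max_iter: int = 300) -> ClusterResult:
    """Best-of-restarts correlation-distance k-means; deterministic under seed."""
    X = profiles.values
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer distinct rows than k")
    xn = _row_standardize(X)
    best = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        assign, cn, total = _lloyd(xn, k, rng, max_iter)
        if best is None or total < best[2]:
            best = (assign, cn, total)
    assign, cn, total = best
    res = ClusterResult(
        k=k,
        assignments=pd.Series(assign, index=profiles.genes, name="cluster"),
        centroids=cn,
        total_distance=total,
        restarts_used=restarts,
        seed=seed,
    )
    res.kinetic_class = label_clusters(res, profiles)
    return res


def label_clusters(res: ClusterResult, profiles: ProfileMatrix,
                   control_condition: str | None = None) -> dict[int, str]:
    """Kinetic class of each cluster from the control-condition centroid shape.

    Up rubric (applied when the extreme of the control segment is positive):
    argmax at 1 h with the 18 h value below half the max -> transient_early;
    argmax at 4 h -> intermediate; argmax at 18 h -> late.  The mirrored
    rubric on the argmin yields the down classes; anything else is mixed.
    """
    conditions = profiles.conditions
    ctrl = conditions[0] if control_condition is None else control_condition
    i = conditions.index(ctrl)
    ntime = len(profiles.times)
    labels: dict[int, str] = {}
    for c in range(res.k):
        seg = res.centroids[c, i * ntime:(i + 1) * ntime]
        labels[c] = _label_segment(seg)
    return labels


def _label_segment(seg: np.ndarray) -> str:
    hi, lo = float(seg.max()), float(seg.min())
    if hi >= -lo:  # predominantly induced
        i = int(seg.argmax())
        if i == 0:
            return "transient_early" if seg[-1] < 0.5 * hi else "mixed"
        if i == 1:
            return "intermediate"
        return "late"
    j = int(seg.argmin())
    if j == 0:
        return "down_transient_early" if seg[-1] > 0.5 * lo else "mixed"
    if j == 1:
        return "down_intermediate"
    return "down_late"
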