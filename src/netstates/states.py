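"""Recurring connectivity states by k-means and per-subject temporal properties.

Pooled dynamic-connectivity frames from all subjects are clustered with
the cityblock (L1) distance.  The Lloyd-style alternation uses the exact
L1 centroid update (coordinatewise median).  The number of states is
selected by the mean silhouette width under cityblock distances, with the
Calinski-Harabasz index recorded alongside; states are renumbered so that
state 1 is the most strongly connected (largest mean off-diagonal
centroid value).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import groupby

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score, silhouette_score

__all__ = [
    "StateResult",
    "TemporalProperties",
    "kmeans_cityblock",
    "select_k",
    "temporal_properties",
    "renumber_by_strength",
    "cluster_states",
]

logger = logging.getLogger(__name__)


@dataclass
class StateResult:
    k: int
    centroids: np.ndarray  # k x pair-dimension
    labels: dict[str, np.ndarray]  # subject -> per-frame labels in 1..k
    selection_scores: dict[int, dict[str, float]] = field(default_factory=dict)


@dataclass
class TemporalProperties:
    fraction_time: np.ndarray  # per state
    mean_dwell_time: np.ndarray  # per state, frames (0 if state absent)
    n_transitions: int


@njit(cache=True)
def _l1_assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid L1 assignment with early distance abandonment."""
    n, d = X.shape
    k = centroids.shape[0]
    labels = np.empty(n, dtype=np.int64)
    dmin = np.empty(n)
    for i in range(n):
        best = 0
        bd = np.inf
        for c in range(k):
            s = 0.0
            for j in range(d):
                s += abs(X[i, j] - centroids[c, j])
                if s >= bd:
                    break
            if s < bd:
                bd = s
                best = c
        labels[i] = best
        dmin[i] = bd
    return labels, dmin


def _lloyd_l1(X: np.ndarray, init: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    centroids = init.copy()
    k = centroids.shape[0]
    labels = np.full(X.shape[0], -1, dtype=np.int64)
    for _ in range(max_iter):
        new_labels, dmin = _l1_assign(X, centroids)
        for c in range(k):
            members = X[new_labels == c]
            if members.shape[0] == 0:
                # reseed the empty centroid at the farthest point
                far = int(dmin.argmax())
                logger.info("reseeding empty cluster %d at point %d", c, far)
                centroids[c] = X[far]
                new_labels[far] = c
            else:
                centroids[c] = np.median(members, axis=0)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    _, dfinal = _l1_assign(X, centroids)
    cost = float(dfinal.sum())
    return centroids, labels, cost


def kmeans_cityblock(
    frames_matrix: np.ndarray, k: int, n_replicates: int = 20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Best-of-n_replicates L1 k-means (k-medians) on pooled frames.

    Returns (centroids, labels); labels are 0-based here, the pipeline
    wrapper converts to the 1-based state convention.
    """
    X = np.asarray(frames_matrix, dtype=float)
    if k < 1 or X.shape[0] < k:
        raise ValueError("need at least k rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_replicates, 1)):
        init = X[rng.choice(X.shape[0], size=k, replace=False)]
        centroids, labels, cost = _lloyd_l1(X, init)
        if best is None or cost < best[2]:
            best = (centroids, labels, cost)
    return best[0], best[1]


def select_k(
    frames_matrix: np.ndarray,
    k_range: range | list[int] = range(2, 9),
    n_replicates: int = 20,
    seed: int = 0,
) -> tuple[int, dict[int, dict[str, float]]]:
    """Scan candidate state counts; pick the silhouette maximizer.

    The mean silhouette width uses cityblock distances (precomputed once);
    the Calinski-Harabasz index (L2 dispersion ratio) is recorded for each
    candidate.  When the two criteria disagree the silhouette choice wins
    and the disagreement is logged.
    """
    X = np.asarray(frames_matrix, dtype=float)
    ks = sorted(k_range)
    if not ks or min(ks) < 2 or max(ks) > X.shape[0] - 1:
        raise ValueError("k_range must be a non-empty subset of {2..rows-1}")
    D = squareform(pdist(X, metric="cityblock"))
    scores: dict[int, dict[str, float]] = {}
    for k in ks:
        centroids, labels = kmeans_cityblock(X, k, n_replicates, seed)
        if len(np.unique(labels)) < 2:
            scores[k] = {"silhouette": -1.0, "calinski_harabasz": 0.0}
            continue
        sil = float(silhouette_score(D, labels, metric="precomputed"))
        ch = float(calinski_harabasz_score(X, labels))
        scores[k] = {"silhouette": sil, "calinski_harabasz": ch}
    by_sil = max(ks, key=lambda k: scores[k]["silhouette"])
    by_ch = max(ks, key=lambda k: scores[k]["calinski_harabasz"])
    if by_ch != by_sil:
        logger.info("silhouette (k=%d) and Calinski-Harabasz (k=%d) disagree", by_sil, by_ch)
    if scores[by_sil]["silhouette"] < 0.3:
        warnings.warn(
            f"weak cluster structure: best silhouette {scores[by_sil]['silhouette']:.3f} < 0.3",
            stacklevel=2,
        )
    return by_sil, scores


def temporal_properties(labels: np.ndarray, k: int) -> TemporalProperties:
    """Fraction time, mean dwell time, and transition count of one subject.

    ``labels`` are 1-based per-frame state assignments.
    """
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("labels must be non-empty")
    if lab.min() < 1 or lab.max() > k:
        raise ValueError("label out of range 1..k")
    T = lab.size
    ft = np.array([np.mean(lab == s) for s in range(1, k + 1)])
    mdt = np.zeros(k)
    runs: dict[int, list[int]] = {}
    for s, grp in groupby(lab):
        runs.setdefault(int(s), []).append(len(list(grp)))
    for s, lens in runs.items():
        mdt[s - 1] = float(np.mean(lens))
    n_trans = int(np.sum(lab[1:] != lab[:-1]))
    return TemporalProperties(ft, mdt, n_trans)


def renumber_by_strength(
    centroids: np.ndarray, offdiag_mask: np.ndarray | None = None
) -> np.ndarray:
    """Permutation mapping old state index -> rank by connectivity strength.

    Strength is the mean centroid value over ``offdiag_mask`` columns (all
    columns when no mask is given); rank 0 = strongest, so the reported
    state 1 is the strongly connected one.
    """
    C = centroids if offdiag_mask is None else centroids[:, offdiag_mask]
    order = np.argsort(-C.mean(axis=1), kind="stable")
    perm = np.empty_like(order)
    perm[order] = np.arange(order.size)
    return perm


def cluster_states(
    tensors: dict[str, np.ndarray],
    k: int | None = None,
    k_range: range | list[int] = range(2, 9),
    n_replicates: int = 20,
    seed: int = 0,
    offdiag_mask: np.ndarray | None = None,
) -> StateResult:
    """Pool per-subject dFC frames, cluster, renumber, and split labels back.

    ``tensors`` maps subject id -> frames x pairs matrix.  When ``k`` is
    None it is selected via :func:`select_k`.
    """
    ids = list(tensors)
    X = np.vstack([tensors[s] for s in ids])
    scores: dict[int, dict[str, float]] = {}
    if k is None:
        k, scores = select_k(X, k_range, n_replicates, seed)
    centroids, labels0 = kmeans_cityblock(X, k, n_replicates, seed)
    perm = renumber_by_strength(centroids, offdiag_mask)
    centroids = centroids[np.argsort(perm)]
    relabeled = perm[labels0] + 1
    out: dict[str, np.ndarray] = {}
    start = 0
    for s in ids:
        n = tensors[s].shape[0]
        out[s] = relabeled[start : start + n]
        start += n
    return StateResult(k=k, centroids=centroids, labels=out, selection_scores=scores)
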