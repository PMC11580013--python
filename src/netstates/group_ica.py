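"""Group spatial ICA with stability analysis and dual regression.

Multi-subject voxels x time data are reduced by PCA along the time
dimension, unmixed by natural-gradient infomax ICA (logistic
nonlinearity), and stabilized by repeated runs whose pooled estimates are
agglomeratively clustered (ICASSO): each cluster's centrotype is the
retained component and its quality index Iq is the mean within-cluster
minus mean between-cluster absolute correlation.  Subject-specific time
courses and maps come from two-stage (spatial-temporal / dual)
regression.  Components are matched to template masks by the Dice
similarity coefficient and retained when both the Dice match and the
low-frequency fraction of their time-course power pass thresholds.

The model order can be estimated from the eigenvalue spectrum with the
Wax-Kailath minimum-description-length criterion (no i.i.d.-violation
correction is applied to the sample count; see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import expit

__all__ = [
    "ICAResult",
    "StableICAResult",
    "SubjectComponentSet",
    "PcaReduction",
    "ComponentSelection",
    "estimate_order_mdl",
    "pca_reduce",
    "infomax_ica",
    "icasso",
    "back_reconstruct",
    "dice_coefficient",
    "select_components",
]


@dataclass
class ICAResult:
    mixing_matrix: np.ndarray  # k x k (in the reduced space)
    source_maps: np.ndarray  # k x voxels, unit-variance rows
    n_iterations: int
    final_step_norm: float
    converged: bool


@dataclass
class StableICAResult:
    centrotype_maps: np.ndarray  # k x voxels
    stability_index: np.ndarray  # Iq per component, sorted non-increasing
    run_count: int


@dataclass
class SubjectComponentSet:
    subject_id: str
    spatial_maps: np.ndarray  # k x voxels
    timecourses: np.ndarray  # frames x k


@dataclass
class PcaReduction:
    reduced: np.ndarray  # k x samples
    basis: np.ndarray  # time x k eigenvectors
    eigenvalues: np.ndarray  # all eigenvalues, descending

    def back_project(self) -> np.ndarray:
        """Reconstruct the (centered) voxels x time data."""
        return self.reduced.T @ self.basis.T


@dataclass
class ComponentSelection:
    indices: list[int]
    labels: list[str]
    dice: list[float]
    lf_power: list[float]


def estimate_order_mdl(data: np.ndarray) -> int:
    """Wax-Kailath MDL estimate of the number of signal components.

    Eigenvalues of the time-dimension covariance (voxels as samples) feed
    the MDL criterion; the arg-min over candidate orders k is returned
    (at least 1).  Rank-deficient data are truncated to the numerical
    rank with a warning.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need voxels x time data with time >= 2")
    n_samples, p = X.shape
    Xc = X - X.mean(axis=0)
    ev = np.linalg.eigvalsh(Xc.T @ Xc / max(n_samples - 1, 1))[::-1]
    tol = max(p, n_samples) * np.finfo(float).eps * max(ev[0], 1.0)
    rank = int(np.sum(ev > tol))
    if rank < p:
        warnings.warn(
            f"rank-deficient data (rank {rank} < {p}): rank-limited MDL estimate",
            stacklevel=2,
        )
    ev = ev[:rank]
    if rank == 1:
        return 1
    mdl = np.empty(rank)
    N = n_samples
    for k in range(rank):
        tail = ev[k:]
        m = tail.size
        geo = np.exp(np.mean(np.log(tail)))
        arith = np.mean(tail)
        mdl[k] = -N * m * np.log(geo / arith) + 0.5 * k * (2 * p - k) * np.log(N)
    return max(int(np.argmin(mdl)), 1)


def pca_reduce(data: np.ndarray, k: int) -> PcaReduction:
    """Top-k principal subspace of voxels x time data (time dimension).

    ``reduced`` is k x voxels; back-projection reconstructs the centered
    data with squared error equal to the sum of discarded eigenvalues
    (times n_samples - 1).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a 2-d matrix")
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"k must lie in [1, {min(X.shape)}]")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / max(X.shape[0] - 1, 1)
    ev, vec = np.linalg.eigh(cov)
    order = np.argsort(ev)[::-1]
    ev, vec = ev[order], vec[:, order]
    basis = vec[:, :k]
    reduced = (Xc @ basis).T
    return PcaReduction(reduced=reduced, basis=basis, eigenvalues=ev)


def _orient_by_skewness(S: np.ndarray) -> np.ndarray:
    """Flip source rows so each has non-negative skewness (sign convention)."""
    m = S.mean(axis=1, keepdims=True)
    s3 = np.mean((S - m) ** 3, axis=1)
    flip = np.where(s3 < 0, -1.0, 1.0)
    return S * flip[:, None]


def infomax_ica(
    reduced: np.ndarray,
    seed: int = 0,
    learning_rate: float = 0.001,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ICAResult:
    """Natural-gradient infomax ICA with the logistic nonlinearity.

    The input (k x samples) is whitened internally; the unmixing weights
    follow dW ~ (I + (1 - 2 g(u)) u^T / n) W with g the logistic sigmoid,
    the learning rate annealed by 0.9 whenever the update direction
    reverses.  Stops when the relative weight change drops below ``tol``;
    non-convergence returns the best iterate flagged.
    """
    X = np.asarray(reduced, dtype=float)
    k, n = X.shape
    if k < 2 or n <= k:
        raise ValueError("need k >= 2 and more samples than components")
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / n
    ev, vec = np.linalg.eigh(cov)
    ev = np.maximum(ev, 1e-12)
    whiten = vec @ np.diag(ev**-0.5) @ vec.T
    Z = whiten @ Xc
    W = np.linalg.qr(rng.standard_normal((k, k)))[0]
    lr = learning_rate * k  # scale-free step for the natural gradient
    block = min(max(int(np.sqrt(n)), 32), n)
    eye = np.eye(k)
    last_delta = None
    step_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # one pass of mini-batch natural-gradient updates in random order
        order = rng.permutation(n)
        W_start = W.copy()
        for lo in range(0, n, block):
            Zb = Z[:, order[lo : lo + block]]
            nb = Zb.shape[1]
            U = W @ Zb
            Y = expit(U)
            W = W + lr * (eye + (1.0 - 2.0 * Y) @ U.T / nb) @ W
            if not np.all(np.isfinite(W)):  # diverged: restart smaller
                lr *= 0.5
                W = W_start
                break
        delta = W - W_start
        if last_delta is not None and np.sum(delta * last_delta) < 0:
            lr *= 0.9  # oscillation between passes: anneal
        step_norm = float(np.linalg.norm(delta) / max(np.linalg.norm(W_start), 1e-12))
        last_delta = delta
        if step_norm < tol:
            break
    converged = step_norm < tol
    if not converged:
        warnings.warn("infomax did not converge; returning last iterate", stacklevel=2)
    S = W @ Z
    S = _orient_by_skewness(S)
    sd = S.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    S = S / sd
    mixing = np.linalg.pinv(W @ whiten)
    return ICAResult(mixing, S, it, step_norm, converged)


def icasso(
    reduced: np.ndarray, k: int, n_runs: int = 100, seed: int = 0
) -> StableICAResult:
    """Stability analysis by repeated infomax runs.

    All n_runs x k source estimates are pooled; pairwise dissimilarity
    1 - |corr| is clustered by average-linkage agglomeration into k
    clusters; each cluster's centrotype (the estimate with maximal
    intra-cluster similarity) is retained with its quality index
    Iq = mean intra-cluster |corr| - mean extra-cluster |corr|.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    root = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in root.spawn(n_runs)]
    pool = []
    for s in run_seeds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pool.append(infomax_ica(reduced, seed=s).source_maps)
    S = np.vstack(pool)  # (n_runs*k) x samples
    C = np.abs(np.corrcoef(S))
    np.fill_diagonal(C, 1.0)
    D = 1.0 - C
    Z = linkage(squareform(D, checks=False), method="average")
    assign = fcluster(Z, t=k, criterion="maxclust")
    maps, iq = [], []
    for c in np.unique(assign):
        members = np.flatnonzero(assign == c)
        intra = C[np.ix_(members, members)]
        extra = C[np.ix_(members, np.flatnonzero(assign != c))]
        if members.size > 1:
            sums = (intra.sum(axis=1) - 1.0) / (members.size - 1)
            centro = members[int(np.argmax(sums))]
            intra_mean = float((intra.sum() - members.size) / (members.size * (members.size - 1)))
        else:
            centro = members[0]
            intra_mean = 1.0
        extra_mean = float(extra.mean()) if extra.size else 0.0
        maps.append(S[centro])
        iq.append(intra_mean - extra_mean)
    order = np.argsort(iq)[::-1]
    return StableICAResult(
        centrotype_maps=np.vstack(maps)[order],
        stability_index=np.asarray(iq)[order],
        run_count=n_runs,
    )


def back_reconstruct(
    group_maps: np.ndarray, subject_data: np.ndarray, subject_id: str = ""
) -> SubjectComponentSet:
    """Dual (spatial-temporal) regression of one subject on the group maps.

    Stage 1 regresses the subject's voxels x frames data on the group
    spatial maps to get time courses; stage 2 regresses the data on those
    time courses to get subject-specific maps.
    """
    M = np.asarray(group_maps, dtype=float)  # k x voxels
    Y = np.asarray(subject_data, dtype=float)  # voxels x frames
    if M.shape[1] != Y.shape[0]:
        raise ValueError("voxel dimensions of maps and data disagree")
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"group map {bad + 1} is all-zero (degenerate regressor)")
    G = np.corrcoef(M)
    off = np.abs(G - np.eye(M.shape[0]))
    if np.linalg.matrix_rank(M) < M.shape[0]:
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(f"collinear group maps: components {i + 1} and {j + 1}")
    tc, *_ = np.linalg.lstsq(M.T, Y, rcond=None)  # k x frames
    maps, *_ = np.linalg.lstsq(tc.T, Y.T, rcond=None)  # k x voxels
    return SubjectComponentSet(subject_id, maps, tc.T)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|) of two binary masks.

    Two empty masks give 0 with a warning (the 0/0 case).
    """
    A = np.asarray(a).astype(bool)
    B = np.asarray(b).astype(bool)
    if A.shape != B.shape:
        raise ValueError("masks must share a grid")
    total = A.sum() + B.sum()
    if total == 0:
        warnings.warn("both masks empty: Dice defined as 0", stacklevel=2)
        return 0.0
    return float(2.0 * np.logical_and(A, B).sum() / total)


def low_frequency_fraction(tc: np.ndarray, fs_hz: float, cutoff_hz: float = 0.10) -> float:
    """Fraction of time-course spectral power below ``cutoff_hz``."""
    x = np.asarray(tc, dtype=float)
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs_hz)
    total = power[1:].sum()
    if total == 0:
        return 0.0
    return float(power[1:][freqs[1:] < cutoff_hz].sum() / total)


def select_components(
    component_masks: np.ndarray,
    timecourses: np.ndarray,
    templates: dict[str, np.ndarray],
    dice_min: float = 0.2,
    lf_power_min: float = 0.5,
    fs_hz: float = 1.0 / 0.8,
) -> ComponentSelection:
    """Label components against template masks and filter.

    Each component gets the label of its maximum-Dice template and is
    retained iff that Dice is >= ``dice_min`` and the low-frequency
    (< 0.10 Hz) fraction of its time-course power is >= ``lf_power_min``.
    The retained subset is returned in component order; an empty
    selection is a warning, not an error.
    """
    if not 0 <= dice_min <= 1 or not 0 <= lf_power_min <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    names = list(templates)
    sel = ComponentSelection([], [], [], [])
    for c in range(component_masks.shape[0]):
        dices = [dice_coefficient(component_masks[c], templates[n]) for n in names]
        best = int(np.argmax(dices))
        lf = low_frequency_fraction(timecourses[:, c], fs_hz)
        if dices[best] >= dice_min and lf >= lf_power_min:
            sel.indices.append(c)
            sel.labels.append(names[best])
            sel.dice.append(float(dices[best]))
            sel.lf_power.append(lf)
    if not sel.indices:
        warnings.warn("no component passed the selection criteria", stacklevel=2)
    return sel
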