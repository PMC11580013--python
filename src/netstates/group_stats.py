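"""Covariate-adjusted group comparisons, multiplicity control, correlations.

Group differences in connectivity features are tested with an OLS model
``y ~ 1 + group + age + sex + education``; the t statistic on the group
coefficient reduces to the pooled-variance two-sample t when no
covariates are supplied.  Families of tests are corrected by
Benjamini-Hochberg FDR.  Voxelwise map comparisons use a permutation
max-cluster-extent scheme (Freedman-Lane residual permutation for the
nuisance covariates) in place of parametric random-field FWE, at the same
nominal voxel and cluster levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlmTestResult",
    "CorrectionResult",
    "ClusterResult",
    "glm_group_test",
    "fdr_bh",
    "perm_fwe_maps",
    "pearson_with_clinical",
    "joa_recovery_rate",
]

_P_FLOOR = np.finfo(float).tiny


@dataclass
class GlmTestResult:
    effect: float
    t: float
    df: int
    p: float
    flag: str | None = None


@dataclass
class CorrectionResult:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    method: str


@dataclass
class ClusterResult:
    """One significant cluster: voxel indices (grid coordinates), extent, peak."""

    voxels: np.ndarray  # n x ndim grid indices, 0-based
    extent: int
    peak_t: float
    peak_index: tuple[int, ...]
    p_fwe: float


def _design(group: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = group.size
    cols = [np.ones(n), np.asarray(group, dtype=float)]
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cols.extend(C.T)
    return np.column_stack(cols)


def glm_group_test(
    y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None = None
) -> GlmTestResult:
    """OLS of y on [1, group, covariates]; t-test on the group coefficient.

    ``group`` is binary (0/1 or two labels); with no covariates this is
    the classic pooled-variance two-sample t-test.  Degenerate cases are
    flagged rather than raised: constant y gives p = 1, a perfect fit
    gives p at the machine floor.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("group must have exactly two levels")
    g = (group == levels[1]).astype(float)
    X = _design(g, covariates)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need at least regressors + 2 subjects")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("collinear design matrix (check group/covariate columns)")
    if np.ptp(y) == 0:
        warnings.warn("zero-variance response: effect 0, p reported as 1", stacklevel=2)
        return GlmTestResult(0.0, 0.0, n - p, 1.0, flag="zero_variance")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    sse = float(resid @ resid)
    XtX_inv = np.linalg.inv(X.T @ X)
    if sse <= 1e-12 * float(y @ y):
        return GlmTestResult(float(beta[1]), np.inf, df, _P_FLOOR, flag="perfect_fit")
    se = np.sqrt(sse / df * XtX_inv[1, 1])
    t = float(beta[1] / se)
    pval = float(2.0 * stats.t.sf(abs(t), df))
    return GlmTestResult(float(beta[1]), t, df, max(pval, _P_FLOOR))


def fdr_bh(pvals: np.ndarray | list, q: float = 0.05) -> CorrectionResult:
    """Benjamini-Hochberg step-up at level q."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return CorrectionResult(p, p.copy(), np.zeros(0, dtype=bool), "fdr_bh")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return CorrectionResult(p, adj, rejected, "fdr_bh")


def _group_tmap(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorized per-column t statistic on the group coefficient (column 1)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    sse = np.einsum("ij,ij->j", resid, resid)
    df = n - p
    se = np.sqrt(np.maximum(sse, 1e-300) / df * XtX_inv[1, 1])
    return beta[1] / se


def _clusters(sig: np.ndarray, grid: tuple[int, ...]) -> list[np.ndarray]:
    vol = sig.reshape(grid)
    structure = ndimage.generate_binary_structure(len(grid), 1)  # face adjacency
    labeled, n = ndimage.label(vol, structure=structure)
    flat = labeled.ravel()
    return [np.flatnonzero(flat == i) for i in range(1, n + 1)]


def perm_fwe_maps(
    maps: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None,
    grid: tuple[int, ...],
    n_perm: int = 500,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    seed: int = 0,
) -> list[ClusterResult]:
    """Permutation max-cluster-extent FWE test of voxelwise group differences.

    The observed two-sided t-map is thresholded at ``voxel_p``;
    suprathreshold clusters are formed by face adjacency on ``grid``.  The
    null distribution of the maximum cluster extent comes from ``n_perm``
    group-label permutations under the Freedman-Lane scheme: the reduced
    model (intercept + covariates) is fit, its residuals are permuted and
    added back to the reduced fit, and the full-model t-map is recomputed.
    Clusters larger than the (1 - cluster_p) null quantile are returned.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Y = np.asarray(maps, dtype=float)  # subjects x voxels
    group = np.asarray(group)
    levels = np.unique(group)
    g = (group == levels[1]).astype(float)
    X = _design(g, covariates)
    n, p = X.shape
    df = n - p
    t_thr = stats.t.isf(voxel_p / 2.0, df)
    t_obs = _group_tmap(Y, X)
    obs_clusters = _clusters(np.abs(t_obs) > t_thr, grid)
    if not obs_clusters:
        return []

    # Freedman-Lane: reduced model without the group column
    Xr = np.delete(X, 1, axis=1)
    Hr = Xr @ np.linalg.inv(Xr.T @ Xr) @ Xr.T
    fitted_r = Hr @ Y
    resid_r = Y - fitted_r
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yb = fitted_r + resid_r[perm]
        tb = _group_tmap(Yb, X)
        cl = _clusters(np.abs(tb) > t_thr, grid)
        null_max[b] = max((c.size for c in cl), default=0)
    thr_extent = np.quantile(null_max, 1.0 - cluster_p)
    results = []
    for c in obs_clusters:
        if c.size > thr_extent:
            coords = np.array(np.unravel_index(c, grid)).T
            peak = c[int(np.argmax(np.abs(t_obs[c])))]
            p_fwe = float((np.sum(null_max >= c.size) + 1) / (n_perm + 1))
            results.append(
                ClusterResult(
                    voxels=coords,
                    extent=int(c.size),
                    peak_t=float(t_obs[peak]),
                    peak_index=tuple(int(i) for i in np.unravel_index(peak, grid)),
                    p_fwe=p_fwe,
                )
            )
    return sorted(results, key=lambda r: -r.extent)


def pearson_with_clinical(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r between a connectivity feature and a clinical variable,
    with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def joa_recovery_rate(pre_score: float, post_score: float) -> float:
    """Surgical recovery rate on the 17-point myelopathy scale:
    (post - pre) / (17 - pre)."""
    if pre_score >= 17.0:
        raise ValueError("recovery rate undefined for a pre-operative score of 17")
    return (post_score - pre_score) / (17.0 - pre_score)
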