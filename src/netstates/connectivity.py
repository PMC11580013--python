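"""Static and window-free dynamic inter-network connectivity.

Static connectivity is the Fisher-Z-transformed Pearson correlation matrix
of the cleaned network time courses.  Two window-free dynamic estimators
are provided:

* DCC — dynamic conditional correlation.  Each series is first fit with a
  univariate GARCH(1,1) by Gaussian quasi-maximum likelihood; the DCC(1,1)
  recursion ``Q_t = (1-a-b) Qbar + a z_{t-1} z_{t-1}' + b Q_{t-1}`` is then
  driven by the standardized residuals ``z``, with (a, b) maximized under
  the correlation pseudo-likelihood.  Every frame yields a valid
  correlation matrix ``R_t``.

* FLS — flexible least squares.  For each ordered pair of standardized
  series, the time-varying slope ``beta_t`` minimizes the sum of squared
  measurement residuals plus ``mu`` times the sum of squared dynamic
  (frame-to-frame) coefficient changes; the exact minimizer solves a
  symmetric tridiagonal system.  The two directed slopes of a pair are
  averaged.  Unlike DCC, FLS values are regression slopes and need not lie
  in (-1, 1); values outside are clipped before the Fisher-Z transform and
  counted.

Tensors store frames x (k*k) Fisher-Z values; temporal summaries are the
elementwise mean and sample standard deviation across frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import linalg, optimize, signal
from scipy.special import expit

__all__ = [
    "StaticFCMatrix",
    "GarchFit",
    "DccParams",
    "DynamicConnectivityTensor",
    "DynamicConnectivitySummary",
    "FlsConfig",
    "static_fc",
    "fit_garch11",
    "dcc",
    "fls",
    "summarize_dfc",
    "pair_names",
]

_CLIP = 1.0 - 1e-7


@dataclass
class StaticFCMatrix:
    values: np.ndarray  # k x k Fisher-Z, diagonal 0
    method: str = "pearson_fisherz"

    @property
    def n_networks(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strictly-upper-triangle values in row-major pair order."""
        iu = np.triu_indices(self.n_networks, k=1)
        return self.values[iu]


@dataclass
class GarchFit:
    omega: float
    alpha: float
    beta: float
    sigma: np.ndarray  # conditional sd series
    residuals: np.ndarray  # standardized residuals z_t
    converged: bool = True

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.alpha < 0 or self.beta < 0:
            raise ValueError("GARCH parameters out of range")
        if self.alpha + self.beta >= 1:
            raise ValueError("alpha + beta must be < 1 (covariance stationarity)")


@dataclass
class DccParams:
    a: float
    b: float
    qbar: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b >= 1:
            raise ValueError("DCC parameters must satisfy a,b >= 0, a+b < 1")


@dataclass
class DynamicConnectivityTensor:
    """frames x (k*k) Fisher-Z dynamic-connectivity values."""

    values: np.ndarray
    n_networks: int
    method: str  # "dcc" | "fls"
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.n_networks**2:
            raise ValueError("tensor width must be n_networks**2")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def frame_matrix(self, t: int) -> np.ndarray:
        """k x k Fisher-Z slice at frame t."""
        return self.values[t].reshape(self.n_networks, self.n_networks)

    def upper_triangle_series(self) -> np.ndarray:
        """frames x (k(k-1)/2) series of the strictly-upper-triangle pairs."""
        k = self.n_networks
        iu = np.triu_indices(k, k=1)
        return self.values.reshape(-1, k, k)[:, iu[0], iu[1]]


@dataclass
class DynamicConnectivitySummary:
    fc_mean: np.ndarray  # k x k temporal mean
    fc_sd: np.ndarray  # k x k temporal sample sd
    method: str


@dataclass(frozen=True)
class FlsConfig:
    mu: float = 100.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or self.mu <= 0:
            raise ValueError("mu must be finite and positive")


def pair_names(k: int, upper_only: bool = True) -> list[str]:
    """Stable pair labels: 'IC01-IC02' in row-major order."""
    names = []
    for i in range(k):
        js = range(i + 1, k) if upper_only else range(k)
        for j in js:
            names.append(f"IC{i + 1:02d}-IC{j + 1:02d}")
    return names


def _fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def static_fc(tc: np.ndarray) -> StaticFCMatrix:
    """Fisher-Z Pearson correlation matrix with zeroed diagonal."""
    X = np.asarray(tc, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a frames x k matrix with at least 3 frames")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"component {bad + 1} is constant; correlation undefined")
    r = np.corrcoef(X, rowvar=False)
    z = np.asarray(_fisher_z(r))
    np.fill_diagonal(z, 0.0)
    return StaticFCMatrix(values=z)


# ---------------------------------------------------------------------------
# GARCH(1,1)


def _garch_sigma2(x2: np.ndarray, omega: float, alpha: float, beta: float) -> np.ndarray:
    """sigma^2_t = omega + alpha x^2_{t-1} + beta sigma^2_{t-1}, sigma^2_0 = var(x)."""
    n = x2.size
    s0 = x2.mean()
    drive = omega + alpha * np.concatenate([[0.0], x2[:-1]])
    drive[0] = s0  # initialization at the sample variance
    # y_t = drive_t + beta * y_{t-1} via an IIR filter
    zi = signal.lfiltic([1.0], [1.0, -beta], [0.0])
    s2, _ = signal.lfilter([1.0], [1.0, -beta], drive, zi=zi * 0.0)
    return s2


def _garch_negloglik(params: np.ndarray, x: np.ndarray) -> float:
    w, p, q = params
    omega = np.exp(w)
    pers = 0.999 * expit(p)
    frac = expit(q)
    alpha = pers * frac
    beta = pers * (1.0 - frac)
    s2 = _garch_sigma2(x * x, omega, alpha, beta)
    if np.any(s2 <= 0) or not np.all(np.isfinite(s2)):
        return 1e12
    return 0.5 * float(np.sum(np.log(s2) + x * x / s2))


def fit_garch11(series: np.ndarray) -> GarchFit:
    """Gaussian QML fit of GARCH(1,1) to a demeaned series.

    Optimization runs in an unconstrained parameterization (log omega,
    logit persistence, logit alpha-share) enforcing omega > 0 and
    alpha + beta < 1.  On optimizer failure or a degenerate series the
    constant-variance model (alpha = beta = 0) is returned with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 50:
        raise ValueError("need a 1-d series of length >= 50")
    v = x.var()
    if v <= 0:
        warnings.warn("constant series: constant-variance fallback", stacklevel=2)
        return GarchFit(1e-12, 0.0, 0.0, np.full(x.size, 1e-6), np.zeros(x.size), False)
    x0 = np.array([np.log(v * 0.05), np.log(0.9 / 0.1), np.log(0.1 / 0.9)])
    omega, alpha, beta = np.nan, 0.0, 0.0
    try:
        res = optimize.minimize(
            _garch_negloglik,
            x0,
            args=(x,),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxfev": 500},
        )
        w, p, q = res.x
        omega = float(np.exp(w))
        pers = 0.999 * float(expit(p))
        alpha = pers * float(expit(q))
        beta = pers - alpha
        converged = bool(res.success) or res.fun < _garch_negloglik(x0, x)
    except (ValueError, FloatingPointError):
        converged = False
    if not converged or not np.isfinite(omega):
        warnings.warn("GARCH optimizer failure: constant-variance fallback", stacklevel=2)
        omega, alpha, beta = v, 0.0, 0.0
    s2 = _garch_sigma2(x * x, omega, max(alpha, 0.0), max(beta, 0.0))
    sigma = np.sqrt(s2)
    return GarchFit(omega, alpha, beta, sigma, x / sigma, converged)


# ---------------------------------------------------------------------------
# DCC(1,1)


@njit(cache=True)
def _dcc_negloglik(z: np.ndarray, qbar: np.ndarray, a: float, b: float) -> float:
    T, k = z.shape
    Q = qbar.copy()
    nll = 0.0
    for t in range(T):
        if t > 0:
            zz = np.outer(z[t - 1], z[t - 1])
            Q = (1.0 - a - b) * qbar + a * zz + b * Q
        d = np.sqrt(np.diag(Q))
        R = Q / np.outer(d, d)
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0:
            return 1e12
        zt = z[t]
        quad = zt @ np.linalg.solve(R, zt)
        nll += 0.5 * (logdet + quad - zt @ zt)
    return nll


@njit(cache=True)
def _dcc_path(z: np.ndarray, qbar: np.ndarray, a: float, b: float) -> np.ndarray:
    T, k = z.shape
    Q = qbar.copy()
    out = np.empty((T, k, k))
    for t in range(T):
        if t > 0:
            zz = np.outer(z[t - 1], z[t - 1])
            Q = (1.0 - a - b) * qbar + a * zz + b * Q
        d = np.sqrt(np.diag(Q))
        out[t] = Q / np.outer(d, d)
    return out


def _dcc_objective(params: np.ndarray, z: np.ndarray, qbar: np.ndarray) -> float:
    s = 0.999 * expit(params[0])
    w = expit(params[1])
    return _dcc_negloglik(z, qbar, s * w, s * (1.0 - w))


def dcc(tc: np.ndarray) -> tuple[DynamicConnectivityTensor, DccParams]:
    """Two-stage DCC(1,1) estimate of time-varying correlations.

    Stage 1 fits GARCH(1,1) per column; stage 2 maximizes the correlation
    pseudo-likelihood over (a, b) with a logit reparameterization
    enforcing a + b < 1, multi-started from three fixed points.  Falls
    back to a coarse (a, b) grid search when all starts fail.
    """
    X = np.asarray(tc, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("DCC needs a frames x k matrix with k >= 2")
    if X.shape[0] < 100:
        raise ValueError("DCC needs at least 100 frames")
    X = X - X.mean(axis=0)
    z = np.column_stack([fit_garch11(X[:, j]).residuals for j in range(X.shape[1])])
    qbar = np.corrcoef(z, rowvar=False)
    starts = [(0.02, 0.95), (0.05, 0.90), (0.10, 0.80)]
    best = None
    for a0, b0 in starts:
        s0 = a0 + b0
        x0 = np.array([np.log(s0 / (0.999 - s0)), np.log(a0 / (s0 - a0))])
        try:
            res = optimize.minimize(
                _dcc_objective,
                x0,
                args=(z, qbar),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxfev": 200},
            )
        except (ValueError, FloatingPointError):
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    converged = best is not None and best.fun < 1e11
    if converged:
        s = 0.999 * float(expit(best.x[0]))
        w = float(expit(best.x[1]))
        a, b = s * w, s * (1.0 - w)
    else:
        warnings.warn("DCC optimizer failure: grid-search fallback", stacklevel=2)
        grid = [
            (a, b)
            for a in np.linspace(0.0, 0.2, 9)
            for b in np.linspace(0.6, 0.98, 9)
            if a + b < 0.999
        ]
        nlls = [_dcc_negloglik(z, qbar, a, b) for a, b in grid]
        a, b = grid[int(np.argmin(nlls))]
    path = _dcc_path(z, qbar, a, b)
    T, k = z.shape[0], z.shape[1]
    vals = np.asarray(_fisher_z(path)).reshape(T, k * k)
    diag_idx = np.arange(k) * k + np.arange(k)
    vals[:, diag_idx] = np.arctanh(_CLIP)  # unit diagonal before Fisher-Z
    tensor = DynamicConnectivityTensor(vals, k, "dcc")
    return tensor, DccParams(a, b, qbar, converged)


# ---------------------------------------------------------------------------
# FLS


def _fls_beta(y: np.ndarray, x: np.ndarray, mu: float) -> np.ndarray:
    """Exact FLS path: (diag(x^2) + mu L'L) beta = x*y, L = first difference."""
    n = y.size
    ab = np.zeros((2, n))
    ab[1] = x * x + 2.0 * mu
    ab[1, 0] -= mu
    ab[1, -1] -= mu
    ab[0, 1:] = -mu
    return linalg.solveh_banded(ab, x * y, lower=False)


def fls(tc: np.ndarray, config: FlsConfig | None = None) -> DynamicConnectivityTensor:
    """Flexible-least-squares time-varying pairwise coupling.

    Columns are standardized; for each ordered pair the penalized
    time-varying slope is solved exactly, and the two directions are
    averaged into a symmetric value.  The diagonal is 1 by convention.
    """
    config = config or FlsConfig()
    X = np.asarray(tc, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need a frames x k matrix with at least 10 frames")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"component {bad + 1} has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    T, k = Z.shape
    beta = np.zeros((T, k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                beta[:, i, j] = 1.0
            elif i < j:
                bij = _fls_beta(Z[:, j], Z[:, i], config.mu)
                bji = _fls_beta(Z[:, i], Z[:, j], config.mu)
                sym = 0.5 * (bij + bji)
                beta[:, i, j] = sym
                beta[:, j, i] = sym
    flat = beta.reshape(T, k * k)
    n_clipped = int(np.sum(np.abs(flat) > _CLIP) - T * k)  # diagonal excluded
    vals = np.asarray(_fisher_z(flat))
    if n_clipped > 0:
        warnings.warn(f"FLS: clipped {n_clipped} values outside (-1, 1)", stacklevel=2)
    return DynamicConnectivityTensor(vals, k, "fls", n_clipped=max(n_clipped, 0))


def summarize_dfc(tensor: DynamicConnectivityTensor) -> DynamicConnectivitySummary:
    """Temporal mean and sample standard deviation of the Fisher-Z values."""
    if tensor.n_frames < 2:
        raise ValueError("need at least 2 frames to summarize")
    k = tensor.n_networks
    mean = tensor.values.mean(axis=0).reshape(k, k)
    sd = tensor.values.std(axis=0, ddof=1).reshape(k, k)
    return DynamicConnectivitySummary(fc_mean=mean, fc_sd=sd, method=tensor.method)
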