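"""Component time-course post-processing and head-motion summaries.

The cleaning pipeline applied to each network time course before
connectivity estimation is, in order: polynomial detrending (orders 1-3
jointly), despiking of outlier samples against a smooth baseline,
zero-phase Butterworth low-pass filtering at 0.08 Hz, and regression of
the 24 Friston motion regressors.  Framewise displacement is available in
the Power, Jenkinson, and Van Dijk variants for motion QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "PostprocConfig",
    "detrend",
    "despike",
    "lowpass",
    "friston24",
    "regress_nuisance",
    "framewise_displacement",
    "clean_timecourses",
]


@dataclass(frozen=True)
class PostprocConfig:
    detrend_orders: frozenset[int] = frozenset({1, 2, 3})
    despike_c1: float = 2.5
    despike_c2: float = 4.0
    lowpass_hz: float = 0.08
    sampling_hz: float = 1.0 / 0.8

    def __post_init__(self) -> None:
        if not 0 < self.lowpass_hz < self.sampling_hz / 2:
            raise ValueError("lowpass_hz must lie in (0, Nyquist)")


def detrend(tc: np.ndarray, orders: set[int] | frozenset[int] = frozenset({1, 2, 3})) -> np.ndarray:
    """Residual of a joint least-squares fit on intercept + polynomial trends.

    The time index is centered and scaled to [-1, 1] before raising to the
    requested powers, which keeps the design well conditioned.
    """
    tc = np.asarray(tc, dtype=float)
    single = tc.ndim == 1
    Y = tc[:, None] if single else tc
    n = Y.shape[0]
    orders = sorted(orders)
    if n <= max(orders) + 1:
        raise ValueError(f"need more than {max(orders) + 1} frames for orders {orders}")
    t = np.linspace(-1.0, 1.0, n)
    X = np.column_stack([np.ones(n)] + [t**o for o in orders])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid[:, 0] if single else resid


def _despike_baseline(n: int) -> np.ndarray:
    """Quadratic polynomial plus Fourier pairs up to 3 cycles."""
    t = np.linspace(-1.0, 1.0, n)
    cols = [np.ones(n), t, t**2]
    for c in range(1, 4):
        arg = 2.0 * np.pi * c * np.arange(n) / n
        cols.append(np.sin(arg))
        cols.append(np.cos(arg))
    return np.column_stack(cols)


def despike(tc: np.ndarray, c1: float = 2.5, c2: float = 4.0) -> np.ndarray:
    """AFNI-style despiking of one series.

    A smooth baseline (order-2 polynomial + 3 Fourier pairs) is fit by
    least squares; residuals are scaled by the robust sigma MAD/0.6745.
    Samples whose scaled residual s exceeds c1 are shrunk to
    ``c1 + (c2-c1)*tanh((s-c1)/(c2-c1))`` sigmas from the baseline, so a
    spike of any size lands strictly below c2 sigmas.
    """
    x = np.asarray(tc, dtype=float)
    if x.ndim != 1:
        raise ValueError("despike operates on a single series")
    n = x.size
    if n < 8:
        raise ValueError("series too short to despike")
    X = _despike_baseline(n)
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    base = X @ beta
    resid = x - base
    sigma = np.median(np.abs(resid - np.median(resid))) / 0.6745
    if sigma == 0:
        warnings.warn("zero MAD: series returned unchanged", stacklevel=2)
        return x.copy()
    s = np.abs(resid) / sigma
    out = x.copy()
    hit = s > c1
    shrunk = c1 + (c2 - c1) * np.tanh((s[hit] - c1) / (c2 - c1))
    out[hit] = base[hit] + np.sign(resid[hit]) * sigma * shrunk
    return out


def lowpass(tc: np.ndarray, cutoff_hz: float = 0.08, fs_hz: float = 1.0 / 0.8) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (forward-backward)."""
    if cutoff_hz >= fs_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    x = np.asarray(tc, dtype=float)
    b, a = signal.butter(4, cutoff_hz / (fs_hz / 2), btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def friston24(motion: np.ndarray) -> np.ndarray:
    """24-regressor motion model: [R(t), R(t-1), R(t)^2, R(t-1)^2].

    ``motion`` is frames x 6 (3 translations mm, 3 rotations rad); the
    lag-1 blocks are zero-padded at the first frame.
    """
    R = np.asarray(motion, dtype=float)
    if R.ndim != 2 or R.shape[1] != 6:
        raise ValueError("motion must be frames x 6")
    if R.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    lag = np.vstack([np.zeros((1, 6)), R[:-1]])
    return np.hstack([R, lag, R**2, lag**2])


def regress_nuisance(tc: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Least-squares residual of tc on the nuisance columns.

    Collinear or zero columns are dropped (with a warning) before the
    projection; no intercept is added, matching regression of already
    detrended series.
    """
    Y = np.asarray(tc, dtype=float)
    N = np.asarray(nuisance, dtype=float)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    if N.shape[0] != Y.shape[0]:
        raise ValueError("frame counts differ between tc and nuisance")
    keep = np.ptp(N, axis=0) > 0
    N = N[:, keep]
    if N.shape[1]:
        # SVD basis of the column space; rank deficiency = collinear columns
        u, sv, _ = np.linalg.svd(N, full_matrices=False)
        rank = int(np.sum(sv > 1e-10 * sv.max()))
        if rank < N.shape[1]:
            warnings.warn(
                f"dropped {N.shape[1] - rank} collinear nuisance columns",
                stacklevel=2,
            )
        basis = u[:, :rank]
    else:
        basis = np.empty((Y.shape[0], 0))
    if basis.shape[1] == 0:
        return Y[:, 0].copy() if single else Y.copy()
    resid = Y - basis @ (basis.T @ Y)
    return resid[:, 0] if single else resid


def framewise_displacement(motion: np.ndarray, method: str = "power") -> np.ndarray:
    """Per-frame head-motion summary; first frame is 0 by convention.

    power     sum of |frame differences| of translations plus 50 mm times
              the |differences| of rotations (50 mm sphere radius).
    jenkinson RMS displacement of the differential rigid-body transform
              over an 80 mm-radius sphere centered at the origin.
    vandijk   Euclidean norm of the translation differences only.
    """
    R = np.asarray(motion, dtype=float)
    if R.ndim != 2 or R.shape[1] != 6:
        raise ValueError("motion must be frames x 6")
    if R.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.diff(R, axis=0)
    if method == "power":
        fd = np.abs(d[:, :3]).sum(axis=1) + 50.0 * np.abs(d[:, 3:]).sum(axis=1)
    elif method == "vandijk":
        fd = np.linalg.norm(d[:, :3], axis=1)
    elif method == "jenkinson":
        fd = np.array(
            [_jenkinson_step(R[t], R[t + 1]) for t in range(R.shape[0] - 1)]
        )
    else:
        raise ValueError(f"unknown FD method: {method!r}")
    return np.concatenate([[0.0], fd])


def _rigid_transform(params: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx, ty, tz, rx, ry, rz)."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rz @ Ry @ Rx
    T[:3, 3] = (tx, ty, tz)
    return T


def _jenkinson_step(p0: np.ndarray, p1: np.ndarray, radius: float = 80.0) -> float:
    T = _rigid_transform(p1) @ np.linalg.inv(_rigid_transform(p0)) - np.eye(4)
    A = T[:3, :3]
    t = T[:3, 3]
    return float(np.sqrt(radius**2 / 5.0 * np.trace(A.T @ A) + t @ t))


def clean_timecourses(
    tc: np.ndarray, motion: np.ndarray, config: PostprocConfig | None = None
) -> np.ndarray:
    """Full cleaning pipeline: detrend -> despike -> low-pass -> Friston-24.

    Frame counts are preserved at every stage.
    """
    config = config or PostprocConfig()
    out = detrend(tc, config.detrend_orders)
    out = np.column_stack(
        [despike(out[:, j], config.despike_c1, config.despike_c2) for j in range(out.shape[1])]
    )
    out = lowpass(out, config.lowpass_hz, config.sampling_hz)
    return regress_nuisance(out, friston24(motion))
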