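"""Seeded synthetic cohorts with planted connectivity-state ground truth.

The generator emulates a two-group resting-state study: per-subject
multivariate network time courses driven by a hidden Markov switching of
the inter-network covariance between a strongly connected and a sparsely
connected state, six rigid-body motion parameters, and a clinical table
(age, sex, education, pre/post myelopathy scores) whose surgical-recovery
outcome is statistically coupled to the subject's planted connectivity
features.  All randomness flows from a single root seed through named
per-subject substreams, so cohorts are reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScanConfig",
    "StateModel",
    "ClinicalRecord",
    "Cohort",
    "CohortConfig",
    "InvalidModelError",
    "default_state_model",
    "default_spatial_maps",
    "generate_state_sequence",
    "generate_timecourses",
    "generate_voxel_data",
    "generate_motion",
    "generate_cohort",
    "generate_prognosis_features",
    "write_cohort",
    "read_cohort",
    "cohort_hash",
]


class InvalidModelError(ValueError):
    """Raised when a generative model violates its invariants."""


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition geometry of one functional run.

    ``n_discard`` initial volumes are dropped before analysis, so the
    analyzed length is ``n_volumes - n_discard`` frames sampled every
    ``tr_seconds``.
    """

    tr_seconds: float = 0.8
    n_volumes: int = 450
    n_discard: int = 10
    n_networks: int = 11

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_volumes <= 0 or self.n_discard < 0:
            raise ValueError("volume counts must be non-negative, n_volumes positive")
        if self.n_discard >= self.n_volumes:
            raise ValueError("n_discard must be smaller than n_volumes")
        if self.n_networks <= 0:
            raise ValueError("n_networks must be positive")

    @property
    def analyzed_length(self) -> int:
        return self.n_volumes - self.n_discard

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.tr_seconds


@dataclass
class StateModel:
    """Hidden-Markov Gaussian switching-covariance model of network dynamics.

    ``state_covariances[s]`` is the network covariance while the chain is
    in state ``s``; state 0 (reported as "state 1") must be the strongly
    connected one, i.e. have the larger mean off-diagonal correlation.
    """

    transition_matrix: np.ndarray
    state_covariances: list[np.ndarray]

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.state_covariances = [np.asarray(c, dtype=float) for c in self.state_covariances]
        P = self.transition_matrix
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise InvalidModelError("transition matrix must be square")
        if P.shape[0] != len(self.state_covariances):
            raise InvalidModelError("one covariance per state required")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise InvalidModelError("transition matrix rows must be stochastic")
        for s, cov in enumerate(self.state_covariances):
            if cov.shape != self.state_covariances[0].shape:
                raise InvalidModelError("state covariances must share a shape")
            if not np.allclose(cov, cov.T):
                raise InvalidModelError(f"state {s + 1} covariance not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise InvalidModelError(f"state {s + 1} covariance not positive definite")
        if self.n_states >= 2:
            strengths = [_mean_offdiag_corr(c) for c in self.state_covariances]
            if not strengths[0] > strengths[1]:
                raise InvalidModelError(
                    "state 1 must have larger mean off-diagonal correlation than state 2"
                )

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def n_networks(self) -> int:
        return self.state_covariances[0].shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Left Perron eigenvector of the transition matrix, normalized."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        return pi / pi.sum()


def _mean_offdiag_corr(cov: np.ndarray) -> float:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    mask = ~np.eye(cov.shape[0], dtype=bool)
    return float(corr[mask].mean())


def _corr_matrix(k: int, r: float) -> np.ndarray:
    return np.full((k, k), r) + (1.0 - r) * np.eye(k)


def default_state_model(
    n_networks: int = 11,
    r_strong: float = 0.55,
    r_sparse: float = 0.10,
    p_leave_strong: float = 0.06,
    p_enter_strong: float = 0.03,
) -> StateModel:
    """Two-state model: a less frequent strongly connected state 1 and a
    more frequent sparsely connected state 2.

    Defaults put the stationary occupancy of state 1 at
    ``p_enter/(p_enter+p_leave) = 1/3`` with mean dwell times of roughly
    17 and 33 frames (13 s and 27 s at TR 0.8 s).
    """
    P = np.array(
        [
            [1.0 - p_leave_strong, p_leave_strong],
            [p_enter_strong, 1.0 - p_enter_strong],
        ]
    )
    covs = [_corr_matrix(n_networks, r_strong), _corr_matrix(n_networks, r_sparse)]
    return StateModel(transition_matrix=P, state_covariances=covs)


@dataclass
class ClinicalRecord:
    """One subject's demographic and clinical row.

    The myelopathy severity scale runs 0..17 (17 = intact); pre/post
    scores and symptom duration exist only for patients.
    """

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "F" | "M"
    education: float
    joa_pre: float | None = None
    joa_post: float | None = None
    symptom_duration: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError("group must be 'patient' or 'control'")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.joa_post is not None and self.joa_post < 0:
            raise ValueError("joa_post must be non-negative")


@dataclass
class Cohort:
    """A generated two-group cohort with its planted ground truth."""

    scan_config: ScanConfig
    clinical: list[ClinicalRecord]
    timecourses: dict[str, np.ndarray]  # subject -> frames x networks
    motion: dict[str, np.ndarray]  # subject -> frames x 6
    ground_truth: dict

    def __post_init__(self) -> None:
        ids = {rec.subject_id for rec in self.clinical}
        if set(self.timecourses) != ids or set(self.motion) != ids:
            raise ValueError("one time-series and one motion matrix per clinical record")

    @property
    def subject_ids(self) -> list[str]:
        return [rec.subject_id for rec in self.clinical]

    def group_ids(self, group: str) -> list[str]:
        return [rec.subject_id for rec in self.clinical if rec.group == group]


@dataclass
class CohortConfig:
    """Full generator configuration; defaults are the study conditions.

    ``fc_effect_size`` is an additive increment on the patients'
    inter-network correlations at ``fc_effect_pairs``;
    ``transition_shift`` biases the patients' chain toward state 1;
    ``outcome_coupling`` is the standardized slope linking the planted
    connectivity features to the recovery rate.
    """

    scan: ScanConfig = field(default_factory=ScanConfig)
    n_patients: int = 44
    n_controls: int = 39
    r_strong: float = 0.55
    r_sparse: float = 0.10
    p_leave_strong: float = 0.06
    p_enter_strong: float = 0.03
    transition_shift: float = 0.015
    fc_effect_pairs: tuple[tuple[int, int], ...] = ((1, 5), (2, 3), (2, 5))
    fc_effect_size: float = 0.12
    outcome_coupling: float = 0.6
    recovery_mean: float = 0.74
    recovery_sd: float = 0.16
    joa_pre_mean: float = 11.4
    joa_pre_sd: float = 2.1
    age_mean_patients: float = 54.0
    age_sd_patients: float = 10.7
    age_mean_controls: float = 53.7
    age_sd_controls: float = 8.3
    education_mean: float = 11.2
    education_sd: float = 2.7
    duration_mean: float = 4.0
    duration_sd: float = 2.1
    motion_sd_mm: float = 0.05
    motion_sd_rad: float = 0.001
    motion_ar: float = 0.95

    def state_model(self, group: str) -> StateModel:
        """Group-specific model: patients get the transition shift toward
        state 1 and the additive correlation increment on the effect pairs."""
        p_leave = self.p_leave_strong
        p_enter = self.p_enter_strong
        if group == "patient":
            p_leave = max(p_leave - self.transition_shift, 1e-4)
            p_enter = min(p_enter + self.transition_shift, 1.0 - 1e-4)
        model = default_state_model(
            self.scan.n_networks, self.r_strong, self.r_sparse, p_leave, p_enter
        )
        if group == "patient" and self.fc_effect_size != 0.0:
            covs = []
            for cov in model.state_covariances:
                cov = cov.copy()
                for i, j in self.fc_effect_pairs:
                    cov[i, j] += self.fc_effect_size
                    cov[j, i] += self.fc_effect_size
                covs.append(cov)
            try:
                model = StateModel(model.transition_matrix, covs)
            except InvalidModelError as exc:
                raise InvalidModelError(
                    f"fc_effect_size {self.fc_effect_size} breaks a state covariance: {exc}"
                ) from exc
        return model


def _substream(seed: int, *key: object) -> np.random.Generator:
    """Named substream: stable child generator derived from (seed, key)."""
    digest = hashlib.sha256(("|".join(map(str, key))).encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(int, words)]))


def generate_state_sequence(
    model: StateModel,
    length: int,
    seed: int | np.random.Generator,
    initial_state: int | None = None,
) -> np.ndarray:
    """Sample a per-frame state-label sequence (labels 1..n_states).

    The chain starts from the uniform distribution over states (or from
    ``initial_state``, 1-based, when given) and follows the model's
    row-stochastic transition matrix.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = model.transition_matrix
    n = model.n_states
    labels = np.empty(length, dtype=np.int64)
    cum = np.cumsum(P, axis=1)
    u = rng.random(length)
    if initial_state is None:
        state = min(int(u[0] * n), n - 1)
    else:
        if not 1 <= initial_state <= n:
            raise ValueError("initial_state out of range")
        state = initial_state - 1
    labels[0] = state
    for t in range(1, length):
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, n - 1)
        labels[t] = state
    return labels + 1


def generate_timecourses(
    states: np.ndarray, model: StateModel, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw frame t from a zero-mean MVN with the covariance of state(t)."""
    states = np.asarray(states)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = model.n_networks
    if states.size == 0:
        return np.empty((0, k))
    if states.min() < 1 or states.max() > model.n_states:
        raise InvalidModelError("state label without a covariance in the model")
    z = rng.standard_normal((states.size, k))
    out = np.empty_like(z)
    for s in range(model.n_states):
        idx = states == s + 1
        if not idx.any():
            continue
        L = np.linalg.cholesky(model.state_covariances[s])
        out[idx] = z[idx] @ L.T
    return out


def generate_voxel_data(
    spatial_maps: np.ndarray,
    timecourses: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Linear mixing X = M^T T^T + noise, returning voxels x time.

    ``spatial_maps`` is (n_maps, n_voxels); ``timecourses`` is
    (frames, n_maps).
    """
    maps = np.atleast_2d(np.asarray(spatial_maps, dtype=float))
    tc = np.atleast_2d(np.asarray(timecourses, dtype=float))
    if maps.shape[0] != tc.shape[1]:
        raise ValueError(
            f"map count {maps.shape[0]} != time-course columns {tc.shape[1]}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = maps.T @ tc.T
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return X


def default_spatial_maps(
    grid: tuple[int, int, int] = (12, 12, 6), n_maps: int = 11
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Disjoint rectangular network blobs on a small voxel grid.

    Returns (n_maps x n_voxels array of {0,1} indicators, grid shape).
    The grid is tiled into 4x4x3 boxes and the first ``n_maps`` boxes
    (row-major) become the maps.
    """
    nx, ny, nz = grid
    bx, by, bz = 4, 4, 3
    slots = []
    for z0 in range(0, nz - bz + 1, bz):
        for y0 in range(0, ny - by + 1, by):
            for x0 in range(0, nx - bx + 1, bx):
                slots.append((x0, y0, z0))
    if n_maps > len(slots):
        raise ValueError(f"grid {grid} holds at most {len(slots)} disjoint maps")
    maps = np.zeros((n_maps, nx * ny * nz))
    vol = np.arange(nx * ny * nz).reshape(grid)
    for m, (x0, y0, z0) in enumerate(slots[:n_maps]):
        idx = vol[x0 : x0 + bx, y0 : y0 + by, z0 : z0 + bz].ravel()
        maps[m, idx] = 1.0
    return maps, grid


def generate_motion(
    length: int,
    rng: np.random.Generator,
    sd_mm: float = 0.05,
    sd_rad: float = 0.001,
    ar: float = 0.95,
) -> np.ndarray:
    """AR(1) drift for 3 translations (mm) and 3 rotations (rad)."""
    innov_sd = np.array([sd_mm] * 3 + [sd_rad] * 3) * np.sqrt(1.0 - ar**2)
    eps = rng.standard_normal((length, 6)) * innov_sd
    out = np.empty((length, 6))
    out[0] = rng.standard_normal(6) * np.array([sd_mm] * 3 + [sd_rad] * 3)
    for t in range(1, length):
        out[t] = ar * out[t - 1] + eps[t]
    return out


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Generate a full two-group cohort.

    Patients carry (a) a transition bias toward the strongly connected
    state, (b) an additive correlation increment on the configured pairs,
    and (c) a recovery rate linearly coupled to their planted state-1
    fraction time.  The planted state sequences, per-group models and the
    subjects' true connectivity features are recorded in ``ground_truth``.
    """
    config = config or CohortConfig()
    scan = config.scan
    T = scan.analyzed_length
    models = {g: config.state_model(g) for g in ("patient", "control")}

    clinical: list[ClinicalRecord] = []
    timecourses: dict[str, np.ndarray] = {}
    motion: dict[str, np.ndarray] = {}
    gt_states: dict[str, list[int]] = {}
    gt_ft1: dict[str, float] = {}

    roster = [("patient", i) for i in range(config.n_patients)] + [
        ("control", i) for i in range(config.n_controls)
    ]
    for group, i in roster:
        sid = f"{'P' if group == 'patient' else 'C'}{i + 1:03d}"
        rng = _substream(seed, "subject", sid)
        model = models[group]
        labels = generate_state_sequence(model, T, rng)
        tc = generate_timecourses(labels, model, rng)
        mot = generate_motion(
            T, rng, config.motion_sd_mm, config.motion_sd_rad, config.motion_ar
        )
        age_mean = config.age_mean_patients if group == "patient" else config.age_mean_controls
        age_sd = config.age_sd_patients if group == "patient" else config.age_sd_controls
        rec = ClinicalRecord(
            subject_id=sid,
            group=group,
            age=_truncnorm(rng, age_mean, age_sd, 18.0, 90.0),
            sex="F" if rng.random() < 0.5 else "M",
            education=_truncnorm(rng, config.education_mean, config.education_sd, 0.0, 25.0),
        )
        if group == "patient":
            rec.joa_pre = _truncnorm(rng, config.joa_pre_mean, config.joa_pre_sd, 0.0, 16.5)
            rec.symptom_duration = _truncnorm(
                rng, config.duration_mean, config.duration_sd, 0.1, 20.0
            )
        clinical.append(rec)
        timecourses[sid] = tc
        motion[sid] = mot
        gt_states[sid] = labels.tolist()
        gt_ft1[sid] = float(np.mean(labels == 1))

    # Outcome: recovery rate coupled to the planted state-1 fraction time,
    # standardized within patients so outcome_coupling is a standardized slope.
    patients = [r for r in clinical if r.group == "patient"]
    ft = np.array([gt_ft1[r.subject_id] for r in patients])
    ft_sd = ft.std()
    z_ft = (ft - ft.mean()) / ft_sd if ft_sd > 0 else np.zeros_like(ft)
    beta = config.outcome_coupling
    noise_scale = config.recovery_sd * np.sqrt(max(1.0 - min(beta**2, 1.0), 0.0))
    for rec, z in zip(patients, z_ft):
        rng = _substream(seed, "outcome", rec.subject_id)
        rate = (
            config.recovery_mean
            + beta * config.recovery_sd * z
            + rng.normal(0.0, noise_scale)
        )
        rate = float(np.clip(rate, 0.02, 0.98))
        rec.joa_post = float(np.clip(rec.joa_pre + rate * (17.0 - rec.joa_pre), 0.0, 17.0))

    ground_truth = {
        "seed": int(seed),
        "state_sequences": gt_states,
        "fraction_time_state1": gt_ft1,
        "group_mean_ft1": {
            g: float(np.mean([gt_ft1[r.subject_id] for r in clinical if r.group == g]))
            for g in ("patient", "control")
        },
        "transition_matrices": {
            g: models[g].transition_matrix.tolist() for g in ("patient", "control")
        },
        "fc_effect_pairs": [list(p) for p in config.fc_effect_pairs],
        "fc_effect_size": config.fc_effect_size,
        "outcome_coupling": config.outcome_coupling,
    }
    return Cohort(scan, clinical, timecourses, motion, ground_truth)


def generate_prognosis_features(
    n_good: int = 22,
    n_poor: int = 22,
    n_networks: int = 11,
    sfc_effect: float = 0.8,
    dfc_mean_effect: float = 0.8,
    temporal_effect: float = 1.2,
    n_signal_pairs: int = 5,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Planted-feature cohort for classifier studies.

    Produces raw feature blocks (static-FC upper triangle, dynamic-FC
    temporal means and SDs, five temporal properties) with standardized
    group effects (Cohen's d) on ``n_signal_pairs`` static pairs, the same
    number of dynamic means, and on the temporal properties — emulating a
    study where dynamic features carry more prognostic signal than static
    ones.  Returns ``(blocks, labels)`` with labels 1 = good outcome.
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_networks * (n_networks - 1) // 2
    n = n_good + n_poor
    labels = np.array([1] * n_good + [0] * n_poor)
    sign = np.where(labels == 1, 0.5, -0.5)

    def block(width: int, effect: float, n_sig: int) -> np.ndarray:
        X = rng.standard_normal((n, width))
        X[:, :n_sig] += np.outer(sign, np.full(n_sig, effect))
        return X

    blocks = {
        "sfc": block(n_pairs, sfc_effect, n_signal_pairs),
        "dfc_mean": block(n_pairs, dfc_mean_effect, n_signal_pairs),
        "dfc_sd": block(n_pairs, 0.0, 0),
        "temporal": block(5, temporal_effect, 5),
    }
    return blocks, labels


# ---------------------------------------------------------------------------
# Cohort serialization


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort as TSV tables plus a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.clinical:
        rows.append(dataclasses.asdict(rec))
    pd.DataFrame(rows).to_csv(out / "clinical.tsv", sep="\t", index=False)
    fmt = "%.17g"  # round-trip exact for float64
    for sid in cohort.subject_ids:
        np.savetxt(out / f"sub-{sid}_timeseries.tsv", cohort.timecourses[sid], fmt=fmt, delimiter="\t")
        np.savetxt(out / f"sub-{sid}_motion.tsv", cohort.motion[sid], fmt=fmt, delimiter="\t")
    gt = dict(cohort.ground_truth)
    gt["scan_config"] = dataclasses.asdict(cohort.scan_config)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    src = Path(in_dir)
    with open(src / "ground_truth.json") as fh:
        gt = json.load(fh)
    scan = ScanConfig(**gt.pop("scan_config"))
    table = pd.read_csv(src / "clinical.tsv", sep="\t", float_precision="round_trip")
    clinical = []
    for _, row in table.iterrows():
        kwargs = {k: row[k] for k in table.columns}
        for key in ("joa_pre", "joa_post", "symptom_duration"):
            if key in kwargs and pd.isna(kwargs[key]):
                kwargs[key] = None
        clinical.append(ClinicalRecord(**kwargs))
    timecourses = {}
    motion = {}
    for rec in clinical:
        timecourses[rec.subject_id] = np.loadtxt(
            src / f"sub-{rec.subject_id}_timeseries.tsv", delimiter="\t", ndmin=2
        )
        motion[rec.subject_id] = np.loadtxt(
            src / f"sub-{rec.subject_id}_motion.tsv", delimiter="\t", ndmin=2
        )
    return Cohort(scan, clinical, timecourses, motion, gt)


def cohort_hash(cohort: Cohort) -> str:
    """SHA-256 over a canonical serialization; equal iff cohorts identical."""
    h = hashlib.sha256()
    h.update(json.dumps(dataclasses.asdict(cohort.scan_config), sort_keys=True).encode())
    for rec in cohort.clinical:
        h.update(json.dumps(dataclasses.asdict(rec), sort_keys=True).encode())
        h.update(np.ascontiguousarray(cohort.timecourses[rec.subject_id]).tobytes())
        h.update(np.ascontiguousarray(cohort.motion[rec.subject_id]).tobytes())
    h.update(json.dumps(cohort.ground_truth, sort_keys=True).encode())
    return h.hexdigest()


def export_nifti(volume_series: np.ndarray, grid: tuple[int, int, int], path: str | Path) -> None:
    """Optional NIfTI export of toy voxel data (voxels x time) on a grid."""
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError("NIfTI export requires nibabel") from exc
    vols = np.asarray(volume_series).reshape(*grid, -1)
    nib.save(nib.Nifti1Image(vols.astype(np.float32), np.eye(4)), str(path))
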