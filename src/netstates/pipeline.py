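"""End-to-end orchestration: simulate -> [ica] -> postproc -> connectivity
-> states -> stats -> mvpa, with a YAML-round-trippable run configuration
and a provenance manifest (hashes, seeds, wall times)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from netstates import connectivity as cn
from netstates import group_stats as gs
from netstates import mvpa as mv
from netstates import postproc as pp
from netstates import states as st
from netstates import synthcohort as sc

__all__ = [
    "RunConfig",
    "validate_config",
    "run_pipeline",
    "load_config",
    "save_config",
    "selected_state_count",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ica", "postproc", "connectivity", "states", "stats", "mvpa")


@dataclass
class RunConfig:
    """Stage-wise configuration of one reproducible run."""

    seed: int = 0
    out_dir: str = "netstates_run"
    cohort: sc.CohortConfig = field(default_factory=sc.CohortConfig)
    postproc: pp.PostprocConfig = field(default_factory=pp.PostprocConfig)
    fls: cn.FlsConfig = field(default_factory=cn.FlsConfig)
    mvpa: mv.MvpaConfig = field(default_factory=mv.MvpaConfig)
    dfc_methods: tuple[str, ...] = ("dcc", "fls")
    k_states: int | None = 2  # None -> select via silhouette over k_range
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    kmeans_replicates: int = 20
    mvpa_permutations: int = 0  # 0 disables the permutation test in the run
    stages: tuple[str, ...] = ("simulate", "postproc", "connectivity", "states", "stats", "mvpa")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> RunConfig:
    kwargs = dict(raw)
    if "cohort" in kwargs:
        coh = dict(kwargs["cohort"])
        if "scan" in coh:
            coh["scan"] = sc.ScanConfig(**coh["scan"])
        if "fc_effect_pairs" in coh:
            coh["fc_effect_pairs"] = tuple(tuple(p) for p in coh["fc_effect_pairs"])
        kwargs["cohort"] = sc.CohortConfig(**coh)
    if "postproc" in kwargs:
        ppc = dict(kwargs["postproc"])
        if "detrend_orders" in ppc:
            ppc["detrend_orders"] = frozenset(ppc["detrend_orders"])
        kwargs["postproc"] = pp.PostprocConfig(**ppc)
    if "fls" in kwargs:
        kwargs["fls"] = cn.FlsConfig(**kwargs["fls"])
    if "mvpa" in kwargs:
        kwargs["mvpa"] = mv.MvpaConfig(**kwargs["mvpa"])
    for key in ("dfc_methods", "k_range", "stages"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def validate_config(config: RunConfig) -> list[str]:
    """Check every nested invariant; returns a list of human-readable
    violations (empty when the configuration is valid)."""
    violations: list[str] = []
    try:
        nyquist = config.postproc.sampling_hz / 2
        if not 0 < config.postproc.lowpass_hz < nyquist:
            violations.append(
                f"low-pass cutoff {config.postproc.lowpass_hz} Hz outside (0, Nyquist {nyquist} Hz)"
            )
    except Exception as exc:  # frozen dataclass may already have raised
        violations.append(str(exc))
    if config.mvpa.n_permutations < 100:
        violations.append("mvpa.n_permutations must be >= 100")
    if not 0 < config.mvpa.cutoff < 1:
        violations.append("mvpa.cutoff must lie in (0, 1)")
    if config.cohort.scan.n_discard >= config.cohort.scan.n_volumes:
        violations.append("scan.n_discard must be below scan.n_volumes")
    for stage in config.stages:
        if stage not in STAGES:
            violations.append(f"unknown stage {stage!r}")
    if "mvpa" in config.stages and "states" not in config.stages:
        violations.append("mvpa dynamic feature sets require the states stage")
    try:
        config.cohort.state_model("patient")
    except sc.InvalidModelError as exc:
        violations.append(f"cohort effects break the state model: {exc}")
    if config.mvpa_permutations and config.mvpa_permutations < 100:
        violations.append("mvpa_permutations must be 0 or >= 100")
    return violations


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a provenance manifest.

    Returns the manifest; numeric outputs land under ``config.out_dir``.
    Re-running with an identical configuration reproduces identical
    numbers.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": _to_plain(config)}
    artifacts: dict = {}

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    cohort = None
    if "simulate" in config.stages:
        t0 = time.time()
        cohort = sc.generate_cohort(config.cohort, seed=config.seed)
        sc.write_cohort(cohort, out / "cohort")
        record("simulate", t0, n_subjects=len(cohort.clinical),
               cohort_hash=sc.cohort_hash(cohort))
    if cohort is None:
        raise ValueError("missing upstream artifact: stage 'simulate' produced no cohort")

    if "ica" in config.stages:
        t0 = time.time()
        from netstates import group_ica as gi

        maps, grid = sc.default_spatial_maps(n_maps=config.cohort.scan.n_networks)
        rng = np.random.default_rng(config.seed)
        voxel = np.hstack(
            [
                sc.generate_voxel_data(maps, cohort.timecourses[sid], 0.1, rng)
                for sid in cohort.subject_ids
            ]
        )
        k = maps.shape[0]
        red = gi.pca_reduce(voxel, k)
        stable = gi.icasso(red.reduced, k, n_runs=10, seed=config.seed)
        record("ica", t0, n_components=k,
               mean_iq=float(stable.stability_index.mean()))
        artifacts["ica"] = stable

    clean: dict[str, np.ndarray] = {}
    if "postproc" in config.stages:
        t0 = time.time()
        for sid in cohort.subject_ids:
            clean[sid] = pp.clean_timecourses(
                cohort.timecourses[sid], cohort.motion[sid], config.postproc
            )
        record("postproc", t0, n_subjects=len(clean))
    else:
        clean = dict(cohort.timecourses)

    sfc: dict[str, np.ndarray] = {}
    tensors: dict[str, dict[str, cn.DynamicConnectivityTensor]] = {m: {} for m in config.dfc_methods}
    summaries: dict[str, dict[str, cn.DynamicConnectivitySummary]] = {m: {} for m in config.dfc_methods}
    if "connectivity" in config.stages:
        t0 = time.time()
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        for sid in cohort.subject_ids:
            mat = cn.static_fc(clean[sid])
            sfc[sid] = mat.values
            np.savetxt(conn_dir / f"sub-{sid}_sfc.tsv", mat.values, fmt="%.9g", delimiter="\t")
            for method in config.dfc_methods:
                if method == "dcc":
                    tensor, _ = cn.dcc(clean[sid])
                elif method == "fls":
                    tensor = cn.fls(clean[sid], config.fls)
                else:
                    raise ValueError(f"unknown dFC method {method!r}")
                tensors[method][sid] = tensor
                summaries[method][sid] = cn.summarize_dfc(tensor)
        record("connectivity", t0, methods=list(config.dfc_methods),
               sfc_hash=_hash_array(np.vstack([sfc[s] for s in cohort.subject_ids])))

    state_results: dict[str, st.StateResult] = {}
    temporal: dict[str, dict[str, np.ndarray]] = {}
    if "states" in config.stages:
        t0 = time.time()
        k_net = config.cohort.scan.n_networks
        offdiag = ~np.eye(k_net, dtype=bool).ravel()
        for method in config.dfc_methods:
            res = st.cluster_states(
                {s: t.values for s, t in tensors[method].items()},
                k=config.k_states,
                k_range=list(config.k_range),
                n_replicates=config.kmeans_replicates,
                seed=config.seed,
                offdiag_mask=offdiag,
            )
            state_results[method] = res
            temporal[method] = {}
            for sid, lab in res.labels.items():
                tp = st.temporal_properties(lab, res.k)
                temporal[method][sid] = np.concatenate(
                    [tp.fraction_time, tp.mean_dwell_time, [tp.n_transitions]]
                )
        record("states", t0, k={m: r.k for m, r in state_results.items()})

    if "stats" in config.stages:
        t0 = time.time()
        group = np.array([r.group == "patient" for r in cohort.clinical], dtype=int)
        covs = np.column_stack(
            [
                [r.age for r in cohort.clinical],
                [1.0 if r.sex == "F" else 0.0 for r in cohort.clinical],
                [r.education for r in cohort.clinical],
            ]
        )
        iu = np.triu_indices(config.cohort.scan.n_networks, k=1)
        rows = []
        sfc_stack = np.stack([sfc[s] for s in cohort.subject_ids])
        pair_labels = cn.pair_names(config.cohort.scan.n_networks)
        pvals = []
        for idx, (i, j) in enumerate(zip(*iu)):
            res = gs.glm_group_test(sfc_stack[:, i, j], group, covs)
            rows.append(
                {
                    "contrast": "patient-control",
                    "feature": f"sfc_{pair_labels[idx]}",
                    "estimate": res.effect,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                }
            )
            pvals.append(res.p)
        corr = gs.fdr_bh(np.array(pvals))
        table = pd.DataFrame(rows)
        table["p_adj"] = corr.adjusted_p
        table["flag"] = corr.rejected
        table.to_csv(out / "stats_sfc.tsv", sep="\t", index=False)
        record("stats", t0, n_tests=len(rows), n_significant=int(corr.rejected.sum()))
        artifacts["stats"] = table

    if "mvpa" in config.stages:
        t0 = time.time()
        if not state_results:
            raise ValueError("missing upstream artifact: mvpa dynamic sets need stage 'states'")
        patients = [r for r in cohort.clinical if r.group == "patient"]
        pids = [r.subject_id for r in patients]
        labels, rates = mv.label_outcomes(patients, config.mvpa.cutoff)
        results = {}
        for method in config.dfc_methods:
            for tag in (f"dfc_{method}", f"fusion_{method}"):
                table = mv.assemble_features(
                    pids,
                    tag,
                    sfc={s: sfc[s] for s in pids},
                    dfc_mean={s: summaries[method][s].fc_mean for s in pids},
                    dfc_sd={s: summaries[method][s].fc_sd for s in pids},
                    temporal={s: temporal[method][s] for s in pids},
                    n_states=state_results[method].k,
                )
                results[tag] = _classify(table, labels, config)
        sfc_table = mv.assemble_features(pids, "sfc", sfc={s: sfc[s] for s in pids})
        results["sfc"] = _classify(sfc_table, labels, config)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)
        record("mvpa", t0, **{k: v["accuracy"] for k, v in results.items()})
        artifacts["mvpa"] = results

    manifest["versions"] = {"numpy": np.__version__, "pandas": pd.__version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def selected_state_count(
    seed: int,
    n_per_group: int = 12,
    n_volumes: int = 210,
    n_discard: int = 10,
    method: str = "dcc",
    k_range: range | list[int] = range(2, 9),
    n_replicates: int = 20,
) -> tuple[int, dict[int, dict[str, float]], int]:
    """State count selected on pooled dFC frames of one reduced cohort.

    Generates a default-condition cohort at reduced size, cleans the time
    courses, estimates per-subject dynamic connectivity, pools all frames,
    and runs the silhouette/Calinski-Harabasz scan.  Returns
    (selected k, per-k scores, number of pooled frames).
    """
    import warnings

    cfg = sc.CohortConfig(
        n_patients=n_per_group,
        n_controls=n_per_group,
        scan=sc.ScanConfig(n_volumes=n_volumes, n_discard=n_discard),
    )
    cohort = sc.generate_cohort(cfg, seed=seed)
    frames = []
    for sid in cohort.subject_ids:
        clean = pp.clean_timecourses(cohort.timecourses[sid], cohort.motion[sid])
        if method == "dcc":
            tensor, _ = cn.dcc(clean)
        else:
            tensor = cn.fls(clean)
        frames.append(tensor.values)
    X = np.vstack(frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # weak-silhouette advisory expected here
        k, scores = st.select_k(X, k_range, n_replicates=n_replicates, seed=seed)
    return k, scores, X.shape[0]


def _classify(table: mv.FeatureTable, labels: np.ndarray, config: RunConfig) -> dict:
    res = mv.loocv_classify(table, labels, config.mvpa, seed=config.seed)
    outcome = {
        "accuracy": res.accuracy,
        "auc": res.auc,
        "n_features": len(table.feature_names),
    }
    if config.mvpa_permutations >= 100:
        cfg = dataclasses.replace(config.mvpa, n_permutations=config.mvpa_permutations)
        p, _ = mv.permutation_test(table, labels, cfg, res.accuracy, seed=config.seed)
        outcome["permutation_p"] = p
    return outcome
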