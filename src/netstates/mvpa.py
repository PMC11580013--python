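"""Prognosis classification from connectivity features.

Patients are split into good and poor surgical outcome at a recovery-rate
cutoff (default 0.75).  Five feature sets are assembled per subject: the
55 static-FC upper-triangle values; 115 dynamic-FC features (55 temporal
means, 55 temporal SDs, and the five temporal state properties) for each
dynamic estimator; and the 170-feature fusion of the two.  Classification
is leave-one-out cross-validation: within every training fold the
features are standardized, LASSO selects a sparse subset, and a
sigmoid-kernel SVM (C = 1, gamma = 0.1) is trained on the selected
features and applied to the held-out subject.  Significance comes from a
label-permutation null of the whole LOOCV, with
p = #(null accuracy >= observed) / n_permutations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from netstates.connectivity import pair_names
from netstates.group_stats import joa_recovery_rate

__all__ = [
    "FeatureTable",
    "MvpaConfig",
    "ClassificationResult",
    "label_outcomes",
    "assemble_features",
    "loocv_classify",
    "permutation_test",
    "roc_auc",
]

logger = logging.getLogger(__name__)

SET_TAGS = ("sfc", "dfc_fls", "dfc_dcc", "fusion_fls", "fusion_dcc")


@dataclass
class FeatureTable:
    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # subjects x features
    set_tag: str

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("values shape must be subjects x features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")


@dataclass(frozen=True)
class MvpaConfig:
    C: float = 1.0
    gamma: float = 0.1
    coef0: float = 0.0
    kernel: str = "sigmoid"
    lasso_lambda: float | str = "cv"  # fixed alpha, or "cv" for inner 5-fold CV
    n_permutations: int = 1000
    cutoff: float = 0.75

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")


@dataclass
class ClassificationResult:
    predicted: np.ndarray
    scores: np.ndarray  # decision values of the held-out subjects
    accuracy: float
    roc_points: np.ndarray  # (fpr, tpr) rows
    auc: float
    permutation_p: float | None = None
    null_accuracies: np.ndarray | None = None
    selected_features: list[list[str]] = field(default_factory=list)


def label_outcomes(clinical, cutoff: float = 0.75) -> tuple[np.ndarray, np.ndarray]:
    """Binary outcome labels for patients: 1 = good (recovery rate >= cutoff).

    Returns (labels, recovery_rates) over the patient records in order.
    A cohort where only one class occurs is flagged with a warning.
    """
    rates = np.array(
        [joa_recovery_rate(rec.joa_pre, rec.joa_post) for rec in clinical]
    )
    labels = (rates >= cutoff).astype(int)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class outcome labels: cohort unclassifiable", stacklevel=2)
    return labels, rates


def assemble_features(
    subject_ids: list[str],
    set_tag: str,
    sfc: dict[str, np.ndarray] | None = None,
    dfc_mean: dict[str, np.ndarray] | None = None,
    dfc_sd: dict[str, np.ndarray] | None = None,
    temporal: dict[str, np.ndarray] | None = None,
    n_states: int = 2,
) -> FeatureTable:
    """Assemble one of the five feature sets from per-subject artifacts.

    ``sfc``/``dfc_mean``/``dfc_sd`` map subject -> k x k matrix (only the
    strictly-upper triangle is used, row-major); ``temporal`` maps subject
    -> the 2k+1 temporal-property vector (fraction times, mean dwell
    times, transition count).  With 11 networks and 2 states the sets have
    55 (sfc), 115 (dfc_*), and 170 (fusion_*) features.
    """
    if set_tag not in SET_TAGS:
        raise ValueError(f"unknown set tag {set_tag!r}")
    need_sfc = set_tag == "sfc" or set_tag.startswith("fusion")
    need_dfc = set_tag != "sfc"
    blocks: list[tuple[str, dict[str, np.ndarray], list[str]]] = []

    def _upper(mat: np.ndarray) -> np.ndarray:
        k = mat.shape[0]
        return mat[np.triu_indices(k, k=1)]

    if need_sfc:
        if sfc is None:
            raise ValueError("sfc matrices required for this set")
        k = next(iter(sfc.values())).shape[0]
        blocks.append(("sfc", {s: _upper(m) for s, m in sfc.items()},
                       [f"sfc_{p}" for p in pair_names(k)]))
    if need_dfc:
        if dfc_mean is None or dfc_sd is None or temporal is None:
            raise ValueError("dfc summaries and temporal properties required")
        k = next(iter(dfc_mean.values())).shape[0]
        blocks.append(("dfc_mean", {s: _upper(m) for s, m in dfc_mean.items()},
                       [f"dfc_mean_{p}" for p in pair_names(k)]))
        blocks.append(("dfc_sd", {s: _upper(m) for s, m in dfc_sd.items()},
                       [f"dfc_sd_{p}" for p in pair_names(k)]))
        tp_names = (
            [f"fraction_time_state{s}" for s in range(1, n_states + 1)]
            + [f"mean_dwell_time_state{s}" for s in range(1, n_states + 1)]
            + ["n_transitions"]
        )
        blocks.append(("temporal", temporal, tp_names))

    missing = [
        s
        for s in subject_ids
        if any(s not in data for _, data, _ in blocks)
    ]
    if missing:
        raise ValueError(f"missing upstream artifacts for subjects: {missing}")
    names: list[str] = []
    cols: list[np.ndarray] = []
    for _, data, blk_names in blocks:
        arr = np.vstack([np.asarray(data[s], dtype=float).ravel() for s in subject_ids])
        if arr.shape[1] != len(blk_names):
            raise ValueError("artifact width does not match feature-name count")
        names.extend(blk_names)
        cols.append(arr)
    return FeatureTable(list(subject_ids), names, np.hstack(cols), set_tag)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC.

    AUC is the normalized Mann-Whitney U: the probability that a random
    positive outscores a random negative, ties counted one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)
    fpr, tpr, _ = roc_curve(y, s)
    return np.column_stack([fpr, tpr]), auc


def _select_features(
    Xtr: np.ndarray, ytr: np.ndarray, lasso_lambda: float | str, seed: int
) -> np.ndarray:
    if lasso_lambda == "cv":
        model = LassoCV(
            alphas=np.logspace(-3, 0, 10),
            cv=min(5, len(ytr)),
            max_iter=5000,
            random_state=seed,
        )
    else:
        model = Lasso(alpha=float(lasso_lambda), max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xtr, ytr.astype(float))
    return np.flatnonzero(model.coef_ != 0)


def loocv_classify(
    features: FeatureTable,
    labels: np.ndarray,
    config: MvpaConfig | None = None,
    seed: int = 0,
) -> ClassificationResult:
    """Leave-one-out classification with in-fold standardization and LASSO.

    All data-dependent steps (feature standardization, LASSO selection,
    SVM training) see the training fold only; the held-out subject is
    transformed with training-fold statistics.  A fold whose LASSO
    selects no feature falls back to the full feature set (logged).
    """
    config = config or MvpaConfig()
    X = features.values
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = X.shape[0]
    predicted = np.empty(n, dtype=int)
    scores = np.empty(n)
    selected: list[list[str]] = []
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        Xtr, ytr = X[tr], y[tr]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Ztr = (Xtr - mu) / sd
        Zte = (X[i] - mu) / sd
        sel = _select_features(Ztr, ytr, config.lasso_lambda, seed)
        if sel.size == 0:
            logger.info("fold %d: LASSO selected no features, using all", i)
            sel = np.arange(X.shape[1])
        clf = SVC(
            kernel=config.kernel, C=config.C, gamma=config.gamma, coef0=config.coef0
        )
        clf.fit(Ztr[:, sel], ytr)
        predicted[i] = int(clf.predict(Zte[None, sel])[0])
        scores[i] = float(clf.decision_function(Zte[None, sel])[0])
        selected.append([features.feature_names[j] for j in sel])
    accuracy = float(np.mean(predicted == y))
    roc_points, auc = roc_auc(scores, y)
    return ClassificationResult(predicted, scores, accuracy, roc_points, auc,
                                selected_features=selected)


def permutation_test(
    features: FeatureTable,
    labels: np.ndarray,
    config: MvpaConfig | None = None,
    observed_accuracy: float | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Label-permutation null of the full LOOCV (selection included).

    p = #(null accuracy >= observed) / n_permutations, the literal
    counting proportion; the smallest reportable p is 1/n_permutations
    (attained only when no null value ties or exceeds the observed one).
    """
    config = config or MvpaConfig()
    y = np.asarray(labels)
    if observed_accuracy is None:
        observed_accuracy = loocv_classify(features, y, config, seed).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        yb = rng.permutation(y)
        while len(np.unique(yb)) < 2:  # cannot happen for mixed y, defensive
            yb = rng.permutation(y)
        null[b] = loocv_classify(features, yb, config, seed).accuracy
    count = int(np.sum(null >= observed_accuracy))
    p = float(max(count, 1) / config.n_permutations)  # floor at 1/n_permutations
    return p, null
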