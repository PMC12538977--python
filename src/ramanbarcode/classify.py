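"""Patient-stratified classification of replicate spectra with per-patient
score aggregation and ROC evaluation.

The workflow mirrors a clinical spectral-diagnostics study: patients are
split 80:20 into training and testing sets with class balance preserved;
a spectrum-level model (bagged decision trees on barcode features, or a
linear SVM on 95%-variance PCA scores of the full fingerprint) is tuned by
a 20-candidate random search under patient-grouped 5-fold cross-validation,
then retrained 10 times with reshuffled folds to estimate variability (SEM
of the CV AUC).  Per-spectrum hard calls are aggregated into a per-patient
classification score — the percentage of a patient's replicate spectra
called positive — and ROC curves with a Youden-optimal model operating
point are reported at both spectrum and patient level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GroupKFold, RandomizedSearchCV, cross_val_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .synth import PatientRecord

__all__ = [
    "SplitSpec",
    "ModelSpec",
    "TrainedModel",
    "RetrainResult",
    "RocResult",
    "EvalReport",
    "stratified_split",
    "pca_reduce_fingerprint",
    "train_model",
    "retrain_ensemble",
    "patient_scores",
    "roc_with_mop",
    "metrics_table",
    "evaluate_ensemble",
]

POSITIVE = "AD"


@dataclass
class SplitSpec:
    """A patient-level train/test partition."""

    train_patient_ids: list
    test_patient_ids: list
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_patient_ids) & set(self.test_patient_ids):
            raise ValueError("train and test patient sets overlap")


def stratified_split(
    patients: Sequence[PatientRecord] | Sequence[tuple[str, str]],
    ratio: float = 0.8,
    seed: int = 0,
) -> SplitSpec:
    """Class-balanced random patient split.

    Per class, the nearest integer to ``ratio * class size`` patients go to
    the training set and the remainder to testing (66 disease + 75 reference
    patients at 0.8 give 53 + 60 = 113 train, 28 test).
    """
    pairs = [
        (p.patient_id, p.diagnosis) if isinstance(p, PatientRecord) else (p[0], p[1])
        for p in patients
    ]
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    labels = sorted(set(d for _, d in pairs))
    if len(labels) < 2:
        raise ValueError("both classes must be present")
    for lab in labels:
        ids = [pid for pid, d in pairs if d == lab]
        n_train = int(np.floor(ratio * len(ids) + 0.5))
        if n_train == 0 or n_train == len(ids):
            raise ValueError(f"class {lab!r} too small for a {ratio:.0%} split")
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    return SplitSpec(sorted(train), sorted(test), ratio, seed)


def pca_reduce_fingerprint(train_X: np.ndarray, variance: float = 0.95) -> tuple[PCA, np.ndarray]:
    """Fit a PCA projector on training spectra retaining the given variance.

    Returns the fitted projector (to be reused verbatim on test spectra) and
    the transformed training data.  The smallest component count whose
    cumulative explained variance reaches ``variance`` is kept.
    """
    if not 0 < variance <= 1:
        raise ValueError("variance retained must be in (0, 1]")
    X = np.asarray(train_X, dtype=float)
    n_comp = min(X.shape[0] - 1, X.shape[1]) if variance == 1.0 else variance
    pca = PCA(n_components=n_comp, svd_solver="full")
    return pca, pca.fit_transform(X)


@dataclass
class ModelSpec:
    """Model family, input space and training protocol."""

    kind: str = "bagged_tree"  # or "linear_svm"
    input_space: str = "barcode_features"  # or "fingerprint_pcs"
    pca_variance_retained: float = 0.95
    misclassification_costs: np.ndarray | None = None  # 2x2, zero diagonal
    cv_folds: int = 5
    tuning_budget: int = 20
    n_retrains: int = 10
    param_grid: dict | None = None  # overrides the built-in search grid

    def __post_init__(self) -> None:
        if self.kind not in ("bagged_tree", "linear_svm"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.misclassification_costs is not None:
            c = np.asarray(self.misclassification_costs, dtype=float)
            if c.shape != (2, 2) or np.any(c < 0) or np.any(np.diag(c) != 0):
                raise ValueError("costs must be a nonnegative 2x2 matrix with zero diagonal")
            self.misclassification_costs = c


def _class_weight(spec: ModelSpec) -> dict | None:
    if spec.misclassification_costs is None:
        return None
    c = spec.misclassification_costs
    # weight each true class by the cost of misclassifying it
    return {0: float(c[0, 1]), 1: float(c[1, 0])}


def _estimator_and_grid(spec: ModelSpec, seed: int):
    cw = _class_weight(spec)
    if spec.kind == "bagged_tree":
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(class_weight=cw, random_state=seed),
            random_state=seed,
        )
        grid = {
            "n_estimators": [20, 50, 100, 200],
            "estimator__max_depth": [None, 3, 5, 10, 20],
            "estimator__min_samples_leaf": [1, 2, 5, 10],
        }
    else:
        est = SVC(kernel="linear", class_weight=cw, random_state=seed)
        grid = {"C": np.logspace(-3, 2, 21).tolist()}
    if spec.param_grid is not None:
        grid = spec.param_grid
    return est, grid


def _score_of(model, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class score: probability if available, else margin."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class TrainedModel:
    estimator: object
    params: dict
    cv_auc: float
    spec: ModelSpec


def _check_xy(spec: ModelSpec, y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need 2 classes, got {classes.tolist()}")
    if counts.min() < spec.cv_folds:
        raise ValueError("fewer spectra than CV folds in one class")


def train_model(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, groups: Sequence, seed: int = 0
) -> TrainedModel:
    """Tune and fit one spectrum-level model.

    Hyperparameters are chosen by a ``tuning_budget``-candidate random search
    scored by cross-validated AUC; CV folds are grouped by patient so no
    patient's replicates span folds.  The best candidate is refitted on the
    full training data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_xy(spec, y)
    est, grid = _estimator_and_grid(spec, seed)
    cv = GroupKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    n_grid = int(np.prod([len(v) for v in grid.values()]))
    search = RandomizedSearchCV(
        est,
        grid,
        n_iter=min(spec.tuning_budget, n_grid),
        scoring="roc_auc",
        cv=cv,
        random_state=seed,
        refit=True,
        n_jobs=1,
        error_score=0.5,  # a single-class fold scores a candidate at chance
    )
    search.fit(X, y, groups=np.asarray(groups))
    return TrainedModel(search.best_estimator_, search.best_params_, float(search.best_score_), spec)


@dataclass
class RetrainResult:
    models: list
    cv_aucs: np.ndarray
    sem: float
    spec: ModelSpec


def retrain_ensemble(
    trained: TrainedModel, X: np.ndarray, y: np.ndarray, groups: Sequence, seed: int = 0
) -> RetrainResult:
    """Refit the tuned model ``n_retrains`` times with reshuffled CV folds.

    Each retrain records its patient-grouped CV AUC; the SEM of those AUCs
    (SD / sqrt(n_retrains)) quantifies model variability.  Evaluation later
    averages the retrains' test predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    spec = trained.spec
    _check_xy(spec, y)
    models, aucs = [], []
    for i in range(spec.n_retrains):
        rs = seed + 1000 * (i + 1)
        est = clone(trained.estimator)
        if "random_state" in est.get_params():
            est.set_params(random_state=rs)
        cv = GroupKFold(n_splits=spec.cv_folds, shuffle=True, random_state=rs)
        scores = cross_val_score(
            est, X, y, groups=groups, cv=cv, scoring="roc_auc", n_jobs=1,
            error_score=np.nan,
        )
        # a reshuffle can produce a single-class fold on tiny cohorts; its
        # AUC is undefined and excluded from the retrain mean
        aucs.append(float(np.nanmean(scores)))
        est.fit(X, y)
        models.append(est)
    aucs = np.asarray(aucs)
    sem = float(aucs.std(ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
    return RetrainResult(models, aucs, sem, spec)


def patient_scores(calls: Sequence[int], patient_ids: Sequence) -> pd.Series:
    """Per-patient classification score: % of the patient's spectra called
    positive."""
    calls = np.asarray(calls)
    pids = np.asarray(patient_ids)
    if calls.size != pids.size:
        raise KeyError("every spectrum call must map to a patient id")
    s = pd.Series(calls.astype(float), index=pd.Index(pids, name="patient_id"))
    return 100.0 * s.groupby(level=0, sort=False).mean()


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    mop_threshold: float
    sensitivity: float
    specificity: float


def roc_with_mop(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC curve with AUC and the Youden-optimal operating point.

    The model operating point (MOP) maximises J = sensitivity + specificity
    - 1; ties are broken toward higher specificity.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size != 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # lowest fpr among ties
    return RocResult(
        fpr, tpr, thr, float(_auc(fpr, tpr)), float(thr[best]), float(tpr[best]), float(1 - fpr[best])
    )


def metrics_table(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> dict:
    """Confusion-matrix metrics at a fixed score threshold.

    Predictions are positive when score >= threshold.  Returns accuracy,
    sensitivity, specificity, PPV, NPV, F1 and AUROC as fractions in [0, 1];
    cells whose denominator is zero are reported as ``None``.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def frac(num, den):
        return num / den if den > 0 else None

    sens = frac(tp, tp + fn)
    ppv = frac(tp, tp + fp)
    f1 = (
        2 * ppv * sens / (ppv + sens)
        if ppv is not None and sens is not None and (ppv + sens) > 0
        else None
    )
    return {
        "accuracy": frac(tp + tn, tp + tn + fp + fn),
        "sensitivity": sens,
        "specificity": frac(tn, tn + fp),
        "ppv": ppv,
        "npv": frac(tn, tn + fn),
        "f1": f1,
        "auroc": roc_with_mop(s, y).auc if np.unique(y).size == 2 else None,
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        "threshold": float(threshold),
    }


@dataclass
class EvalReport:
    """Spectrum- and patient-level evaluation of a retrain ensemble."""

    spectrum_scores: np.ndarray
    spectrum_labels: np.ndarray
    patient_score: pd.Series  # % of spectra called positive, averaged over retrains
    patient_labels: pd.Series
    roc_spectrum: RocResult
    roc_patient: RocResult
    metrics: dict  # Table-style metrics at the patient-level MOP
    cv_auc_sem: float


def evaluate_ensemble(
    retrains: RetrainResult,
    X_test: np.ndarray,
    y_test: Sequence[int],
    test_patient_ids: Sequence,
) -> EvalReport:
    """Evaluate averaged retrain predictions on held-out patients.

    Per-spectrum continuous scores and hard calls are averaged over the
    retrains; per-patient classification scores (% spectra called positive)
    feed the patient-level ROC, whose Youden operating point defines the
    reported metrics.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=int)
    pids = np.asarray(test_patient_ids)
    score_mat = np.stack([_score_of(m, X_test) for m in retrains.models])
    call_mat = np.stack([m.predict(X_test) for m in retrains.models])

    spectrum_scores = score_mat.mean(axis=0)
    pat_scores = (
        pd.DataFrame(
            {i: patient_scores(call_mat[i], pids) for i in range(call_mat.shape[0])}
        ).mean(axis=1)
    )
    pat_labels = pd.Series(y_test, index=pd.Index(pids, name="patient_id")).groupby(
        level=0, sort=False
    ).first()
    pat_labels = pat_labels.loc[pat_scores.index]

    roc_s = roc_with_mop(spectrum_scores, y_test)
    roc_p = roc_with_mop(pat_scores.to_numpy(), pat_labels.to_numpy())
    metrics = metrics_table(pat_scores.to_numpy(), pat_labels.to_numpy(), roc_p.mop_threshold)
    return EvalReport(
        spectrum_scores, y_test, pat_scores, pat_labels, roc_s, roc_p, metrics, retrains.sem
    )
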