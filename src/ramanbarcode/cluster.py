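"""Exploratory projections of barcode-feature tables: PCA, two-class LDA and
linear-cutoff class assignment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["ProjectionResult", "pca_project", "lda_project", "linear_cutoff_accuracy"]


@dataclass
class ProjectionResult:
    """Scores, loadings and (for PCA) per-component explained variance."""

    scores: np.ndarray  # (n_samples, n_components)
    loadings: np.ndarray  # (n_features, n_components)
    explained_variance: np.ndarray | None = None
    feature_names: list | None = None


def _as_array(features) -> tuple[np.ndarray, list | None]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    return np.asarray(features, dtype=float), None


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def pca_project(features, n_components: int = 2, standardize: bool = True) -> ProjectionResult:
    """Column-centred PCA of a feature table.

    Features are z-scored by default because region areas have heterogeneous
    scales.  Components are ordered by decreasing explained variance and the
    loading matrix has orthonormal columns.
    """
    X, names = _as_array(features)
    if n_components > X.shape[1]:
        raise ValueError(f"n_components {n_components} exceeds feature count {X.shape[1]}")
    if np.allclose(X, X[0], atol=0):
        raise ValueError("feature matrix is constant; PCA undefined")
    Xs = _standardize(X) if standardize else X
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    return ProjectionResult(scores, pca.components_.T, pca.explained_variance_, names)


def lda_project(features, labels: Sequence, standardize: bool = True) -> ProjectionResult:
    """Two-class linear discriminant analysis, one discriminant axis (LD1).

    When a class has fewer samples than features + 1 the within-class
    covariance is singular; an automatically shrunk covariance estimate is
    used instead (and a warning issued).
    """
    X, names = _as_array(features)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"LDA here is two-class; got {classes.tolist()}")
    Xs = _standardize(X) if standardize else X
    min_class = min(int((y == c).sum()) for c in classes)
    if min_class >= X.shape[1] + 1:
        lda = LinearDiscriminantAnalysis(solver="eigen", n_components=1)
    else:
        warnings.warn(
            "class size below feature count + 1; using shrinkage-regularised LDA"
        )
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto", n_components=1)
    scores = lda.fit_transform(Xs, y)
    loadings = lda.scalings_[:, :1]
    return ProjectionResult(scores, loadings, None, names)


def linear_cutoff_accuracy(scores: Sequence[float], labels: Sequence) -> dict:
    """Best single-threshold class assignment on a 1-D projection.

    The threshold (and which class sits above it) is chosen to maximise
    balanced accuracy; among ties the lower threshold wins.  Returns per-class
    and overall fractions correct along with the chosen cutoff.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    a, b = classes
    uniq = np.unique(s)
    cands = np.concatenate(([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]))
    best = None
    for thr in cands:  # ascending, so first tie keeps the lower threshold
        for hi_class, lo_class in ((a, b), (b, a)):
            pred = np.where(s > thr, hi_class, lo_class)
            acc_a = float(np.mean(pred[y == a] == a))
            acc_b = float(np.mean(pred[y == b] == b))
            bal = (acc_a + acc_b) / 2.0
            if best is None or bal > best["balanced"] + 1e-12:
                best = {
                    "threshold": float(thr),
                    "above": hi_class,
                    str(a): acc_a,
                    str(b): acc_b,
                    "overall": float(np.mean(pred == y)),
                    "balanced": bal,
                }
    return best
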