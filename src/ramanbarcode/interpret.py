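"""Feature-importance analysis of the barcode-feature classifier.

Two complementary views: a global surrogate importance (the average absolute
local weight of a kernel-weighted interpretable surrogate fitted around each
training point, in the spirit of LIME aggregated over the whole training
set) and one-way partial dependence, whose per-feature maximum summarises
how strongly a feature can push the predicted disease score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = ["ImportanceReport", "global_surrogate_importance", "partial_dependence"]


def _score_of(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return np.asarray(model.predict(X), dtype=float)


@dataclass
class ImportanceReport:
    """Per-feature global importances (mean |local surrogate weight|),
    optional partial-dependence curves and their maxima, and the resulting
    descending-importance ranking."""

    importance: np.ndarray
    ranking: np.ndarray  # feature indices, most important first
    feature_names: list | None = None
    pd_grids: list | None = None
    pd_curves: list | None = None
    pd_max: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"importance": self.importance}
        if self.pd_max is not None:
            d["pd_max"] = self.pd_max
        idx = self.feature_names or list(range(len(self.importance)))
        return pd.DataFrame(d, index=idx).sort_values("importance", ascending=False)


def global_surrogate_importance(
    model,
    X,
    kernel_width: float = 0.5,
    n_samples_per_point: int = 1000,
    max_points: int | None = None,
    surrogate_depth: int = 3,
    seed: int = 0,
) -> ImportanceReport:
    """Global importance by aggregating kernel-weighted local surrogates.

    For each training point, feature values are perturbed with unit-SD
    Gaussian noise in z-scored feature space, perturbations are weighted by a
    Gaussian kernel of width ``kernel_width`` (in the same standardised
    space), and a depth-limited regression tree is fitted to the model's
    predicted positive-class score.  The point's local weights are the
    surrogate's feature importances; the global importance of a feature is
    the mean absolute local weight over all (optionally subsampled) points.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    if not hasattr(model, "predict"):
        raise ValueError("model must be fitted and expose predict()")
    rng = np.random.default_rng(seed)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    idx = np.arange(X.shape[0])
    if max_points is not None and max_points < idx.size:
        idx = rng.choice(idx, size=max_points, replace=False)

    d_feat = X.shape[1]
    local = np.zeros((idx.size, d_feat))
    for row, i in enumerate(idx):
        # perturb at the kernel scale so the weighted sample stays informative
        pert_z = Z[i] + kernel_width * rng.standard_normal((n_samples_per_point, d_feat))
        d2 = np.mean((pert_z - Z[i]) ** 2, axis=1)  # per-feature, dimension-free
        w = np.exp(-d2 / (2.0 * kernel_width**2))
        target = _score_of(model, pert_z * sd + mu)
        tree = DecisionTreeRegressor(max_depth=surrogate_depth, random_state=int(rng.integers(2**31)))
        tree.fit(pert_z, target, sample_weight=w)
        local[row] = tree.feature_importances_
    importance = np.abs(local).mean(axis=0)
    ranking = np.argsort(-importance, kind="stable")
    return ImportanceReport(importance, ranking, names)


def partial_dependence(
    model, X, feature_index: int, grid_size: int = 50
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-way partial dependence of the predicted positive score.

    PD(v) is the mean predicted score over the training points with feature
    ``feature_index`` forced to v, evaluated on a uniform grid covering the
    observed feature range.  Returns (grid, curve, maximum).
    """
    X = np.asarray(X, dtype=float)
    col = X[:, feature_index]
    lo, hi = col.min(), col.max()
    if hi == lo:
        warnings.warn(f"feature {feature_index} is constant; partial dependence is flat")
        grid = np.array([lo])
    else:
        grid = np.linspace(lo, hi, grid_size)
    curve = np.empty(grid.size)
    Xi = X.copy()
    for k, v in enumerate(grid):
        Xi[:, feature_index] = v
        curve[k] = float(_score_of(model, Xi).mean())
    return grid, curve, float(curve.max())
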