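"""ATN biomarker scoring and covariate-adjusted partial correlations.

The PLM scale counts how many of the three CSF ATN biomarkers are in their
pathological range (amyloid-beta 42 below 680 pg/ml, phospho-tau above
56 pg/ml, total tau above 355 pg/ml), grading the likelihood of Alzheimer's
disease from 0 to 3.  Associations between spectral biomarker areas (or
classifier output scores) and log-transformed biomarker concentrations are
quantified by age- and sex-adjusted partial correlation, with
Benjamini-Hochberg control of the false discovery rate at 5% within each
family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import PatientRecord

__all__ = [
    "PLM_CUTOFFS",
    "PLMScore",
    "PartialCorrelationResult",
    "plm_score",
    "partial_correlation",
    "bh_adjust",
    "correlation_matrix",
    "plm_correlations",
]

#: pathological-range cutoffs (pg/ml): amyloid positive below, tau positive above
PLM_CUTOFFS: dict[str, float] = {"abeta42": 680.0, "ptau": 56.0, "total_tau": 355.0}


@dataclass
class PLMScore:
    """Count of positive ATN biomarkers for one patient (0-3).

    ``n_positive`` is ``None`` (score undefined) when any component
    biomarker is missing; ``components`` records per-marker positivity.
    """

    patient_id: str
    n_positive: int | None
    components: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.n_positive is not None


def plm_score(
    record: PatientRecord, cutoffs: Mapping[str, float] = PLM_CUTOFFS
) -> PLMScore:
    """Score one patient on the 0-3 ATN positivity scale.

    A (amyloid) is positive when abeta42 < cutoff; T (p-tau) and N (total
    tau) are positive above their cutoffs.  A missing biomarker makes the
    score undefined rather than raising.
    """
    if record.total_tau is None:
        return PLMScore(record.patient_id, None, {})
    comps = {
        "A": bool(record.abeta42 < cutoffs["abeta42"]),
        "T": bool(record.ptau > cutoffs["ptau"]),
        "N": bool(record.total_tau > cutoffs["total_tau"]),
    }
    return PLMScore(record.patient_id, sum(comps.values()), comps)


@dataclass
class PartialCorrelationResult:
    x_name: str
    y_name: str
    n: int
    r: float
    p_raw: float
    n_covariates: int
    p_adj: float | None = None
    significant: bool | None = None


def _residualise(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of v after least-squares regression on [1, C]."""
    design = np.column_stack([np.ones(v.size), C]) if C.size else np.ones((v.size, 1))
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after removing covariate effects.

    Both variables are regressed (with intercept) on the covariate matrix;
    r is the Pearson correlation of the residuals and the two-sided p-value
    comes from t = r * sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k degrees of
    freedom with k covariates.  With no covariates this is exactly the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = (
        np.empty((x.size, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if C.shape[0] != x.size and C.shape[1] == x.size:
        C = C.T
    k = C.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations, got n={n}, k={k}")
    if k:
        design = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise np.linalg.LinAlgError("collinear covariates; drop or recode them")
    rx = _residualise(x, C)
    ry = _residualise(y, C)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    # a residual at rounding level means the covariates explain the variable
    # completely and the partial correlation is undefined
    if sx <= 1e-10 * max(np.linalg.norm(x - x.mean()), 1e-300) or sy <= 1e-10 * max(
        np.linalg.norm(y - y.mean()), 1e-300
    ):
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return PartialCorrelationResult(x_name, y_name, n, r, p, k)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finish_family(
    results: list[PartialCorrelationResult], fdr: float
) -> pd.DataFrame:
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
        r.significant = bool(a < fdr)
    return pd.DataFrame(
        [
            {
                "x": r.x_name,
                "y": r.y_name,
                "n": r.n,
                "r": r.r,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def correlation_matrix(
    features: pd.DataFrame,
    biomarkers: pd.DataFrame,
    covariates: pd.DataFrame,
    log_transform: bool = True,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Partial correlations of every feature with every ATN biomarker.

    ``features`` holds per-patient aggregated region areas (patients x
    features); ``biomarkers`` concentration columns in pg/ml (natural-log
    transformed before correlating unless ``log_transform`` is False; the
    correlation is invariant to the log base); ``covariates`` the adjustment
    columns (age, sex coded 0/1), all indexed by patient.  Patients missing a
    biomarker are dropped from that biomarker's column only.  All feature x
    biomarker tests form one Benjamini-Hochberg family.
    """
    common = features.index.intersection(biomarkers.index).intersection(covariates.index)
    feats = features.loc[common]
    bios = biomarkers.loc[common]
    covs = covariates.loc[common].to_numpy(dtype=float)

    results: list[PartialCorrelationResult] = []
    for bio_name in bios.columns:
        col = bios[bio_name].to_numpy(dtype=float)
        ok = np.isfinite(col)
        if ok.sum() == 0:
            import warnings

            warnings.warn(f"biomarker column {bio_name!r} is empty; skipped")
            continue
        yv = np.log(col[ok]) if log_transform else col[ok]
        for feat_name in feats.columns:
            results.append(
                partial_correlation(
                    feats[feat_name].to_numpy(dtype=float)[ok],
                    yv,
                    covs[ok],
                    x_name=str(feat_name),
                    y_name=str(bio_name),
                )
            )
    return _finish_family(results, fdr)


def plm_correlations(
    features: pd.DataFrame,
    plm: pd.Series,
    covariates: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Partial correlations of each feature (or score) with the ordinal PLM
    status, adjusted for the covariates; one BH family across the features."""
    common = features.index.intersection(plm.dropna().index).intersection(covariates.index)
    feats = features.loc[common]
    y = plm.loc[common].to_numpy(dtype=float)
    covs = covariates.loc[common].to_numpy(dtype=float)
    results = [
        partial_correlation(
            feats[c].to_numpy(dtype=float), y, covs, x_name=str(c), y_name="PLM"
        )
        for c in feats.columns
    ]
    return _finish_family(results, fdr)
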