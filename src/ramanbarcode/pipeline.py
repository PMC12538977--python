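"""End-to-end orchestration: simulate or load -> preprocess -> split ->
barcode -> features -> train/evaluate -> interpret -> correlate -> report.

The barcode and every model are fitted on training patients only; test
spectra are touched only at evaluation.  All stochastic stages take their
seeds from the :class:`~ramanbarcode.io.RunConfig`, so a rerun with the same
configuration reproduces every artefact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import barcode as bc
from . import classify as cl
from . import correlate as co
from . import interpret as it
from .io import RunConfig, read_metadata, read_spectra, save_config, write_metadata, write_spectra
from .preprocess import preprocess_pipeline
from .spectra import SpectrumSet
from .synth import PatientRecord, simulate_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclasses.dataclass
class PipelineResult:
    processed: SpectrumSet
    records: list
    split: cl.SplitSpec
    barcode: bc.Barcode
    features: pd.DataFrame
    eval_report: cl.EvalReport
    importance: it.ImportanceReport
    feature_biomarker: pd.DataFrame
    feature_plm: pd.DataFrame
    score_plm: co.PartialCorrelationResult | None
    outlier_patient_ids: list


def _labels_for(records: list, pids) -> np.ndarray:
    dx = {r.patient_id: r.diagnosis for r in records}
    return np.array([1 if dx[str(p)] == cl.POSITIVE else 0 for p in pids])


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> PipelineResult:
    """Run the full analysis described by ``config``.

    When ``config.spectra_path`` is unset a synthetic cohort is generated
    from ``config.synth``.  Artefacts (spectra, barcode, feature table,
    evaluation metrics, importance table, correlation matrices and a summary)
    are written under ``config.output_dir`` unless ``write_artifacts`` is
    False.
    """
    out = Path(config.output_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.yaml")

    # ---- inputs ----------------------------------------------------------
    if config.spectra_path:
        raw = read_spectra(config.spectra_path)
        records = read_metadata(config.metadata_path)
    else:
        raw, records = simulate_cohort(config.synth)
        if write_artifacts:
            write_spectra(out / "raw_spectra.csv", raw)
            write_metadata(out / "metadata.csv", records)

    # ---- preprocessing and outlier screening -----------------------------
    processed, outliers = preprocess_pipeline(raw, params=config.preprocess)
    retained = set(processed.patients)
    records = [r for r in records if r.patient_id in retained]

    # ---- patient split, barcode on training patients only ----------------
    split = cl.stratified_split(records, config.split_ratio, config.split_seed)
    train_set = processed.select_patients(split.train_patient_ids)
    test_set = processed.select_patients(split.test_patient_ids)
    dx = {r.patient_id: r.diagnosis for r in records}
    tr_ad = train_set.subset(np.array([dx[str(p)] == "AD" for p in train_set.patient_ids]))
    tr_non = train_set.subset(np.array([dx[str(p)] != "AD" for p in train_set.patient_ids]))
    barcode = bc.build_barcode(
        tr_ad, tr_non, config.barcode_alpha, config.barcode_max_gap, config.barcode_min_width
    )
    if not barcode.regions:
        raise RuntimeError("barcode extraction found no significant regions")

    feats_train = bc.build_feature_table(train_set, barcode)
    labels_train = np.array(
        ["AD" if dx[str(p)] == "AD" else "non-AD" for p in train_set.patient_ids]
    )
    barcode = bc.rank_features(feats_train, labels_train, barcode)
    feats_train = bc.build_feature_table(train_set, barcode)  # rank-ordered columns
    feats_test = bc.build_feature_table(test_set, barcode)
    feats_all = bc.build_feature_table(processed, barcode)

    # ---- model training and evaluation -----------------------------------
    spec = config.model
    if spec.input_space == "fingerprint_pcs":
        projector, X_train = cl.pca_reduce_fingerprint(
            train_set.intensities, spec.pca_variance_retained
        )
        X_test = projector.transform(test_set.intensities)
    else:
        X_train = feats_train.to_numpy()
        X_test = feats_test.to_numpy()
    y_train = _labels_for(records, train_set.patient_ids)
    y_test = _labels_for(records, test_set.patient_ids)
    trained = cl.train_model(spec, X_train, y_train, train_set.patient_ids, config.train_seed)
    retrains = cl.retrain_ensemble(trained, X_train, y_train, train_set.patient_ids, config.train_seed)
    eval_report = cl.evaluate_ensemble(retrains, X_test, y_test, test_set.patient_ids)

    # ---- feature importance (barcode-feature model only) -----------------
    imp_X = feats_train if spec.input_space == "barcode_features" else pd.DataFrame(X_train)
    importance = it.global_surrogate_importance(
        retrains.models[0],
        imp_X,
        max_points=config.interpret_max_points,
        n_samples_per_point=config.interpret_samples_per_point,
        seed=config.train_seed,
    )
    pd_grids, pd_curves, pd_max = [], [], []
    for j in range(imp_X.shape[1]):
        g, c, m = it.partial_dependence(retrains.models[0], imp_X.to_numpy(), j)
        pd_grids.append(g)
        pd_curves.append(c)
        pd_max.append(m)
    importance.pd_grids, importance.pd_curves = pd_grids, pd_curves
    importance.pd_max = np.asarray(pd_max)

    # ---- biomarker correlations ------------------------------------------
    per_patient = bc.per_patient_features(feats_all)
    meta = pd.DataFrame(
        {
            "age": {r.patient_id: r.age for r in records},
            "sex": {r.patient_id: 1.0 if r.sex == "M" else 0.0 for r in records},
        }
    )
    bios = pd.DataFrame(
        {
            "abeta42": {r.patient_id: r.abeta42 for r in records},
            "ptau": {r.patient_id: r.ptau for r in records},
            "total_tau": {r.patient_id: (np.nan if r.total_tau is None else r.total_tau) for r in records},
        }
    )
    feature_biomarker = co.correlation_matrix(per_patient, bios, meta)
    plm = pd.Series(
        {
            r.patient_id: (s.n_positive if (s := co.plm_score(r)).defined else np.nan)
            for r in records
        }
    )
    feature_plm = co.plm_correlations(per_patient, plm, meta)
    score_plm = None
    test_plm = plm.loc[plm.index.intersection(eval_report.patient_score.index)].dropna()
    if len(test_plm) > 5:
        idx = test_plm.index
        score_plm = co.partial_correlation(
            eval_report.patient_score.loc[idx].to_numpy(),
            test_plm.to_numpy(),
            meta.loc[idx].to_numpy(),
            x_name="classification_score",
            y_name="PLM",
        )

    result = PipelineResult(
        processed,
        records,
        split,
        barcode,
        feats_all,
        eval_report,
        importance,
        feature_biomarker,
        feature_plm,
        score_plm,
        list(outliers.removed_patient_ids),
    )
    if write_artifacts:
        _write_report(out, config, result)
    return result


def _write_report(out: Path, config: RunConfig, res: PipelineResult) -> None:
    res.barcode.to_frame().to_csv(out / "barcode.csv", index=False)
    res.features.to_csv(out / "feature_table.csv")
    res.importance.to_frame().to_csv(out / "feature_importance.csv")
    res.feature_biomarker.to_csv(out / "feature_biomarker_correlations.csv", index=False)
    res.feature_plm.to_csv(out / "feature_plm_correlations.csv", index=False)
    res.eval_report.patient_score.to_frame("classification_score").to_csv(
        out / "patient_scores.csv"
    )
    roc = res.eval_report.roc_patient
    pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(out / "roc_patient.csv", index=False)
    m = dict(res.eval_report.metrics)
    summary = {
        "n_patients_retained": len(set(res.processed.patients)),
        "outlier_patients": res.outlier_patient_ids,
        "n_train_patients": len(res.split.train_patient_ids),
        "n_test_patients": len(res.split.test_patient_ids),
        "n_barcode_regions": len(res.barcode),
        "patient_auc": res.eval_report.roc_patient.auc,
        "spectrum_auc": res.eval_report.roc_spectrum.auc,
        "cv_auc_sem": res.eval_report.cv_auc_sem,
        "metrics": m,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=float)

    if config.make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(roc.fpr, roc.tpr, label=f"patient AUC={roc.auc:.2f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.plot(1 - roc.specificity, roc.sensitivity, "o", label="MOP")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        fig.savefig(out / "roc_patient.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(res.processed.axis, res.barcode.reference_mean, color="0.4", lw=0.8)
        for r in res.barcode.regions:
            ax.axvspan(r.lo, r.hi, color="red" if r.direction > 0 else "blue", alpha=0.3)
        ax.set_xlabel("Raman shift (cm$^{-1}$)")
        ax.set_ylabel("intensity (a.u.)")
        fig.tight_layout()
        fig.savefig(out / "barcode.png", dpi=120)
        plt.close(fig)
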