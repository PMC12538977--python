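"""Delimited-text readers and writers for spectra, metadata and run
configuration.

One flat dialect everywhere: comma-separated, UTF-8, header row, "." decimal.
The spectra matrix has the wavenumber axis in the header (after the
``patient_id`` and ``replicate`` identity columns) and one spectrum per row;
floats are written with Python's shortest round-trip representation so a
write-read cycle is bit-exact.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import ModelSpec
from .preprocess import PreprocessParams
from .spectra import SpectrumSet
from .synth import BiomarkerModel, PatientRecord, PeakSpec, SynthConfig

__all__ = [
    "write_spectra",
    "read_spectra",
    "write_metadata",
    "read_metadata",
    "RunConfig",
    "save_config",
    "load_config",
]


def write_spectra(path: str | Path, spectra: SpectrumSet) -> None:
    """Write a spectrum set as CSV: header = patient_id, replicate, axis."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "replicate"] + [repr(float(v)) for v in spectra.axis])
        for pid, rep, row in zip(spectra.patient_ids, spectra.replicates, spectra.intensities):
            w.writerow([str(pid), int(rep)] + [repr(float(v)) for v in row])


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a spectra matrix written by :func:`write_spectra`.

    Ragged rows, a non-monotone axis and duplicate ``(patient_id,
    replicate)`` keys are rejected with the offending line number.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 4 or header[:2] != ["patient_id", "replicate"]:
            raise ValueError(f"{path}: line 1: expected header 'patient_id,replicate,<axis>'")
        axis = np.array([float(v) for v in header[2:]])
        if not np.all(np.diff(axis) > 0):
            raise ValueError(f"{path}: line 1: wavenumber axis is not strictly increasing")
        pids, reps, rows = [], [], []
        seen: set = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: {len(row)} fields, expected {len(header)}"
                )
            key = (row[0], int(row[1]))
            if key in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate key {key}")
            seen.add(key)
            pids.append(row[0])
            reps.append(int(row[1]))
            rows.append([float(v) for v in row[2:]])
        if not rows:
            raise ValueError(f"{path}: no spectra")
    return SpectrumSet(axis, np.array(rows), np.array(pids, dtype=object), np.array(reps))


_META_COLS = ["patient_id", "diagnosis", "age", "sex", "abeta42", "ptau", "total_tau"]


def write_metadata(path: str | Path, records: Sequence[PatientRecord]) -> None:
    """Write patient metadata as CSV; missing total tau as an empty field."""
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "diagnosis": r.diagnosis,
                "age": r.age,
                "sex": r.sex,
                "abeta42": r.abeta42,
                "ptau": r.ptau,
                "total_tau": r.total_tau,
            }
            for r in records
        ],
        columns=_META_COLS,
    )
    df.to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        tt = row["total_tau"]
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                diagnosis=str(row["diagnosis"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                abeta42=float(row["abeta42"]),
                ptau=float(row["ptau"]),
                total_tau=None if pd.isna(tt) else float(tt),
            )
        )
    return records


@dataclasses.dataclass
class RunConfig:
    """Everything a full pipeline run needs, round-trippable through YAML."""

    output_dir: str = "runs/default"
    spectra_path: str | None = None  # read instead of simulating when set
    metadata_path: str | None = None
    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    preprocess: PreprocessParams = dataclasses.field(default_factory=PreprocessParams)
    model: ModelSpec = dataclasses.field(default_factory=ModelSpec)
    barcode_alpha: float = 0.01
    barcode_max_gap: int = 2
    barcode_min_width: int = 3
    split_ratio: float = 0.8
    split_seed: int = 0
    train_seed: int = 0
    interpret_max_points: int = 100
    interpret_samples_per_point: int = 200
    make_plots: bool = False


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    synth_d = d.pop("synth", {})
    peaks = synth_d.pop("peak_table", None)
    bm = synth_d.pop("biomarker_model", None)
    effect = synth_d.pop("effect_regions", None)
    synth = SynthConfig(
        **synth_d,
        **({"peak_table": tuple(PeakSpec(*p) if isinstance(p, (list, tuple)) else PeakSpec(**p) for p in peaks)} if peaks else {}),
        **({"biomarker_model": BiomarkerModel(**bm)} if bm else {}),
        **({"effect_regions": tuple(tuple(r) for r in effect)} if effect else {}),
    )
    baseline = synth.baseline_coeffs_range
    synth = dataclasses.replace(synth, baseline_coeffs_range=tuple(tuple(b) for b in baseline))
    pp = PreprocessParams(**d.pop("preprocess", {}))
    model = ModelSpec(**d.pop("model", {}))
    return RunConfig(synth=synth, preprocess=pp, model=model, **d)
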