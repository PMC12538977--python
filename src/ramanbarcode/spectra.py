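"""Core carrier objects: wavenumber axis, single spectra and spectrum collections.

A :class:`SpectrumSet` stores all replicate spectra of a cohort as one
2-D intensity matrix on a shared, uniformly spaced wavenumber axis, together
with patient and replicate identity and a provenance log of every processing
step applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np

__all__ = ["make_axis", "Spectrum", "SpectrumSet"]

#: relative tolerance for the uniform-spacing invariant of a wavenumber axis
_AXIS_RTOL = 1e-9


def make_axis(n_points: int, start: float, end: float) -> np.ndarray:
    """Build a uniformly spaced wavenumber axis (cm^-1).

    Parameters
    ----------
    n_points
        Number of channels, at least 2.  The instrument emulated here records
        1015 channels.
    start, end
        First and last Raman shift in cm^-1; ``end`` must exceed ``start``.
        The default acquisition range is 659-1761 cm^-1, giving a channel
        spacing of (1761-659)/1014 ~ 1.09 cm^-1.

    Returns
    -------
    numpy.ndarray
        Strictly increasing axis with exactly ``n_points`` values, first value
        ``start`` and last value ``end``.
    """
    if n_points < 2:
        raise ValueError(f"axis needs at least 2 points, got {n_points}")
    if not end > start:
        raise ValueError(f"axis span must be positive, got [{start}, {end}]")
    return np.linspace(float(start), float(end), int(n_points))


def validate_axis(axis: np.ndarray) -> np.ndarray:
    """Check the axis invariants (strictly increasing, uniform spacing)."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("axis must be a 1-D array with at least 2 points")
    d = np.diff(axis)
    if not np.all(d > 0):
        raise ValueError("axis must be strictly increasing")
    step = (axis[-1] - axis[0]) / (axis.size - 1)
    if not np.allclose(d, step, rtol=_AXIS_RTOL, atol=0.0):
        raise ValueError("axis must be uniformly spaced")
    return axis


@dataclass
class Spectrum:
    """One replicate Raman spectrum of one patient."""

    axis: np.ndarray
    intensity: np.ndarray
    patient_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.shape:
            raise ValueError(
                f"intensity length {self.intensity.size} != axis length {self.axis.size}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis, self.intensity.copy(), self.patient_id, self.replicate)


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavenumber axis.

    ``intensities`` has one row per spectrum; ``patient_ids`` and
    ``replicates`` give each row its identity.  ``(patient_id, replicate)``
    pairs are unique.  ``log`` records each processing step applied, with its
    parameters, so that a processed set can be reproduced from the raw one.
    """

    axis: np.ndarray
    intensities: np.ndarray
    patient_ids: np.ndarray
    replicates: np.ndarray
    log: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.replicates = np.asarray(self.replicates, dtype=int)
        n, p = self.intensities.shape
        if p != self.axis.size:
            raise ValueError(f"intensity columns {p} != axis length {self.axis.size}")
        if self.patient_ids.size != n or self.replicates.size != n:
            raise ValueError("patient_ids/replicates length must match spectrum count")
        keys = list(zip(self.patient_ids, self.replicates))
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate (patient_id, replicate) key: {dup}")

    # -- basic container protocol ------------------------------------------
    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield Spectrum(
                self.axis, self.intensities[i], str(self.patient_ids[i]), int(self.replicates[i])
            )

    @property
    def n_channels(self) -> int:
        return self.axis.size

    @property
    def patients(self) -> list[str]:
        """Unique patient ids in order of first appearance."""
        return list(dict.fromkeys(str(p) for p in self.patient_ids))

    # -- derived views ------------------------------------------------------
    def subset(self, mask: np.ndarray) -> "SpectrumSet":
        mask = np.asarray(mask)
        return SpectrumSet(
            self.axis,
            self.intensities[mask],
            self.patient_ids[mask],
            self.replicates[mask],
            [dict(e) for e in self.log],
        )

    def select_patients(self, ids: Sequence[str]) -> "SpectrumSet":
        wanted = set(str(i) for i in ids)
        mask = np.array([str(p) in wanted for p in self.patient_ids])
        return self.subset(mask)

    def drop_patients(self, ids: Sequence[str]) -> "SpectrumSet":
        unwanted = set(str(i) for i in ids)
        mask = np.array([str(p) not in unwanted for p in self.patient_ids])
        return self.subset(mask)

    def patient_means(self) -> tuple[list[str], np.ndarray]:
        """Per-patient mean spectra, patients in order of first appearance."""
        pats = self.patients
        means = np.empty((len(pats), self.n_channels))
        for i, p in enumerate(pats):
            means[i] = self.intensities[self.patient_ids == p].mean(axis=0)
        return pats, means

    def with_intensities(self, intensities: np.ndarray, step: dict[str, Any] | None = None) -> "SpectrumSet":
        """Return a copy carrying new intensities and an extended log."""
        log = [dict(e) for e in self.log]
        if step is not None:
            log.append(dict(step))
        return SpectrumSet(self.axis, intensities, self.patient_ids, self.replicates, log)

    def copy(self) -> "SpectrumSet":
        return self.with_intensities(self.intensities.copy())
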