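"""Seeded synthetic cohorts of CSF-like Raman spectra with patient metadata.

The generator emulates the statistical structure of a droplet-deposition
Raman study of cerebrospinal fluid in a memory-clinic cohort: 1015-channel
spectra on 659-1761 cm^-1, 30 replicate spectra per patient, a
protein-dominated fingerprint (phenylalanine ring-breathing near 1003 cm^-1,
amide III 1200-1350 cm^-1, amide I 1600-1700 cm^-1), a polynomial
fluorescence baseline, additive Gaussian noise, rare cosmic-ray spikes,
patient-level random effects, and class-dependent intensity changes confined
to a configurable set of diagnostic wavenumber regions.  ATN biomarker
concentrations (amyloid-beta 42, phospho-tau, total tau) are drawn from
class-conditional log-normal distributions coupled to the same per-patient
severity latent that scales the spectral effect.

Everything is driven by one integer seed; identical configuration gives
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .spectra import SpectrumSet, make_axis

__all__ = [
    "PeakSpec",
    "BiomarkerModel",
    "PatientRecord",
    "SynthConfig",
    "simulate_cohort",
    "inject_contamination",
    "class_template",
    "DEFAULT_PEAK_TABLE",
    "DEFAULT_BACKGROUND_BANDS",
    "DEFAULT_EFFECT_REGIONS",
]


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian band: centre (cm^-1), FWHM (cm^-1), peak height (a.u.)."""

    center: float
    fwhm: float
    amplitude: float


# A protein-dominated CSF-like fingerprint.  Band positions follow standard
# literature assignments (tryptophan 757, tyrosine doublet 830/853,
# phenylalanine 1004/1032, amide III 1240-1320, CH2 deformation 1448,
# amide I 1660); amplitudes are relative to the phenylalanine
# ring-breathing band at 1004 cm^-1.
# Diagnostic intervals are tiled by composites of narrow sub-bands (protein
# Raman bands are composites of overlapping vibrational modes), so a
# class effect fills its interval with a sharp falloff at the edges.
DEFAULT_PEAK_TABLE: tuple[PeakSpec, ...] = (
    PeakSpec(744, 7, 0.12),    # tryptophan skeletal composite, 740-771
    PeakSpec(750, 7, 0.14),
    PeakSpec(757, 7, 0.14),
    PeakSpec(764, 7, 0.13),
    PeakSpec(769, 6, 0.10),
    PeakSpec(830, 10, 0.25),   # tyrosine doublet
    PeakSpec(853, 10, 0.30),
    PeakSpec(880, 12, 0.22),   # tryptophan
    PeakSpec(936, 14, 0.28),   # C-C backbone
    PeakSpec(997, 4, 0.25),    # phenylalanine shoulder, 996-1001
    PeakSpec(1000, 4, 0.22),
    PeakSpec(1004, 6, 1.00),   # phenylalanine ring breathing, 1003-1010
    PeakSpec(1008, 5, 0.28),
    PeakSpec(1032, 8, 0.40),   # phenylalanine C-H
    PeakSpec(1080, 16, 0.30),  # C-N stretch
    PeakSpec(1126, 14, 0.25),
    PeakSpec(1192, 6, 0.14),   # aromatic C-C6H5 composite, 1189-1203
    PeakSpec(1196, 6, 0.15),
    PeakSpec(1201, 6, 0.13),
    PeakSpec(1240, 25, 0.45),  # amide III (beta)
    PeakSpec(1270, 20, 0.40),  # amide III (alpha)
    PeakSpec(1318, 13, 0.33),  # CH deformation
    PeakSpec(1330, 6, 0.20),   # tyrosine/tryptophan composite, 1328-1338
    PeakSpec(1336, 6, 0.18),
    PeakSpec(1368, 5, 0.16),   # tyrosine composite, 1366-1374
    PeakSpec(1372, 5, 0.15),
    PeakSpec(1448, 15, 0.55),  # CH2 deformation
    PeakSpec(1483, 7, 0.12),   # histidine composite, 1480-1496
    PeakSpec(1488, 7, 0.13),
    PeakSpec(1493, 7, 0.12),
    PeakSpec(1554, 12, 0.25),  # tryptophan
    PeakSpec(1606, 10, 0.30),  # phenylalanine/tyrosine ring
    PeakSpec(1660, 35, 0.90),  # amide I
    PeakSpec(1748, 4, 0.16),   # ester C=O, 1747-1751
    PeakSpec(1750, 4, 0.15),
)

# Default diagnostic regions (lo, hi, signed effect in units of the
# within-class patient SD).  The eight intervals are the recoverable
# barcode-feature bounds; signs alternate between increased and decreased
# intensity in the disease class.  Two further feature positions are not
# recoverable from the printed record and can be supplied via the config.
# Broad (~150 cm^-1 FWHM) Gaussian background bands whose per-patient
# amplitude variability emulates the biochemical matrix variation of real
# biofluid spectra; they dominate between-patient variance away from the
# sharp bands.
DEFAULT_BACKGROUND_BANDS: tuple[PeakSpec, ...] = (
    PeakSpec(800, 150, 0.30),
    PeakSpec(1100, 150, 0.30),
    PeakSpec(1450, 150, 0.30),
    PeakSpec(1650, 150, 0.30),
)

DEFAULT_EFFECT_REGIONS: tuple[tuple[float, float, float], ...] = (
    (740.0, 771.0, -1.0),
    (996.0, 1001.0, -1.0),
    (1003.0, 1010.0, +1.0),
    (1189.0, 1203.0, -1.0),
    (1328.0, 1338.0, +1.0),
    (1366.0, 1374.0, -1.0),
    (1480.0, 1496.0, +1.0),
    (1747.0, 1751.0, -1.0),
)


@dataclass(frozen=True)
class BiomarkerModel:
    """Class-conditional log-normal model for the three CSF ATN biomarkers.

    ``mu_log`` maps class -> marker -> mean of log concentration (pg/ml);
    ``sigma_log`` is the log-scale SD per marker; ``coupling`` is the slope of
    log concentration on the per-patient severity latent for disease-class
    patients, tying biomarker deviation to spectral effect magnitude.
    """

    mu_log: dict = field(
        default_factory=lambda: {
            "non-AD": {"abeta42": float(np.log(900.0)), "ptau": float(np.log(40.0)), "total_tau": float(np.log(250.0))},
            "AD": {"abeta42": float(np.log(450.0)), "ptau": float(np.log(80.0)), "total_tau": float(np.log(500.0))},
        }
    )
    sigma_log: dict = field(
        default_factory=lambda: {"abeta42": 0.35, "ptau": 0.40, "total_tau": 0.40}
    )
    coupling: dict = field(
        default_factory=lambda: {"abeta42": -0.20, "ptau": 0.25, "total_tau": 0.25}
    )


@dataclass
class PatientRecord:
    """Diagnosis, demographics and CSF biomarker concentrations of one patient."""

    patient_id: str
    diagnosis: str  # "AD" or "non-AD"
    age: float
    sex: str  # "M" or "F"
    abeta42: float
    ptau: float
    total_tau: float | None  # pg/ml, may be missing
    plm: int | None = None  # number of positive ATN markers, 0-3

    def __post_init__(self) -> None:
        if self.diagnosis not in ("AD", "non-AD"):
            raise ValueError(f"diagnosis must be 'AD' or 'non-AD', got {self.diagnosis!r}")
        for name in ("abeta42", "ptau"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.total_tau is not None and not self.total_tau > 0:
            raise ValueError(f"total_tau must be positive or missing, got {self.total_tau}")


@dataclass
class SynthConfig:
    """All knobs of the cohort generator.

    Effect sizes in ``effect_regions`` are expressed in units of the
    within-class patient-to-patient SD of band intensity, so an entry of
    ``(lo, hi, 2.0)`` separates the class means of that region's area by
    about two within-class SDs at the patient level.
    """

    n_ad: int = 67
    n_non_ad: int = 76
    spectra_per_patient: int = 30
    n_points: int = 1015
    axis_start: float = 659.0
    axis_end: float = 1761.0
    peak_table: Sequence[PeakSpec] = DEFAULT_PEAK_TABLE
    effect_regions: Sequence[tuple[float, float, float]] = DEFAULT_EFFECT_REGIONS
    baseline_coeffs_range: Sequence[tuple[float, float]] = (
        (1.0, 3.0), (-1.0, 1.0), (-1.0, 1.0), (-1.0, 1.0), (-1.0, 1.0), (-1.0, 1.0),
    )
    background_bands: Sequence[PeakSpec] = DEFAULT_BACKGROUND_BANDS
    noise_sd: float = 0.05
    patient_effect_sd: float = 0.15
    peak_jitter_sd: float = 0.08
    replicate_jitter_sd: float = 0.12
    background_jitter_sd: float = 0.30
    fine_structure_sd: float = 0.015
    fine_structure_scale: float = 5.0
    severity_spread: float = 0.3
    cosmic_ray_rate: float = 0.1
    cosmic_ray_amplitude: tuple[float, float] = (5.0, 20.0)
    contaminated_patient_ids: Sequence[str] = ()
    contamination_amplitude: float = 0.0
    biomarker_model: BiomarkerModel = field(default_factory=BiomarkerModel)
    missing_ttau_fraction: float = 7.0 / 143.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spectra_per_patient < 1:
            raise ValueError("spectra_per_patient must be >= 1")
        for sd_name in ("noise_sd", "patient_effect_sd", "peak_jitter_sd", "replicate_jitter_sd", "background_jitter_sd", "fine_structure_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        for lo, hi, _ in self.effect_regions:
            if lo < self.axis_start or hi > self.axis_end or lo > hi:
                raise ValueError(
                    f"effect region [{lo}, {hi}] outside axis "
                    f"[{self.axis_start}, {self.axis_end}]"
                )

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    half = fwhm / 2.0
    return 1.0 / (1.0 + ((x - center) / half) ** 2)


def _gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / 2.3548200450309493
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _region_of_peak(center: float, regions: Sequence[tuple[float, float, float]]) -> int:
    """Index of the effect region containing a peak centre, or -1."""
    for i, (lo, hi, _) in enumerate(regions):
        if lo <= center <= hi:
            return i
    return -1


def _effect_shifts(config: SynthConfig) -> np.ndarray:
    """Relative amplitude shift of each band in the disease class.

    The stated effect size of a region is in units of the model's
    within-class patient SD of band intensity at the region centre, which
    has three components: the region random effect, the per-band amplitude
    jitter, and the broad-background variability.  The shift applied to the
    bands of region r is therefore ``effect_r * sd_r / a_r`` with ``a_r``
    the summed band intensity at the region centre — so the class-mean
    separation at the centre is ``effect_r`` within-class SDs by
    construction.

    When both up- and down-regulated regions are present, the down-group
    shifts are rescaled so the expected net band area change is zero
    (composition-neutral effects: intensity gained by up-regulated bands is
    lost by down-regulated ones, as on a normalised intensity scale only
    relative composition is meaningful).
    """
    peaks = list(config.peak_table)
    regions = list(config.effect_regions)
    shifts = np.zeros(len(peaks))
    if not regions:
        return shifts
    peak_region = np.array([_region_of_peak(pk.center, regions) for pk in peaks])
    active = [
        ridx
        for ridx, (lo, hi, effect) in enumerate(regions)
        if effect != 0 and np.any(peak_region == ridx)
    ]
    if not active:
        return shifts
    centers = np.array([0.5 * (regions[r][0] + regions[r][1]) for r in active])

    # band intensity of each active region's members at every active centre
    A = np.zeros((len(active), len(active)))
    for j, rj in enumerate(active):
        for k in np.flatnonzero(peak_region == rj):
            A[:, j] += peaks[k].amplitude * _lorentzian(centers, peaks[k].center, peaks[k].fwhm)

    # within-class SD of band intensity at each centre
    target = np.zeros(len(active))
    for i, ri in enumerate(active):
        var = (config.patient_effect_sd * A[i, i]) ** 2
        for k in np.flatnonzero(peak_region == ri):
            var += (
                config.peak_jitter_sd
                * peaks[k].amplitude
                * _lorentzian(centers[i : i + 1], peaks[k].center, peaks[k].fwhm)[0]
            ) ** 2
        for bg in config.background_bands:
            var += (
                config.background_jitter_sd
                * bg.amplitude
                * _gaussian(centers[i : i + 1], bg.center, bg.fwhm)[0]
            ) ** 2
        var += config.fine_structure_sd**2
        var += (config.replicate_jitter_sd * A[i, i]) ** 2 / max(config.spectra_per_patient, 1)
        target[i] = regions[ri][2] * np.sqrt(var)

    # cross-talk-corrected solve: net class difference at each region centre
    # equals effect * SD there even when neighbouring bands overlap
    try:
        region_shift_active = np.linalg.solve(A, target)
    except np.linalg.LinAlgError:
        region_shift_active = np.linalg.lstsq(A, target, rcond=None)[0]
    region_shift_active = np.clip(region_shift_active, -0.8, 0.8)

    # composition neutrality: rescale the down-group so the expected net band
    # area change is zero (intensity gained by up-regulated bands is lost by
    # down-regulated ones; on a normalised intensity scale only relative
    # composition is meaningful)
    areas = np.array([pk.amplitude * pk.fwhm for pk in peaks])
    d_area = np.zeros(len(active))
    for j, rj in enumerate(active):
        d_area[j] = region_shift_active[j] * areas[peak_region == rj].sum()
    pos, neg = d_area[d_area > 0].sum(), -d_area[d_area < 0].sum()
    if pos > 0 and neg > 0:
        beta = np.sqrt(np.clip(pos / neg, 0.25, 4.0))
        region_shift_active[region_shift_active < 0] *= beta
        region_shift_active[region_shift_active > 0] /= beta

    region_shift = np.zeros(len(regions))
    for j, rj in enumerate(active):
        region_shift[rj] = region_shift_active[j]
    for k, ridx in enumerate(peak_region):
        if ridx >= 0:
            shifts[k] = region_shift[ridx]
    return shifts


def class_template(config: SynthConfig, diagnosis: str) -> np.ndarray:
    """Expected noise- and baseline-free spectrum of a class.

    Class effects scale the amplitude of every band whose centre falls inside
    an effect region multiplicatively (preserving non-negativity), with the
    shift calibrated by :func:`_effect_shifts`; the reference class carries
    the unscaled template.
    """
    axis = make_axis(config.n_points, config.axis_start, config.axis_end)
    shifts = _effect_shifts(config) if diagnosis == "AD" else np.zeros(len(list(config.peak_table)))
    out = np.zeros(config.n_points)
    for pk, sh in zip(config.peak_table, shifts):
        out += pk.amplitude * (1.0 + sh) * _lorentzian(axis, pk.center, pk.fwhm)
    for bg in config.background_bands:
        out += bg.amplitude * _gaussian(axis, bg.center, bg.fwhm)
    return out


def _contamination_shape(axis: np.ndarray) -> np.ndarray:
    """Smooth multi-band component mimicking blood (haem) contamination.

    Band positions follow haemoglobin's resonance-enhanced modes (porphyrin
    breathing ~754, C-N ~1225, ~1548/1565/1585 and ~1620 cm^-1); none
    coincides with a band of the clean model.  Normalised to maximum 1.
    """
    bands = ((754, 28, 0.7), (1225, 30, 0.5), (1548, 26, 0.9), (1565, 24, 0.8), (1585, 26, 0.7), (1620, 26, 0.6))
    shape = np.zeros_like(axis)
    for c, fwhm, a in bands:
        shape += a * _gaussian(axis, c, fwhm)
    return shape / shape.max()


def simulate_cohort(config: SynthConfig) -> tuple[SpectrumSet, list[PatientRecord]]:
    """Generate a full cohort of raw spectra and patient metadata.

    Each replicate spectrum is the sum of the patient's band model, an
    order-5 polynomial fluorescence baseline with random coefficients,
    i.i.d. Gaussian channel noise, and a Poisson number of large cosmic-ray
    spikes.  The patient band model multiplies each diagnostic region's bands
    by ``1 + g_pr + s * effect_r * patient_effect_sd`` where ``g_pr`` is a
    per-patient, per-region N(0, patient_effect_sd) random effect and ``s``
    scales the class effect by the patient's severity latent (disease class
    only).  A global per-patient intensity factor emulates droplet-to-droplet
    concentration differences.
    """
    rng = np.random.default_rng(config.seed)
    axis = make_axis(config.n_points, config.axis_start, config.axis_end)
    regions = list(config.effect_regions)

    n_total = config.n_ad + config.n_non_ad
    diagnoses = ["AD"] * config.n_ad + ["non-AD"] * config.n_non_ad
    ids = [f"P{i + 1:03d}" for i in range(n_total)]

    bm = config.biomarker_model
    records: list[PatientRecord] = []
    all_int = np.empty((n_total * config.spectra_per_patient, config.n_points))
    pat_col = np.empty(n_total * config.spectra_per_patient, dtype=object)
    rep_col = np.empty(n_total * config.spectra_per_patient, dtype=int)

    # precompute unit band profiles once
    profiles = np.stack(
        [_lorentzian(axis, pk.center, pk.fwhm) for pk in config.peak_table]
    )
    base_amps = np.array([pk.amplitude for pk in config.peak_table])
    bg_profiles = (
        np.stack([_gaussian(axis, b.center, b.fwhm) for b in config.background_bands])
        if config.background_bands
        else np.zeros((0, config.n_points))
    )
    bg_amps = np.array([b.amplitude for b in config.background_bands], dtype=float)
    peak_region = np.array(
        [_region_of_peak(pk.center, regions) for pk in config.peak_table]
    )
    effect_shift = _effect_shifts(config)  # calibrated disease-class band shifts

    t = (axis - axis[0]) / (axis[-1] - axis[0])  # [0, 1] for baseline polynomial
    row = 0
    for pid, dx in zip(ids, diagnoses):
        severity = rng.standard_normal()  # latent pathology load
        global_factor = max(0.2, 1.0 + 0.1 * rng.standard_normal())
        region_effect = rng.normal(0.0, config.patient_effect_sd, size=max(len(regions), 1))
        peak_jitter = rng.normal(0.0, config.peak_jitter_sd, size=base_amps.size)

        amps = base_amps * np.maximum(0.05, 1.0 + peak_jitter)
        for k, ridx in enumerate(peak_region):
            if ridx < 0:
                continue
            mult = 1.0 + region_effect[ridx]
            if dx == "AD":
                mult += (1.0 + config.severity_spread * severity) * effect_shift[k]
            amps[k] *= max(0.05, mult)
        bg_jitter = rng.normal(0.0, config.background_jitter_sd, size=bg_amps.size)
        patient_bg = (bg_amps * np.maximum(0.05, 1.0 + bg_jitter)) @ bg_profiles
        if config.fine_structure_sd > 0:
            white = rng.standard_normal(config.n_points)
            fine = gaussian_filter1d(white, config.fine_structure_scale, mode="reflect")
            fine *= config.fine_structure_sd / max(fine.std(), 1e-12)
        else:
            fine = 0.0
        patient_signal = global_factor * (amps @ profiles + patient_bg + fine)

        for rep in range(config.spectra_per_patient):
            coeffs = np.array([rng.uniform(lo, hi) for lo, hi in config.baseline_coeffs_range])
            baseline = np.polynomial.polynomial.polyval(t, coeffs)
            noise = (
                rng.normal(0.0, config.noise_sd, size=config.n_points)
                if config.noise_sd > 0
                else 0.0
            )
            if config.replicate_jitter_sd > 0:
                # site-to-site composition differences across the dried droplet
                rep_jitter = rng.normal(0.0, config.replicate_jitter_sd, size=amps.size)
                rep_signal = global_factor * (
                    (amps * np.maximum(0.05, 1.0 + rep_jitter)) @ profiles + patient_bg + fine
                )
            else:
                rep_signal = patient_signal
            spectrum = rep_signal + baseline + noise
            n_spikes = rng.poisson(config.cosmic_ray_rate) if config.cosmic_ray_rate > 0 else 0
            for _ in range(n_spikes):
                ch = rng.integers(0, config.n_points)
                spectrum[ch] += rng.uniform(*config.cosmic_ray_amplitude)
            all_int[row] = spectrum
            pat_col[row] = pid
            rep_col[row] = rep
            row += 1

        # biomarkers: class-conditional log-normal, coupled to severity in AD
        vals = {}
        for marker in ("abeta42", "ptau", "total_tau"):
            mu = bm.mu_log[dx][marker]
            if dx == "AD":
                mu = mu + bm.coupling[marker] * severity
            vals[marker] = float(np.exp(mu + bm.sigma_log[marker] * rng.standard_normal()))
        records.append(
            PatientRecord(
                patient_id=pid,
                diagnosis=dx,
                age=float(np.clip(rng.normal(64.0 if dx == "AD" else 68.0, 9.0 if dx == "AD" else 11.0), 40, 95)),
                sex="M" if rng.random() < (0.43 if dx == "AD" else 0.71) else "F",
                abeta42=vals["abeta42"],
                ptau=vals["ptau"],
                total_tau=vals["total_tau"],
            )
        )

    # mark a random subset of patients as missing total tau
    n_missing = int(round(config.missing_ttau_fraction * n_total))
    if n_missing > 0:
        for i in rng.choice(n_total, size=n_missing, replace=False):
            records[i].total_tau = None

    cohort = SpectrumSet(
        axis,
        all_int,
        pat_col,
        rep_col,
        log=[{"step": "simulate", "seed": config.seed, "n_patients": n_total}],
    )
    if config.contaminated_patient_ids:
        cohort = inject_contamination(
            cohort, list(config.contaminated_patient_ids), config.contamination_amplitude
        )
    return cohort, records


def inject_contamination(
    spectra: SpectrumSet, patient_ids: Sequence[str], amplitude: float
) -> SpectrumSet:
    """Add a broadband contaminant (blood-like, two broad bands) to all
    spectra of the listed patients; every other spectrum is untouched.

    Raises ``KeyError`` for a patient id not present in the set.
    """
    present = set(spectra.patients)
    for pid in patient_ids:
        if str(pid) not in present:
            raise KeyError(f"unknown patient id: {pid}")
    if not patient_ids or amplitude == 0:
        return spectra.copy()
    shape = amplitude * _contamination_shape(spectra.axis)
    out = spectra.intensities.copy()
    wanted = set(str(p) for p in patient_ids)
    mask = np.array([str(p) in wanted for p in spectra.patient_ids])
    out[mask] += shape
    return spectra.with_intensities(
        out,
        {"step": "inject_contamination", "patients": sorted(wanted), "amplitude": amplitude},
    )
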