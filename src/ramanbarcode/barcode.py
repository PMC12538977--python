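"""Spectral-barcode biomarker extraction.

The barcode method screens every wavenumber channel with a two-sided
Mann-Whitney U test between the two diagnostic classes, merges contiguous
significant channels into regions, assigns each region a direction
(increased or decreased intensity in the disease class, taken from the
training mean difference), and reduces each region to a single per-spectrum
variable: the trapezoidal area under the preprocessed spectrum across the
region.  Regions are ranked by statistical significance, rank 1 being the
most significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "ShiftPValueTrack",
    "BarcodeRegion",
    "Barcode",
    "mannwhitney_per_shift",
    "extract_regions",
    "region_area",
    "build_feature_table",
    "build_barcode",
    "rank_features",
    "per_patient_features",
]


@dataclass
class ShiftPValueTrack:
    """Per-channel Mann-Whitney results across the wavenumber axis."""

    axis: np.ndarray
    p: np.ndarray
    u_stat: np.ndarray
    direction: np.ndarray  # sign of (mean disease - mean reference) per channel

    def __post_init__(self) -> None:
        for name in ("p", "u_stat", "direction"):
            if getattr(self, name).shape != self.axis.shape:
                raise ValueError(f"{name} length must match axis length")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class BarcodeRegion:
    """A contiguous significant wavenumber interval.

    ``lo``/``hi`` are channel-centre positions (cm^-1, closed interval),
    ``direction`` is +1 for increased intensity in the disease class and -1
    for decreased, ``min_p`` the smallest channel p-value inside, ``rank``
    the 1-based significance rank, and ``p_area`` (when set by
    :func:`rank_features`) the Mann-Whitney p-value of the region's area
    feature.
    """

    lo: float
    hi: float
    direction: int
    min_p: float
    rank: int = 0
    p_area: float | None = None

    @property
    def name(self) -> str:
        return f"A({self.lo:.0f}-{self.hi:.0f})"


@dataclass
class Barcode:
    """Rank-ordered list of barcode regions with the training reference mean."""

    regions: list[BarcodeRegion]
    reference_mean: np.ndarray | None = None
    alpha: float = 0.01
    axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        ranks = sorted(r.rank for r in self.regions)
        if ranks != list(range(1, len(self.regions) + 1)):
            raise ValueError("region ranks must be a permutation of 1..K")
        ivals = sorted((r.lo, r.hi) for r in self.regions)
        for (lo1, hi1), (lo2, hi2) in zip(ivals, ivals[1:]):
            if lo2 <= hi1:
                raise ValueError(f"regions overlap: [{lo1},{hi1}] and [{lo2},{hi2}]")

    def __len__(self) -> int:
        return len(self.regions)

    def by_rank(self) -> list[BarcodeRegion]:
        return sorted(self.regions, key=lambda r: r.rank)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": r.rank,
                    "lo": r.lo,
                    "hi": r.hi,
                    "direction": r.direction,
                    "min_p": r.min_p,
                    "p_area": r.p_area,
                }
                for r in self.by_rank()
            ]
        )


def _class_matrices(
    class_a, class_b, aggregate: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    if isinstance(class_a, SpectrumSet) and isinstance(class_b, SpectrumSet):
        if not np.array_equal(class_a.axis, class_b.axis):
            raise ValueError("class sets must share one wavenumber axis")
        if aggregate == "patient":
            return class_a.patient_means()[1], class_b.patient_means()[1], class_a.axis
        return class_a.intensities, class_b.intensities, class_a.axis
    return np.atleast_2d(np.asarray(class_a, float)), np.atleast_2d(np.asarray(class_b, float)), None


def mannwhitney_per_shift(
    class_a, class_b, axis: np.ndarray | None = None, aggregate: str = "spectrum"
) -> ShiftPValueTrack:
    """Two-sided Mann-Whitney U test at every wavenumber channel.

    ``class_a`` is the disease class, ``class_b`` the reference; direction is
    the sign of the channelwise mean difference (a - b).  The exact null
    distribution is enumerated when both groups have at most 20 samples,
    otherwise the normal approximation with tie correction is used.

    ``aggregate="spectrum"`` tests every replicate spectrum as one sample —
    the convention of the emulated workflow, but anti-conservative when
    replicates of one patient are correlated; ``aggregate="patient"``
    (SpectrumSet inputs only) tests per-patient mean spectra, which keeps the
    channelwise null level nominal under patient random effects.
    """
    if aggregate not in ("spectrum", "patient"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    A, B, ax = _class_matrices(class_a, class_b, aggregate)
    if axis is None:
        axis = ax
    if axis is None:
        axis = np.arange(A.shape[1], dtype=float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 spectra per class")
    if A.shape[1] != B.shape[1]:
        raise ValueError("class matrices must have the same channel count")
    method = "exact" if max(A.shape[0], B.shape[0]) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided", method=method)
    direction = np.sign(A.mean(axis=0) - B.mean(axis=0))
    return ShiftPValueTrack(
        np.asarray(axis, float), np.minimum(res.pvalue, 1.0), res.statistic, direction
    )


def extract_regions(
    track: ShiftPValueTrack,
    alpha: float = 0.01,
    max_gap: int = 2,
    min_width: int = 3,
) -> list[BarcodeRegion]:
    """Merge significant channels into ranked barcode regions.

    Maximal runs of channels with p < ``alpha`` are found; runs separated by
    at most ``max_gap`` non-significant channels are merged, but never across
    a change of direction (adjacent bands moving in opposite directions stay
    distinct regions); merged runs narrower than ``min_width`` channels are
    discarded.  Each region's direction is the majority channel direction,
    and regions are ranked by ascending minimum p (ties broken toward the
    lower-wavenumber region).
    """
    sig = np.flatnonzero(track.p < alpha)
    if sig.size == 0:
        return []
    # group significant channels, bridging gaps of <= max_gap between
    # same-direction channels only
    groups: list[list[int]] = [[int(sig[0])]]
    for ch in sig[1:]:
        same_dir = track.direction[ch] == track.direction[groups[-1][-1]]
        if same_dir and ch - groups[-1][-1] <= max_gap + 1:
            groups[-1].append(int(ch))
        else:
            groups.append([int(ch)])
    regions = []
    for g in groups:
        lo_ch, hi_ch = g[0], g[-1]
        if hi_ch - lo_ch + 1 < min_width:
            continue
        span = slice(lo_ch, hi_ch + 1)
        dirsum = np.sum(track.direction[span][track.p[span] < alpha])
        regions.append(
            BarcodeRegion(
                lo=float(track.axis[lo_ch]),
                hi=float(track.axis[hi_ch]),
                direction=+1 if dirsum >= 0 else -1,
                min_p=float(track.p[span].min()),
            )
        )
    regions.sort(key=lambda r: (r.min_p, r.lo))
    for i, r in enumerate(regions, start=1):
        r.rank = i
    return regions


def region_area(s: Spectrum, region: BarcodeRegion) -> float:
    """Trapezoidal area of the spectrum over a region (a.u. * cm^-1).

    Integrates the raw (preprocessed) intensity above zero between the
    channels inside the closed interval [lo, hi]; a region collapsed to a
    single channel has zero area by the trapezoid convention.
    """
    axis = s.axis
    if region.lo < axis[0] or region.hi > axis[-1]:
        raise ValueError(f"region [{region.lo}, {region.hi}] outside axis range")
    mask = (axis >= region.lo) & (axis <= region.hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(s.intensity[mask], x=axis[mask]))


def build_feature_table(spectra: SpectrumSet, barcode: Barcode) -> pd.DataFrame:
    """Per-spectrum region areas, one column per barcode feature.

    Rows are indexed by ``(patient_id, replicate)``; columns follow the
    barcode's rank order (feature 1 first).
    """
    if barcode.axis is not None and not np.array_equal(spectra.axis, barcode.axis):
        raise ValueError("spectrum set axis differs from the barcode's axis")
    axis = spectra.axis
    X = spectra.intensities
    cols = {}
    for r in barcode.by_rank():
        if r.lo < axis[0] or r.hi > axis[-1]:
            raise ValueError(f"region [{r.lo}, {r.hi}] outside axis range")
        mask = (axis >= r.lo) & (axis <= r.hi)
        if mask.sum() < 2:
            cols[r.name] = np.zeros(X.shape[0])
        else:
            cols[r.name] = np.trapezoid(X[:, mask], x=axis[mask], axis=1)
    index = pd.MultiIndex.from_arrays(
        [spectra.patient_ids.astype(str), spectra.replicates],
        names=["patient_id", "replicate"],
    )
    return pd.DataFrame(cols, index=index)


def build_barcode(
    disease: SpectrumSet,
    reference: SpectrumSet,
    alpha: float = 0.01,
    max_gap: int = 2,
    min_width: int = 3,
    aggregate: str = "spectrum",
) -> Barcode:
    """Full barcode extraction from two training-class spectrum sets.

    Runs the per-channel rank test, extracts regions, and sets each region's
    direction from the sign of the mean training-class difference integrated
    over the region (one sign per region).
    """
    track = mannwhitney_per_shift(disease, reference, aggregate=aggregate)
    regions = extract_regions(track, alpha=alpha, max_gap=max_gap, min_width=min_width)
    mean_d = disease.intensities.mean(axis=0)
    mean_r = reference.intensities.mean(axis=0)
    diff = mean_d - mean_r
    for r in regions:
        mask = (track.axis >= r.lo) & (track.axis <= r.hi)
        r.direction = +1 if diff[mask].sum() >= 0 else -1
    reference_mean = np.vstack([disease.intensities, reference.intensities]).mean(axis=0)
    return Barcode(regions, reference_mean=reference_mean, alpha=alpha, axis=track.axis)


def rank_features(
    table: pd.DataFrame, labels: Sequence[str], barcode: Barcode
) -> Barcode:
    """Re-rank barcode regions by the significance of their area features.

    A Mann-Whitney test is run per feature column on the per-spectrum areas;
    regions are re-ranked by ascending p (ties toward the lower-wavenumber
    region).  Returns a new :class:`Barcode` whose regions carry ``p_area``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    a_mask = labels == classes[0]
    if a_mask.sum() < 2 or (~a_mask).sum() < 2:
        raise ValueError("need at least 2 spectra per class")
    ranked = []
    for r in barcode.by_rank():
        x = table[r.name].to_numpy()
        method = "exact" if max(a_mask.sum(), (~a_mask).sum()) <= 20 else "asymptotic"
        p = float(
            stats.mannwhitneyu(
                x[a_mask], x[~a_mask], alternative="two-sided", method=method
            ).pvalue
        )
        ranked.append(
            BarcodeRegion(r.lo, r.hi, r.direction, r.min_p, p_area=min(p, 1.0))
        )
    ranked.sort(key=lambda r: (r.p_area, r.lo))
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return Barcode(ranked, barcode.reference_mean, barcode.alpha, barcode.axis)


def per_patient_features(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-spectrum feature table to per-patient means."""
    return table.groupby(level="patient_id", sort=False).mean()
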