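# Methods

This note documents the statistical model behind `ramanbarcode`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## The synthetic cohort model

The generator (`ramanbarcode.synth`) emulates a droplet-deposition Raman
study of CSF in a memory clinic. Each patient's clean signal is a sum of
Lorentzian bands on the 1015-channel, 659–1761 cm⁻¹ axis (1.09 cm⁻¹
spacing). Band positions follow standard protein assignments (tryptophan
~757, tyrosine 830/853, phenylalanine 998/1004/1032, amide III 1240–1320,
CH₂ deformation 1448, amide I 1660 cm⁻¹). The eight diagnostic intervals
(740–771, 996–1001, 1003–1010, 1189–1203, 1328–1338, 1366–1374, 1480–1496,
1747–1751 cm⁻¹) are tiled by composites of narrow sub-bands — protein Raman
bands are composites of overlapping modes — so a class effect fills its
interval and falls off sharply at the edges. Two further diagnostic
positions of the emulated study are not publicly recoverable; the region
list is fully configurable. Four broad (~150 cm⁻¹ FWHM) Gaussian
background bands with per-patient amplitude variability stand in for the
biochemical matrix variation that dominates between-patient variance away
from the sharp bands.

Stochastic layers, all driven by one seed:

| layer | default | what it emulates |
|---|---|---|
| `noise_sd` | 0.05 a.u. | per-channel replicate noise (SNR ≈ 20 on the phenylalanine band, typical for dilute CSF) |
| `patient_effect_sd` | 0.15 | per-patient, per-region band-intensity random effect |
| `peak_jitter_sd` | 0.08 | per-patient amplitude jitter of every band |
| `replicate_jitter_sd` | 0.12 | droplet site-to-site composition differences between replicates |
| `background_jitter_sd` | 0.30 | patient-level variability of the broad background bands |
| `fine_structure_sd` | 0.015 | smooth (~5-channel) patient-specific residual structure |
| `baseline_coeffs_range` | order-5 polynomial, coefficients U(−1,1), offset U(1,3) | fluorescence background per spectrum |
| `cosmic_ray_rate` | 0.1 / spectrum | Poisson cosmic-ray spikes of amplitude 5–20 a.u. |

**Effect calibration.** An effect-region entry `(lo, hi, e)` separates the
class means at the region centre by `e` within-class patient SDs. Because
the within-class SD at a channel has several components (region effect,
band jitter, background variability, averaged replicate noise), the
generator converts `e` into a multiplicative band shift by a cross-talk-
corrected linear solve: the net class difference at every region centre —
including tails of neighbouring, possibly oppositely-shifted bands such as
the 996–1001/1003–1010 pair — equals `e` times the model's within-class SD
there.

**Composition neutrality.** Preprocessed spectra are unit-norm, so a net
gain of intensity in up-regulated bands must reappear as a loss spread over
all other channels; the order-5 baseline fit likewise redistributes any net
band-area change into smooth lobes across the whole spectrum. Both would
manufacture broad spurious "significant" regions that no practitioner would
interpret as bands. The generator therefore makes class effects
composition-neutral: after calibration, the down-regulated group is
rescaled so the expected net band-area change is zero — the intensity
gained by up-regulated bands is lost by down-regulated ones, as on a
normalised intensity scale only relative composition is meaningful.

**Biomarkers.** Aβ42, p-tau and total tau are class-conditional log-normal
(AD medians 450/80/500 pg/ml, non-AD 900/40/250, log-SD 0.35–0.40). A
per-patient severity latent scales the AD spectral effect
(`severity_spread` = 0.3) and shifts the AD log-concentrations
(couplings −0.20/+0.25/+0.25), so region areas and biomarkers co-vary
within the AD class, not just between classes. A configurable fraction
(default 7/143) of patients lacks total tau. Age and sex follow the
emulated cohort (AD 64 ± 9 y, 43% male; non-AD 68 ± 11 y, 71% male).

Blood contamination (`inject_contamination`) adds a smooth multi-band
haemoglobin-like component (754, 1225, 1548/1565/1585, 1620 cm⁻¹) to every
spectrum of the listed patients.

What the generator does **not** model: coffee-ring drying physics,
wavelength-dependent instrument response, detector etaloning, non-Gaussian
noise, mixed pathologies, or realistic covariance between age/sex and the
spectrum. Passing tests therefore demonstrate that the pipeline's
statistics behave as claimed under a faithful random-effects model of such
a study — not that any particular clinical accuracy would be attained on
real CSF.

## Preprocessing

The chain is: background subtraction (mean of three substrate spectra, when
provided) → cosmic-spike replacement (rolling-median modified z > 8,
window 7) → Haar wavelet denoising → order-5 polynomial baseline removal →
rubberband end anchoring → vector normalisation → spectrum-level then
patient-level outlier removal. A provenance log records every step with
its parameters; `replay_log` reproduces a processed set bit-exactly.

*Wavelet denoising.* Spectra are symmetrically padded to 1024 channels,
decomposed to 6 levels, and detail coefficients are **hard**-thresholded at
the universal threshold σ√(2 ln n), σ from the finest-level MAD. Soft
shrinkage (available as `mode="soft"`) subtracts the threshold from every
retained coefficient; at realistic noise this biases 4–6-channel bands
enough to visibly blunt the diagnostic intervals, so the unbiased hard rule
is the default.

*Rubberband.* Interpreted as end-point line subtraction (both end channels
exactly zero), since the polynomial step has already removed the smooth
background; the classical lower-convex-hull mode is available via
`convex_hull=True`.

*Outlier screening.* At each level a PCA (3 components by default) is
fitted; the outlier distance is the larger of (a) the worst per-component
robust z of the scores and (b) the robust z of the log residual norm off
the component plane (the orthogonal distance, which catches shapes such as
a contaminant band that the components cannot represent). Each statistic
is rescaled by a sample-size-adapted Gaussian cut so that a threshold of 3
corresponds to an expected false-flag count below 0.01 per screen, and the
PCA is refitted once without the most extreme ~5% of samples so outliers
cannot pull the components toward themselves. Thresholds and component
counts are configurable (`PreprocessParams`).

## Barcode extraction

Per-channel two-sided Mann-Whitney U tests (exact enumeration when both
groups have ≤ 20 samples, otherwise the tie-corrected normal
approximation). Runs of channels with p < α (default 0.01) are merged
across gaps of ≤ 2 non-significant channels, **never across a change of
direction** (adjacent bands moving oppositely — like the phenylalanine
pair — remain distinct), and runs narrower than 3 channels are discarded.
Regions are ranked by minimum channel p (ties to the lower wavenumber);
each region's direction comes from the integrated training-mean difference,
so one region has one sign. Region areas are plain trapezoidal integrals of
the preprocessed (normalised) intensity with no local chord subtraction.

Two testing units are supported. `aggregate="spectrum"` treats every
replicate as a sample — the convention of the emulated workflow — but is
anti-conservative when replicates share patient-level random effects (the
channelwise null rate can reach tens of percent). `aggregate="patient"`
tests per-patient mean spectra and keeps the null at its nominal level; the
validation suites use it for all null-rate and region-recovery claims. The
pipeline default remains per-spectrum for fidelity, with the caveat noted
here.

## Classification protocol

Patients are split 80:20 per class by nearest-integer rounding (66 + 75
patients give 53 + 60 = 113 training, 28 testing). Models: a bagged
decision tree on barcode features, or a linear SVM on PCA scores retaining
95% variance (projector fitted on training spectra only). Hyperparameters
are tuned by a 20-candidate random search (tree count/depth/leaf size, or
SVM C) scored by cross-validated AUC; CV folds are grouped by patient so
replicate spectra never straddle folds — an explicit leakage guard the
`--ungrouped-cv` reading would forgo. The tuned model is refitted 10 times
with reshuffled grouped folds; the SEM of the CV AUCs quantifies protocol
variability, and test predictions are averaged over the retrains.
Misclassification costs default to equal and can be supplied as a 2×2
matrix (mapped to class weights).

Per-patient classification score = 100 × (# replicate spectra called
AD)/(# spectra), averaged over retrains. ROC curves are computed at both
levels; the model operating point maximises Youden's J (ties toward higher
specificity) and defines the reported accuracy/sensitivity/specificity/
PPV/NPV/F1.

## Interpretation

Global surrogate importance: for each (optionally subsampled) training
point, features are perturbed in z-scored space at the kernel scale,
perturbations are weighted by a Gaussian kernel of width 0.5 with a
dimension-normalised distance, and a depth-3 regression tree is fitted to
the model's predicted AD probability; a feature's global importance is the
mean absolute local weight. Perturbing at the kernel scale keeps the
weighted effective sample size useful — with unit-scale perturbations and
kernel width 0.5 essentially no perturbation carries weight and the local
fits are noise. Partial dependence is the standard average-prediction
curve over a grid spanning the observed feature range; its maximum is
reported per feature.

## PLM scoring and partial correlations

PLM = number of positive ATN markers (Aβ42 < 680, p-tau > 56, total tau >
355 pg/ml; strict inequalities); undefined when a marker is missing.
Partial correlation residualises both variables on the covariates (age,
sex 0/1) with an intercept and correlates the residuals; p-values use
t = r√((n−2−k)/(1−r²)). Concentrations are natural-log transformed —
the correlation is invariant to the log base. Patients missing total tau
are excluded from total-tau tests only. Two separate BH families at FDR
5%: the 10 features × 3 biomarkers (30 tests) and the 10 feature–PLM tests.
A residual whose norm is at rounding level (covariates explaining the
variable exactly, e.g. an age column affine in the variable) makes the
partial correlation undefined and raises rather than returning noise.

## Validation problem sizes

The Monte-Carlo suites in `tests/test_acceptance.py` use: region recovery —
50 cohorts of 40 + 40 patients × 30 replicates with 1-SD effects, mean
best-match Jaccard against the injected intervals ≥ 0.5; null channel rate
— 50 null cohorts (40 + 40 × 10), mean significant-channel fraction ≈ 1% at
α = 0.01; classification power — 50 cohorts of 20 + 20 patients × 8
replicates per effect size in {0, 0.5, 1, 2} SD with a 2-candidate search
and 2 retrains, patient-level AUC ≈ 0.5 at zero effect, ≥ 0.9 at 2 SD,
non-decreasing, and above the spectrum-level AUC; FDR control — 500 null
feature–biomarker families of 30 tests at 60 patients. The contamination
screen is validated on the full 143-patient reference cohort. Across seeds
the screen occasionally (≈1 cohort in 15) also flags one genuinely extreme
clean patient; on small cohorts (≲30 patients) the robust scale estimates
are noisier and extra flags are more common.

## Known limitations

- The spectrum-level rank test inherits the pseudo-replication of the
  emulated workflow; patient-level aggregation is provided and recommended.
- Narrow printed intervals (4–5 cm⁻¹) can never be recovered with high
  Jaccard overlap by any band-shaped effect, since a band's tails extend
  beyond the interval; recovery is assessed as a cohort-level average.
- The outlier screen is a heuristic: its false-flag calibration assumes
  roughly Gaussian patient-level variation and degrades on very small
  cohorts.
- The surrogate-importance and partial-dependence analyses explain the
  fitted model, not the biology.
- The convolutional-network variant of the emulated workflow is out of
  scope; the model interface (`ModelSpec.kind`) is pluggable so one can be
  added.
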