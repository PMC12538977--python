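"""Simulate a synthetic CSF Raman cohort and write it to delimited text.

The generator produces replicate spectra per patient on the 1015-channel
659-1761 cm^-1 axis, with disease-dependent intensity changes confined to
eight diagnostic wavenumber intervals, plus patient metadata whose ATN
biomarker concentrations (amyloid-beta 42, p-tau, total tau, pg/ml) are
coupled to the spectral effect through a per-patient severity latent.
"""

import numpy as np

import ramanbarcode as rb

config = rb.SynthConfig(n_ad=12, n_non_ad=12, spectra_per_patient=10, seed=42)
spectra, records = rb.simulate_cohort(config)

rb.write_spectra("cohort_spectra.csv", spectra)
rb.write_metadata("cohort_metadata.csv", records)

ad = [r for r in records if r.diagnosis == "AD"]
non = [r for r in records if r.diagnosis == "non-AD"]
print(f"cohort: {len(records)} patients, {len(spectra)} spectra, "
      f"{spectra.n_channels} channels "
      f"({spectra.axis[0]:.0f}-{spectra.axis[-1]:.0f} cm^-1)")
print(f"median p-tau  AD: {np.median([r.ptau for r in ad]):6.1f} pg/ml   "
      f"non-AD: {np.median([r.ptau for r in non]):6.1f} pg/ml")
print(f"median Ab42   AD: {np.median([r.abeta42 for r in ad]):6.1f} pg/ml   "
      f"non-AD: {np.median([r.abeta42 for r in non]):6.1f} pg/ml")
# Disease-class p-tau should sit well above the 56 pg/ml positivity cutoff
# and amyloid-beta 42 below its 680 pg/ml cutoff, as in a memory-clinic
# cohort; spectra land in cohort_spectra.csv for the downstream examples.
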