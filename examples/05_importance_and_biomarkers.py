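"""Feature importance of the classifier and partial correlations with CSF
biomarkers.

Runs the full pipeline, then shows (a) which barcode features drive the
model, by kernel-weighted surrogate importance and partial-dependence
maxima, and (b) age/sex-adjusted partial correlations between per-patient
region areas and log-transformed ATN biomarker concentrations, with
Benjamini-Hochberg FDR control over the family of tests.
"""

import ramanbarcode as rb

result = rb.run_pipeline(
    rb.RunConfig(
        output_dir="run_interpret",
        synth=rb.SynthConfig(n_ad=30, n_non_ad=30, spectra_per_patient=10, seed=3),
        model=rb.ModelSpec(tuning_budget=3, n_retrains=3),
        interpret_max_points=60,
        interpret_samples_per_point=200,
    )
)

print("feature importance (mean |local surrogate weight|, PD maximum):")
print(result.importance.to_frame().round(3).to_string())

fb = result.feature_biomarker
print(f"\nfeature-biomarker partial correlations: {len(fb)} tests, "
      f"{int(fb.significant.sum())} significant at FDR 5%")
print(fb[fb.significant][["x", "y", "n", "r", "p_adj"]].round(3).to_string(index=False))

plm = result.feature_plm
print(f"\nfeature-PLM correlations: {len(plm)} tests, "
      f"{int(plm.significant.sum())} significant at FDR 5%")
if result.score_plm is not None:
    s = result.score_plm
    print(f"classification score vs PLM status (test patients): "
          f"r = {s.r:.2f}, p = {s.p_raw:.3f} (adjusted for age and sex)")
# The top-importance features are the injected diagnostic regions; the
# significant correlations connect those same region areas to the
# biomarkers they were coupled to in the generator (p-tau and total tau up,
# amyloid-beta 42 down in the disease class).
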