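"""Preprocessing contracts: each correction step, the outlier screens and
provenance replay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ramanbarcode as rb
from ramanbarcode.spectra import Spectrum
from ramanbarcode.preprocess import replay_log


def spec(y, axis=None):
    y = np.asarray(y, dtype=float)
    if axis is None:
        axis = np.arange(y.size, dtype=float)
    return Spectrum(axis, y)


class TestSubtractBackground:
    def test_mean_of_three_backgrounds(self):
        s = spec([4.0, 4.0])
        bgs = [spec([2.0, 2.0]), spec([4.0, 4.0]), spec([6.0, 6.0])]
        assert np.allclose(rb.subtract_background(s, bgs).intensity, [0, 0])

    def test_zero_backgrounds_identity(self):
        s = spec([1.0, 2.0, 3.0])
        bgs = [spec([0.0, 0.0, 0.0])] * 3
        assert np.allclose(rb.subtract_background(s, bgs).intensity, s.intensity)

    def test_backgrounds_equal_to_signal_give_zero(self):
        s = spec([1.0, 2.0, 3.0])
        assert np.allclose(rb.subtract_background(s, [s, s, s]).intensity, 0.0)

    def test_axis_mismatch_rejected(self):
        s = spec([1.0, 2.0])
        with pytest.raises(ValueError):
            rb.subtract_background(s, [spec([1.0, 2.0, 3.0])] * 3)


class TestRemoveSpikes:
    def test_smooth_spectrum_unchanged(self):
        axis = np.linspace(0, 100, 200)
        s = Spectrum(axis, np.exp(-0.5 * ((axis - 50) / 8) ** 2))
        assert np.array_equal(rb.remove_spikes(s).intensity, s.intensity)

    def test_single_spike_replaced_neighbours_untouched(self):
        rng = np.random.default_rng(0)
        y = 1.0 + 0.01 * rng.standard_normal(101)
        y[50] = 100.0
        out = rb.remove_spikes(spec(y)).intensity
        assert out[50] < 2.0  # replaced by local median
        mask = np.ones(101, bool)
        mask[50] = False
        assert np.array_equal(out[mask], y[mask])

    def test_constant_spectrum_unchanged(self):
        s = spec(np.full(64, 3.0))
        assert np.array_equal(rb.remove_spikes(s).intensity, s.intensity)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            rb.remove_spikes(spec(np.zeros(16)), window=4)


class TestDenoiseWavelet:
    def test_constant_spectrum_unchanged(self):
        s = spec(np.full(128, 5.0))
        assert np.allclose(rb.denoise_wavelet(s).intensity, 5.0, atol=1e-10)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        sds = []
        for _ in range(100):
            s = spec(rng.standard_normal(256))
            sds.append(rb.denoise_wavelet(s).intensity.std())
        assert np.mean(sds) < 1.0

    def test_rmse_to_clean_signal_improves(self):
        rng = np.random.default_rng(2)
        axis = np.linspace(0, 1, 512)
        clean = np.sin(6 * np.pi * axis) + 2 * np.exp(-0.5 * ((axis - 0.5) / 0.05) ** 2)
        improved = 0
        for _ in range(20):
            noisy = clean + 0.1 * rng.standard_normal(512)
            den = rb.denoise_wavelet(Spectrum(axis, noisy)).intensity
            if np.sqrt(np.mean((den - clean) ** 2)) < np.sqrt(np.mean((noisy - clean) ** 2)):
                improved += 1
        assert improved >= 18

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            rb.denoise_wavelet(spec(np.zeros(32)), levels=6)


class TestPolyBaseline:
    @pytest.mark.parametrize("order", [0, 1, 3, 5])
    def test_polynomial_inputs_annihilated(self, order):
        axis = np.linspace(659, 1761, 200)
        coeffs = np.arange(order + 1, dtype=float) + 1
        y = np.polynomial.polynomial.polyval((axis - 659) / 1102, coeffs)
        out = rb.subtract_poly_baseline(Spectrum(axis, y)).intensity
        assert np.max(np.abs(out)) < 1e-8 * max(np.max(np.abs(y)), 1)

    def test_constant_becomes_zero(self):
        out = rb.subtract_poly_baseline(spec(np.full(100, 7.0))).intensity
        assert np.max(np.abs(out)) < 1e-10

    def test_narrow_peak_height_preserved(self):
        axis = np.linspace(0, 1, 500)
        baseline = 3 + 2 * axis - axis**2
        peak = np.exp(-0.5 * ((axis - 0.5) / 0.01) ** 2)
        out = rb.subtract_poly_baseline(Spectrum(axis, baseline + peak)).intensity
        # oracle: the direct least-squares fit of the same design matrix
        V = np.polynomial.polynomial.polyvander(2 * axis - 1, 5)
        resid = (baseline + peak) - V @ np.linalg.lstsq(V, baseline + peak, rcond=None)[0]
        assert np.allclose(out, resid, atol=1e-10)
        assert abs(out[250] - peak[250]) < 0.15


class TestRubberband:
    def test_linear_spectrum_zeroed(self):
        axis = np.arange(50, dtype=float)
        out = rb.rubberband_anchor(Spectrum(axis, 2 * axis + 3)).intensity
        assert np.max(np.abs(out)) < 1e-12

    def test_three_point_example(self):
        out = rb.rubberband_anchor(spec([1.0, 5.0, 3.0])).intensity
        assert np.allclose(out, [0.0, 3.0, 0.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_endpoints_always_zero(self, seed):
        y = np.random.default_rng(seed).standard_normal(37)
        out = rb.rubberband_anchor(spec(y)).intensity
        assert out[0] == 0.0 and out[-1] == 0.0

    def test_convex_hull_mode_lower_bound(self):
        rng = np.random.default_rng(3)
        y = np.abs(rng.standard_normal(80)) + 1
        out = rb.rubberband_anchor(spec(y), convex_hull=True).intensity
        assert out.min() >= -1e-10


class TestVectorNormalize:
    def test_three_four_five(self):
        assert np.allclose(rb.vector_normalize(spec([3.0, 4.0])).intensity, [0.6, 0.8])

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        s = spec(rng.standard_normal(64))
        once = rb.vector_normalize(s)
        twice = rb.vector_normalize(once)
        assert np.allclose(once.intensity, twice.intensity, atol=1e-12)
        assert abs(np.linalg.norm(once.intensity) - 1.0) < 1e-12

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            rb.vector_normalize(spec(np.zeros(8)))


def _replicate_set(rows, pid="A"):
    rows = np.asarray(rows, dtype=float)
    axis = np.arange(rows.shape[1], dtype=float)
    return rb.SpectrumSet(
        axis, rows, np.array([pid] * rows.shape[0], dtype=object), np.arange(rows.shape[0])
    )


class TestSpectrumOutliers:
    def test_identical_replicates_no_outliers(self):
        s = _replicate_set(np.tile(np.sin(np.arange(64) / 5), (10, 1)))
        assert rb.pca_outliers_spectra(s).removed_spectrum_keys == []

    def test_single_deviant_replicate_flagged(self):
        rng = np.random.default_rng(5)
        base = np.sin(np.arange(64) / 5)
        rows = np.tile(base, (30, 1)) + 0.01 * rng.standard_normal((30, 64))
        rows[7] += 5 * np.exp(-0.5 * ((np.arange(64) - 30) / 4) ** 2)
        report = rb.pca_outliers_spectra(_replicate_set(rows))
        assert report.removed_spectrum_keys == [("A", 7)]

    def test_infinite_threshold_empty_report(self):
        rng = np.random.default_rng(6)
        s = _replicate_set(rng.standard_normal((10, 32)))
        assert rb.pca_outliers_spectra(s, dist_thresh=np.inf).removed_spectrum_keys == []

    def test_single_spectrum_patient_warns(self):
        s = _replicate_set(np.random.default_rng(7).standard_normal((1, 32)))
        with pytest.warns(UserWarning):
            report = rb.pca_outliers_spectra(s)
        assert report.removed_spectrum_keys == []


class TestPatientOutliers:
    def test_homogeneous_cohort_none_flagged(self, processed_small):
        _, processed, _, report = processed_small
        assert report.removed_patient_ids == []

    def test_contaminated_patients_flagged(self):
        cfg = rb.SynthConfig(n_ad=20, n_non_ad=20, spectra_per_patient=8, seed=9)
        spectra, _ = rb.simulate_cohort(cfg)
        spectra = rb.inject_contamination(spectra, ["P004", "P031"], 10 * cfg.noise_sd)
        processed, report = rb.preprocess_pipeline(spectra)
        assert sorted(report.removed_patient_ids) == ["P004", "P031"]
        assert len(set(processed.patients)) == 38

    def test_permutation_invariance(self):
        cfg = rb.SynthConfig(n_ad=6, n_non_ad=6, spectra_per_patient=5, seed=10)
        spectra, _ = rb.simulate_cohort(cfg)
        spectra = rb.inject_contamination(spectra, ["P002"], 10 * cfg.noise_sd)
        perm = np.random.default_rng(0).permutation(len(spectra))
        flagged1 = set(rb.pca_outliers_patients(spectra).removed_patient_ids)
        flagged2 = set(rb.pca_outliers_patients(spectra.subset(perm)).removed_patient_ids)
        assert flagged1 == flagged2

    def test_too_few_patients_rejected(self):
        s = _replicate_set(np.random.default_rng(1).standard_normal((4, 32)))
        with pytest.raises(ValueError):
            rb.pca_outliers_patients(s)


class TestPipeline:
    def test_unit_norm_and_zero_ends(self, processed_small):
        _, processed, _, _ = processed_small
        norms = np.linalg.norm(processed.intensities, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert np.allclose(processed.intensities[:, 0], 0.0)
        assert np.allclose(processed.intensities[:, -1], 0.0)

    def test_provenance_replay_reproduces_output(self, small_cohort):
        _, spectra, _ = small_cohort
        processed, _ = rb.preprocess_pipeline(spectra)
        replayed = replay_log(spectra, processed.log)
        assert np.array_equal(replayed.intensities, processed.intensities)
        assert list(replayed.patient_ids) == list(processed.patient_ids)
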