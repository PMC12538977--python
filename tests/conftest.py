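import warnings

import numpy as np
import pytest

import ramanbarcode as rb

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort: 10+10 patients, 6 replicates each."""
    cfg = rb.SynthConfig(n_ad=10, n_non_ad=10, spectra_per_patient=6, seed=7)
    spectra, records = rb.simulate_cohort(cfg)
    return cfg, spectra, records


@pytest.fixture(scope="session")
def processed_small(small_cohort):
    cfg, spectra, records = small_cohort
    processed, report = rb.preprocess_pipeline(spectra)
    return cfg, processed, records, report


@pytest.fixture(scope="session")
def class_split(processed_small):
    """Processed spectra split into the two diagnostic classes."""
    cfg, processed, records, _ = processed_small
    dx = {r.patient_id: r.diagnosis for r in records}
    ad_mask = np.array([dx[str(p)] == "AD" for p in processed.patient_ids])
    return processed.subset(ad_mask), processed.subset(~ad_mask), records
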