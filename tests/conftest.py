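import numpy as np
import pytest

import ucnmr as u


@pytest.fixture(scope="session")
def library():
    return u.default_metabolite_library()


@pytest.fixture(scope="session")
def annotation(library):
    return u.annotate_buckets(
        {sig.name: sig.primary_ppm for sig in library if sig.primary_ppm is not None}
    )


@pytest.fixture(scope="session")
def uceis_effects():
    return u.default_effect_tables()["uceis_high_vs_low"]


@pytest.fixture(scope="session")
def clean_cohort(uceis_effects):
    """Deterministic cohort: no biological variation, no noise, no jitter."""
    cohort = u.CohortSpec(
        between_subject_cv=0.0, noise_sd=0.0, shift_jitter_sd=0.0,
        global_shift_sd=0.0, baseline_drift_amplitude=0.0, master_seed=5,
    )
    fids, meta = u.simulate_cohort(
        cohort, uceis_effects, rng=np.random.default_rng(5), return_fids=True
    )
    table = u.process_spectra(fids, list(meta["sample_id"]))
    return table, meta["class_label"].to_numpy()


@pytest.fixture(scope="session")
def effect_cohort(uceis_effects):
    """Realistic low-noise cohort carrying the endoscopic-activity effects."""
    cohort = u.CohortSpec(between_subject_cv=0.05, noise_sd=1.0, master_seed=11)
    fids, meta = u.simulate_cohort(
        cohort, uceis_effects, rng=np.random.default_rng(11), return_fids=True
    )
    table = u.process_spectra(fids, list(meta["sample_id"]))
    return table, meta["class_label"].to_numpy()
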