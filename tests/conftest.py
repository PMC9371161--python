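import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# generator-rate warnings etc. are expected in bulk runs
logging.getLogger("apnea_mer").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def short_record():
    """One 600-s synthetic record with events, shared across test modules."""
    from apnea_mer import synth

    cfg = synth.SyntheticConfig(n_patients=1, record_s=600.0, seed=11)
    record, annotations, truth = synth.generate_record(cfg, 0)
    return record, annotations, truth


@pytest.fixture(scope="session")
def preprocessed_record(short_record):
    from apnea_mer import features

    record, annotations, truth = short_record
    return features.preprocess_record(record), annotations, truth


@pytest.fixture(scope="session")
def small_window_table():
    """Feature table from a 6-patient, 20-minute cohort (60-s windows)."""
    from apnea_mer import features, synth

    cfg = synth.SyntheticConfig(n_patients=6, record_s=1200.0, seed=5)
    cohort = synth.generate_cohort(cfg)
    return features.extract_table([(r, a) for r, a, _ in cohort], mode="windows")


@pytest.fixture(scope="session")
def end_to_end_result():
    """The full study-scale pipeline run (40 patients, 1-h records), seed 0."""
    from apnea_mer import pipeline

    return pipeline.run_end_to_end(seed=0)
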