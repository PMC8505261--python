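import numpy as np
import pandas as pd
import pytest

from moodmarkers import ExpressionMatrix, SimConfig, generate_cohort
from moodmarkers.preprocess import SCALE_LOG2


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_probesets=300, n_markers_planted=20, effect_log2fc=1.0,
                     noise_sd=0.2, n_subjects_discovery=40,
                     n_subjects_validation=30, n_subjects_test=60, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One seeded synthetic cohort shared by read-only tests."""
    return generate_cohort(small_config)


def make_visits(rows):
    """Minimal visit table from (subject, visit, days, gender, dx, sms7) tuples."""
    df = pd.DataFrame(rows, columns=["subject_id", "visit_number",
                                     "days_since_first", "gender",
                                     "diagnosis", "sms7"])
    df["hamd"] = 0.0
    df["ymrs"] = 0.0
    df["sample_id"] = df["subject_id"] + "_v" + df["visit_number"].astype(str)
    return df


def make_matrix(values, sample_ids, probesets=None, scale=SCALE_LOG2):
    values = np.asarray(values, dtype=float)
    probesets = probesets or [f"p{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=probesets, columns=sample_ids), scale)
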