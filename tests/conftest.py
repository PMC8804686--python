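import warnings

import numpy as np
import pandas as pd
import pytest

from iraeab.config import AnalysisConfig, CohortConfig
from iraeab.differential import assign_groups, run_de
from iraeab.signal import build_abs_matrices, filter_antigens, normalize_rlm
from iraeab.synthetic import generate_cohort


@pytest.fixture(scope="session")
def default_study():
    """One default 60-patient study shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()


def process_isotype(study, isotype="IgG", timepoint="baseline"):
    """Filter + score + normalize one (isotype, timepoint) matrix."""
    signals = study.signals
    retained, _ = filter_antigens(signals, isotype=isotype)
    sub = signals[(signals["isotype"] == isotype) & (signals["timepoint"] == timepoint)]
    matrices = build_abs_matrices(sub, retained={isotype: retained})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalized, report = normalize_rlm(matrices[(isotype, timepoint)])
    return normalized, report


@pytest.fixture(scope="session")
def processed_baseline_igg(default_study):
    matrix, _ = process_isotype(default_study)
    return matrix


def null_de_run(seed: int, grouping=("first_half",), config_kwargs=None, alpha=0.05):
    """Generate a cohort and run baseline-IgG DE; shared by calibration tests."""
    kwargs = {"dim_antigen_fraction": 0.0}
    kwargs.update(config_kwargs or {})
    study = generate_cohort(CohortConfig(seed=seed, **kwargs))
    matrix, _ = process_isotype(study)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ga = assign_groups(study.events, study.clinical, grouping)
        return run_de(matrix, ga, alpha=alpha)


def make_events(rows):
    """Events table from (patient, organ, grade, onset, attribution) tuples."""
    return pd.DataFrame(
        rows, columns=["patient_id", "organ", "grade", "onset_week", "attribution"]
    )


def make_clinical(patient_ids, **cols):
    n = len(patient_ids)
    base = {
        "patient_id": patient_ids,
        "age": np.full(n, 60),
        "sex": ["male"] * n,
        "stage": ["IV"] * n,
        "melanoma_type": ["cutaneous"] * n,
        "ici_cycles": np.full(n, 5),
        "has_week6": [True] * n,
        "followup_months": np.full(n, 25.0),
    }
    base.update(cols)
    return pd.DataFrame(base)
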