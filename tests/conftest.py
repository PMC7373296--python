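import numpy as np
import pandas as pd
import pytest

from ccproteo.cohort import CohortConfig, CohortTable, EffectSpec, generate_cohort


@pytest.fixture
def tiny_config():
    """Fast cohort: 15/15 subjects, 12 proteins, no missingness, no effects."""
    return CohortConfig(
        n_cases=15, n_controls=15, n_proteins=12,
        detection_quantile=0.0, mcar_rate=0.0, seed=42,
    )


@pytest.fixture
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture
def signal_config():
    """Study-scale cohort with one strong U-shaped protein and one linear."""
    return CohortConfig(
        n_cases=39, n_controls=41, n_proteins=15,
        effect_specs=(EffectSpec(0, beta1=0.0, beta2=1.8),
                      EffectSpec(1, beta1=0.8)),
        seed=10,
    )


@pytest.fixture
def hand_table():
    """Hand-built 4-subject x 3-protein table with one missing cell."""
    quantities = pd.DataFrame(
        {
            "P1": [4.0, 10.0, np.nan, 6.0],
            "P2": [1.0, 2.0, 3.0, 4.0],
            "P3": [100.0, 200.0, 400.0, 800.0],
        },
        index=pd.Index(["S1", "S2", "S3", "S4"], name="subject_id"),
    )
    subjects = pd.DataFrame(
        {
            "outcome": ["case", "case", "control", "control"],
            "age": [50.0, 60.0, 55.0, 45.0],
            "sex": ["female"] * 4,
            "race": ["white"] * 4,
            "site": ["new_york"] * 4,
            "season": ["summer", "fall", "summer", "fall"],
            "bmi_class": ["normal"] * 4,
            "sr_ibs": ["no"] * 4,
            "antidepressant": ["no"] * 4,
            "batch": [1, 1, 1, 1],
        },
        index=quantities.index,
    )
    return CohortTable(quantities, subjects)
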