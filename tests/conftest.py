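import numpy as np
import pandas as pd
import pytest

import evosig as es


@pytest.fixture(scope="session")
def small_truth() -> es.SimTruth:
    """Compact ground truth: 60 genes, 4 planted signature genes."""
    return es.make_truth(
        n_genes=60,
        n_signature=4,
        n_q1_extra=8,
        n_q2=6,
        n_q3=6,
        n_q4=6,
        n_de_extra=6,
        n_trend_up=5,
        n_trend_down=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    cohort, _ = es.gen_survival_cohort(300, small_truth, seed=21)
    return cohort


@pytest.fixture(scope="session")
def small_multiregion(small_truth):
    data, _ = es.gen_multiregion(30, (3, 5), small_truth, seed=22)
    return data


@pytest.fixture
def hand_multiregion() -> es.MultiRegionMatrix:
    """Two patients, two regions each: values (0,2) and (4,6)."""
    vals = pd.DataFrame(
        [[0.0, 2.0, 4.0, 6.0]], index=["g1"], columns=["a1", "a2", "b1", "b2"]
    )
    meta = pd.DataFrame(
        {
            "patient_id": ["A", "A", "B", "B"],
            "region_id": ["R1", "R2", "R1", "R2"],
        },
        index=pd.Index(["a1", "a2", "b1", "b2"], name="sample_id"),
    )
    return es.MultiRegionMatrix(vals, meta)
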