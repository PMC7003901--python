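import numpy as np
import pytest

from spnma.data import ArmRecord, NMADataset, StudyRecord


def make_arm(study_id, arm_index, treatment, counts, n=100, E=None, tbar=None):
    return ArmRecord(
        study_id=study_id,
        arm_index=arm_index,
        treatment=treatment,
        n_randomized=n,
        counts=dict(counts),
        person_years=E,
        mean_followup=tbar,
    ).with_followup_filled()


@pytest.fixture
def mixed_format_dataset():
    """Small three-study dataset covering all three formats and a mortality
    outcome (index 2) reported by the format-2 study."""
    s1 = StudyRecord(
        "trial-a", 1,
        [
            make_arm("trial-a", 1, 1, {1: 4, 2: 3}, E=97.0),
            make_arm("trial-a", 2, 2, {1: 3, 2: 5}, E=96.5),
        ],
    )
    s2 = StudyRecord(
        "trial-b", 2,
        [
            make_arm("trial-b", 1, 1, {1: 6, 2: 4}, E=100.0),
            make_arm("trial-b", 2, 3, {1: 5, 2: 2}, E=100.0),
        ],
    )
    s3 = StudyRecord(
        "trial-c", 3,
        [
            make_arm("trial-c", 1, 2, {1: 7, 2: 5}, E=110.0),
            make_arm("trial-c", 2, 3, {1: 6, 2: 6}, E=108.0),
        ],
    )
    ds = NMADataset(
        studies=[s1, s2, s3],
        n_treatments=3,
        n_outcomes=2,
        mortality_outcome=2,
    )
    ds.validate()
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
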