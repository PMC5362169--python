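import numpy as np
import pytest

from sledamage.cohort_io import CohortTable, PatientSeries, VisitRecord
from sledamage.cohort_select import LabeledSequence, ModelDataset
from sledamage.synthetic_cohort import SyntheticConfig, generate_cohort


def make_visit(pid, month, sdi=0, activity=0, flags=None, sex="F", age=40.0,
               codebook=("flag_a", "flag_b")):
    ff = {name: 0 for name in codebook}
    if flags:
        ff.update(flags)
    return VisitRecord(
        patient_id=pid, month_index=month, age_years=age + month / 12.0,
        sex=sex, feature_flags=ff, activity_flag=activity, sdi_score=sdi,
    )


def make_series(pid, months, sdis, codebook=("flag_a", "flag_b"), **kw):
    return PatientSeries(
        patient_id=pid,
        visits=[make_visit(pid, m, sdi=s, codebook=codebook, **kw)
                for m, s in zip(months, sdis)],
    )


@pytest.fixture
def tiny_cohort():
    """Two clean patients: a case-to-be (3 visits, damage at the 4th) and a control."""
    codebook = ["flag_a", "flag_b"]
    p1 = make_series("A", [0, 3, 6, 9], [0, 0, 0, 1])
    p2 = make_series("B", [0, 4, 8], [0, 0, 0])
    return CohortTable(patients=[p1, p2], codebook=codebook)


@pytest.fixture
def small_config():
    """A fast generator configuration for structural tests."""
    return SyntheticConfig(
        n_patients=60,
        followup_max_months=60.0,
        seed=7,
    )


@pytest.fixture
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def separable_dataset():
    """Toy sequences whose first feature equals the label at every visit."""
    rng = np.random.default_rng(5)
    seqs = []
    for i in range(24):
        label = i % 2
        T = int(rng.integers(2, 6))
        X = rng.normal(0, 0.3, size=(T, 3))
        X[:, 0] = label
        seqs.append(LabeledSequence(f"P{i}", X, label))
    return ModelDataset(seqs, ["signal", "noise1", "noise2"], {})
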