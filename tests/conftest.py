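import numpy as np
import pytest

from cocompare.datamodel import PairedObservation, PatientRecord, StudyDataset


def build_pairs(records):
    """records: iterable of (patient_id, timepoint, ci_test, ci_ref)."""
    return [PairedObservation(p, t, ct, cr) for p, t, ct, cr in records]


@pytest.fixture
def two_patient_dataset():
    """2 patients x 5 timepoints, complete, with biometrics."""
    patients = {
        "P1": PatientRecord("P1", 40.0, 160.0, 60.0),
        "P2": PatientRecord("P2", 50.0, 170.0, 70.0),
    }
    obs = []
    for pid, base in (("P1", 2.5), ("P2", 3.0)):
        for tp in range(1, 6):
            ref = base + 0.1 * tp
            obs.append(PairedObservation(pid, tp, ref + 0.05, ref))
    return StudyDataset(patients=patients, observations=obs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
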