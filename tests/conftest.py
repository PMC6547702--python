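import numpy as np
import pandas as pd
import pytest

from pwas.exposure import ExposureMatrix


@pytest.fixture
def toy_exposures():
    """Three patients, two drugs, hand-checkable bits.

    drug X: patient 1 case-only, patient 2 control-only, patient 3 both.
    drug Y: patient 1 control-only, patients 2-3 unexposed.
    """
    return ExposureMatrix(
        patients=np.array(["p1", "p2", "p3"]),
        drugs=np.array(["X", "Y"]),
        case_bits=np.array([[1, 0], [0, 0], [1, 0]], np.uint8),
        control_bits=np.array([[0, 1], [1, 0], [1, 0]], np.uint8),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def random_difference_matrix(rng, n_pairs=20, n_drugs=3,
                             probs=(0.3, 0.4, 0.3)):
    """Random informative difference matrix with entries in {-1, 0, 1}."""
    while True:
        d = rng.choice([-1.0, 0.0, 1.0], size=(n_pairs, n_drugs), p=probs)
        d = d[(d != 0).any(axis=1)]
        if d.shape[0] >= 2 and (d != 0).any(axis=0).all():
            return d


def registry_from_offsets(offsets_by_patient, index_date=100,
                          drug="A01AA01"):
    """Build one-drug dispensing/event tables from per-patient day offsets."""
    rows = []
    ev = []
    for pid, offsets in offsets_by_patient.items():
        for off in offsets:
            rows.append((pid, drug, index_date - off))
        ev.append((pid, index_date, "hospital", 70, "male"))
    dispensings = pd.DataFrame(rows, columns=["patient_id", "drug_code",
                                              "dispense_date"])
    events = pd.DataFrame(ev, columns=["patient_id", "index_date", "source",
                                       "age_years", "sex"])
    return dispensings, events
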