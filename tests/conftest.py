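import numpy as np
import pandas as pd
import pytest

from akrisk.renal import LabSeries


@pytest.fixture
def flat_series():
    """Two years of flat creatinine at 100 µmol/L, monthly tests."""
    days = np.arange(0, 731, 30)
    return LabSeries("p1", days, np.full(len(days), 100.0))


def make_series(points, pid="p"):
    days, scr = zip(*points)
    return LabSeries(pid, np.array(days), np.array(scr, dtype=float))


@pytest.fixture
def tiny_landmark_frame():
    """Minimal hand-built patients/labs/events tables around the day-730
    landmark."""
    patients = pd.DataFrame({
        "patient_id": [1, 2, 3, 4],
        "age_years": [65.0, 70.0, 55.0, 80.0],
        "sex": [1, 0, 1, 0],
        "acr_mg_g": [150.0, np.nan, 20.0, 400.0],
        "diagnosis": ["vascular_htn", "diabetes", "uncertain", "vascular_htn"],
        "diabetes": [1, 1, 0, 0],
        "sbp": [140, 150, 130, 160],
        "dbp": [80, 85, 75, 90],
    })
    rows = []
    for pid in patients["patient_id"]:
        for day in range(0, 731, 60):
            rows.append({"patient_id": pid, "day": day, "scr_umol_l": 110.0})
    labs = pd.DataFrame(rows)
    events = pd.DataFrame({
        "patient_id": [2, 4],
        "rrt_day": [np.nan, 800],
        "death_day": [300, np.nan],   # patient 2 dies pre-landmark
    })
    return patients, labs, events
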