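import numpy as np
import pandas as pd
import pytest

from cortiflow import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-rate cohort with every violation type planted."""
    return simulate_cohort(SimConfig(n_subjects=120, seed=11))


@pytest.fixture()
def hand_table():
    """Three subjects, hand-chosen log concentrations (one full day each)."""
    rows = []
    profiles = {
        "A": [1.49, 1.31, 1.31, 0.70, 0.62, 0.42, 0.40],  # declining CAR
        "B": [1.20, 1.45, 1.55, 0.80, 0.60, 0.45, 0.30],  # rising CAR
        "C": [1.30, 1.30, 1.30, 0.90, 0.70, 0.50, 0.35],  # flat morning
    }
    occ = ["S1", "S2", "S3", "S4", "S5", "S6", "S7"]
    awake = 7.0
    clock = [7.0, 7.25, 7.5, 10.5, 12.0, 17.0, 23.0]
    for sid, vals in profiles.items():
        for o, c, v in zip(occ, clock, vals):
            rows.append(
                dict(
                    subject_id=sid, stage="early", occasion=o, log_conc=v,
                    value=float(np.expm1(v)), time=c - awake, clock_time=c,
                    awakening_time=awake, date="2016-05-01", season="summer",
                    plate_id=0, bmi=24.0, age=33.0, hypertensive=0, gdm=0,
                    smoking=0, parity_primiparous=1, education="upper tertiary",
                    chromosomal_testing=0, mental_disorder=0,
                )
            )
    return pd.DataFrame(rows)
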