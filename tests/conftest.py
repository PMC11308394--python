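import datetime as dt

import numpy as np
import pandas as pd
import pytest

from surgelag.io_formats import PatientRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(
    country="country_1",
    admission="2021-03-10",
    sa=None,
    age=15,
    sex="female",
    method="self_poisoning",
    family_history="no",
    previous_er_visit="no",
    patient_id=None,
):
    return PatientRecord(
        country=country,
        admission_date=dt.date.fromisoformat(admission),
        sa_date=dt.date.fromisoformat(sa) if sa else None,
        age=age,
        sex=sex,
        method=method,
        family_history=family_history,
        previous_er_visit=previous_er_visit,
        patient_id=patient_id,
    )


@pytest.fixture
def sex_period_grouped():
    """Grouped binomial sex-by-period counts for five countries.

    One row per (country, sex level); ``y`` counts second-period
    episodes, ``n`` the total episodes at that level.
    """
    df = pd.DataFrame(
        {
            "country": np.repeat(["HR", "FR", "IT", "PT", "ES"], 2),
            "sex": [0.0, 1.0] * 5,
            "y": [15, 155, 35, 185, 23, 176, 16, 134, 32, 341],
            "n_first": [62, 139, 64, 254, 31, 153, 37, 265, 92, 447],
        }
    )
    df["n"] = df["y"] + df["n_first"]
    return df.drop(columns=["n_first"])
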