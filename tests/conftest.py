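import pandas as pd
import pytest

from reopcause.codesets import default_config, default_pattern_pool
from reopcause.synth import SyntheticConfig, generate


@pytest.fixture(scope="session")
def codesets():
    return default_config()


@pytest.fixture(scope="session")
def pattern_pool():
    return default_pattern_pool()


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Small perfectly coded cohort: every true cause carries its correct codes."""
    return generate(SyntheticConfig.zero_noise(600, seed=11))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default study conditions (realistic coding errors and noise contacts)."""
    return generate(SyntheticConfig.default(800, seed=29))


def make_surgery(
    fracture_id="FX1",
    patient_id="P1",
    surgery_date="2016-03-01",
    procedure="KNGJ49",
    region="G",
    laterality="right",
):
    return {
        "fracture_id": fracture_id,
        "patient_id": patient_id,
        "surgery_date": pd.Timestamp(surgery_date),
        "procedure": procedure,
        "region": region,
        "laterality": laterality,
    }


def make_events(rows):
    """rows: (patient_id, date, code, laterality, contact_id)"""
    frame = pd.DataFrame(
        rows, columns=["patient_id", "date", "code", "laterality", "contact_id"]
    )
    frame["date"] = pd.to_datetime(frame["date"])
    frame["kind"] = [
        "procedure" if c.startswith("K") else "diagnosis" for c in frame["code"]
    ]
    return frame
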