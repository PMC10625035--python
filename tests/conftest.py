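import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import pedipace as pp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_params() -> pp.CostParameters:
    return pp.reference_parameters()


@pytest.fixture(scope="session")
def small_events() -> pd.DataFrame:
    """A modest synthetic cohort shared across read-only tests."""
    cfg = pp.GeneratorConfig(n_patients=300, horizon=20, seed=42)
    return pp.generate_dataset(cfg)


def make_patient(pid, chs_delay_days=10, implant_age=1.0, icd=False,
                 last_day=2000, extra=()):
    """Hand-build one patient's event rows for cohort-filter tests."""
    rows = [
        dict(patient_id=pid, event="chs",
             age_at_event=implant_age - chs_delay_days / 365.25,
             days_since_implant=-int(chs_delay_days), los=0.0,
             direct_charge=0.0, indirect_cost=0.0),
        dict(patient_id=pid, event="ppm_implant", age_at_event=implant_age,
             days_since_implant=0, los=13.0, direct_charge=100_000.0,
             indirect_cost=7000.0),
    ]
    if icd:
        rows.append(dict(patient_id=pid, event="icd_implant",
                         age_at_event=implant_age + 1, days_since_implant=365,
                         los=5.0, direct_charge=0.0, indirect_cost=0.0))
    rows.append(dict(patient_id=pid, event="device_check",
                     age_at_event=implant_age + last_day / 365.25,
                     days_since_implant=int(last_day), los=0.125,
                     direct_charge=463.0, indirect_cost=136.0))
    for r in extra:
        rows.append(dict(patient_id=pid, **r))
    return rows


@pytest.fixture
def events_from_rows():
    def build(*row_lists):
        rows = [r for rl in row_lists for r in rl]
        return pd.DataFrame(rows)[pp.synthetic.EVENT_COLUMNS]
    return build
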