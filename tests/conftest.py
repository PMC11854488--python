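import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hcgrowth import charts, synth

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth_pair():
    """Seeded sex-specific truth curves (nu=1, tau=2: the LMS/normal case)."""
    return {s: synth.make_truth_curves(s, seed=1) for s in ("male", "female")}


@pytest.fixture(scope="session")
def reference(truth_pair):
    """Reference chart tabulated from the truth curves every 10 days."""
    return charts.reference_from_truth(truth_pair, np.arange(0.0, 1801.0, 10.0))


@pytest.fixture(scope="session")
def cohort_df(truth_pair):
    """Mid-sized clean cohort with age_days attached (no artifacts)."""
    cfg = synth.CohortConfig(n_children=2500, seed=42)
    df = synth.records_to_frame(synth.simulate_cohort(truth_pair, cfg))
    return with_age(df)


def with_age(df: pd.DataFrame) -> pd.DataFrame:
    age = (
        pd.to_datetime(df["measurement_date"]) - pd.to_datetime(df["birth_date"])
    ).dt.days
    return df.assign(age_days=age)


@pytest.fixture(scope="session")
def flat_curves():
    """Age-constant truth curves: mu=40 cm, sigma=0.05, nu=1, tau=2."""
    return synth.TruthCurves(sex="male", m0=40.0, m1=0.0, m2=30.0, s0=0.05, s1=0.0)
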