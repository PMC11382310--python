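import numpy as np
import pandas as pd
import pytest

from ril_mediation import default_paper_params, simulate_cohort
from ril_mediation.cohort_io import Cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort at the documented default calibration."""
    return simulate_cohort(default_paper_params(n=1500, seed=42))


@pytest.fixture(scope="session")
def matched_setup(default_cohort):
    """Propensity model + optimal matches on the default cohort."""
    from ril_mediation import fit_ps_model, optimal_match

    ps = fit_ps_model(
        default_cohort,
        ["age", "baseline_alc", "ptv", "ecog", "location", "stage",
         "chemo_cycles", "surgery"],
    )
    matches = optimal_match(ps, default_cohort)
    return ps, matches


def make_cohort(df: pd.DataFrame, **kw) -> Cohort:
    """Wrap a hand-built frame, filling unspecified columns with valid
    constants."""
    defaults = {
        "age": 63.0, "sex": "male", "baseline_alc": 1.6, "ptv": 600.0,
        "ecog": "0", "location": "lower", "stage": "III", "chemo_cycles": 5,
        "barretts": 0, "histology": "adeno", "surgery": 1, "modality": 0,
        "g4ril": 0, "os_months": 12.0, "event": 1,
    }
    df = df.copy()
    if "id" not in df.columns:
        df.insert(0, "id", [f"X{i}" for i in range(len(df))])
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    from ril_mediation.cohort_io import COLUMNS

    return Cohort(df=df[COLUMNS].reset_index(drop=True), **kw)
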