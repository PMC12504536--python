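import numpy as np
import pandas as pd
import pytest

from paequiv import apply_exclusions, generate_cohort, loglinear_scenario


@pytest.fixture(scope="session")
def loglinear_cohort():
    """n=5000 cohort under the log-linear validation truth (ratio 4)."""
    truth = loglinear_scenario(seed=42)
    return generate_cohort(truth, 5000)


@pytest.fixture(scope="session")
def loglinear_prepared(loglinear_cohort):
    kept, _ = apply_exclusions(loglinear_cohort)
    return kept


@pytest.fixture()
def toy_cohort():
    """Hand-built 10-subject table: 2 prevalent, 1 early analytic event,
    1 early competing event.  Columns are jittered so no pair is collinear."""
    rng = np.random.default_rng(99)
    return pd.DataFrame(
        {
            "id": np.arange(1, 11),
            "lpa_min": np.linspace(40, 130, 10) + rng.random(10),
            "mpa_min": np.linspace(5, 50, 10) + rng.random(10),
            "vpa_min": np.linspace(0.5, 10, 10) + rng.random(10),
            "age": np.linspace(45, 72, 10) + rng.random(10),
            "sex": [0, 1] * 5,
            "lifestyle": rng.normal(size=10),
            "follow_time": [0.5, 2.0, 3.0, 4.0, 5.0, 6.0, 0.5, 7.0, 8.0, 9.0],
            "event_code": [1, 1, 0, 0, 1, 2, 2, 0, 0, 1],
            "prevalent_flag": [False, True, True, False, False, False, False, False, False, False],
            "entry_offset": np.zeros(10),
        }
    )
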