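import numpy as np
import pandas as pd
import pytest

import tmlebench as tb


@pytest.fixture(scope="session")
def default_cfg():
    return tb.DgpConfig()


@pytest.fixture(scope="session")
def cohort_5k():
    """One complete benchmark cohort, n=5000."""
    return tb.generate_cohort(tb.DgpConfig(n=5000, seed=314))


@pytest.fixture(scope="session")
def cohort_5k_mnar20(cohort_5k):
    """Same cohort after 20% MNAR outcome amputation."""
    return tb.ampute(cohort_5k,
                     tb.MissingnessSpec(target_rate=0.20, seed=314))


def toy_frame(a, b, c, d):
    """2x2 cohort: a treated events, b treated non-events, c control
    events, d control non-events."""
    z = [1] * (a + b) + [0] * (c + d)
    y = [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d
    return pd.DataFrame({"z": z, "y": y, "delta": 1})
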