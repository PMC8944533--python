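import numpy as np
import pandas as pd
import pytest

from parlourscore import simulate_study
from parlourscore.simulate import INDICATORS


@pytest.fixture(scope="session")
def study_sim() -> pd.DataFrame:
    """One simulated two-farm study dataset (4125 cow-visits), shared."""
    return simulate_study(seed=7)


def make_frame(ls, sw=None, awd=None, shh=None, oh=None, farm="f1") -> pd.DataFrame:
    """Small matched-record frame from per-column sequences (defaults 0)."""
    ls = np.asarray(ls, dtype=int)
    n = len(ls)
    cols = {"sw": sw, "awd": awd, "shh": shh, "oh": oh}
    frame = pd.DataFrame(
        {
            "farm": farm,
            "month": 1,
            "cow_id": [f"c{i}" for i in range(n)],
            "ls": ls,
        }
    )
    for name in INDICATORS:
        v = cols[name]
        frame[name] = np.zeros(n, dtype=int) if v is None else np.asarray(v, dtype=int)
    return frame
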