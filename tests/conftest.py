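import numpy as np
import pandas as pd
import pytest

from erlangen import ReferencePanel, default_config, generate_cohort
from erlangen.datasets import load_reference_distribution, reconstruct_reference_cohort


@pytest.fixture(scope="session")
def refs() -> ReferencePanel:
    return ReferencePanel.default()


@pytest.fixture(scope="session")
def reference_table():
    """Published 4x3 distribution of score categories by diagnostic group."""
    return load_reference_distribution()


@pytest.fixture(scope="session")
def reference_cohort() -> pd.DataFrame:
    return reconstruct_reference_cohort()


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Study-sized synthetic cohort, fixed seed."""
    return generate_cohort(default_config(seed=42))


def surv_frame(time, event, **covs) -> pd.DataFrame:
    """Single-episode counting-process table from subject-level data."""
    time = np.asarray(time, dtype=float)
    frame = pd.DataFrame(dict(id=np.arange(time.size), start=0.0, stop=time,
                              event=np.asarray(event, dtype=int)))
    for name, val in covs.items():
        frame[name] = np.asarray(val, dtype=float)
    return frame
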