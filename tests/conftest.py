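import numpy as np
import pandas as pd
import pytest

from cardiogate import GenConfig, synthetic, pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-subject cohort, generated once per test session."""
    cfg = GenConfig(n_subjects=8, seed=11)
    return synthetic.gen_cohort(cfg)


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    return pipeline.score_dataset(small_cohort)


@pytest.fixture
def toy_session():
    """Hand-checkable session: 4 Go (3 pressed at 400/500/600), 2 NoGo
    (1 pressed at 450), 4 Choose (2 pressed at 500/700)."""
    rows = [
        ("go", "systole", 1, 400.0), ("go", "systole", 1, 500.0),
        ("go", "diastole", 1, 600.0), ("go", "diastole", 0, np.nan),
        ("nogo", "systole", 1, 450.0), ("nogo", "diastole", 0, np.nan),
        ("choose", "systole", 1, 500.0), ("choose", "systole", 0, np.nan),
        ("choose", "diastole", 1, 700.0), ("choose", "diastole", 0, np.nan),
    ]
    return pd.DataFrame(rows, columns=["trial_type", "intended_phase",
                                       "pressed", "rt_ms"])
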