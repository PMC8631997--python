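import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vwpa.preprocess import TimingConfig, make_windows
from vwpa.simulate import SyntheticConfig, generate_vwp_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def timing():
    return TimingConfig()


@pytest.fixture(scope="session")
def windows(timing):
    return make_windows(timing)


@pytest.fixture(scope="session")
def strong_effect_dataset():
    """Default strong constraining effect, one language (study-sized)."""
    cfg = SyntheticConfig(seed=202, languages=("norwegian",))
    return cfg, generate_vwp_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """Small dataset for pipeline/CLI smoke tests (6 participants)."""
    cfg = SyntheticConfig(seed=11, n_participants=6, languages=("norwegian",))
    return cfg, generate_vwp_dataset(cfg)


def as_strings(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a table for content comparison across write/read cycles."""
    out = df.copy()
    for col in out.columns:
        if isinstance(out[col].dtype, pd.CategoricalDtype):
            out[col] = out[col].astype(str)
    return out.reset_index(drop=True)


def assert_table_content_equal(a: pd.DataFrame, b: pd.DataFrame) -> None:
    a, b = as_strings(a), as_strings(b)
    assert list(a.columns) == list(b.columns)
    for col in a.columns:
        av, bv = a[col], b[col]
        if pd.api.types.is_numeric_dtype(av) or pd.api.types.is_numeric_dtype(bv):
            np.testing.assert_allclose(
                pd.to_numeric(av, errors="coerce"),
                pd.to_numeric(bv, errors="coerce"),
                rtol=0, atol=1e-12, equal_nan=True, err_msg=col)
        else:
            assert (av.fillna("") .astype(str) == bv.fillna("").astype(str)).all(), col
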