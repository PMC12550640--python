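import warnings

import numpy as np
import pandas as pd
import pytest

from fusionern.config import GeneratorConfig


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # small-n fits legitimately warn (n vs free parameters); keep test
    # output readable while still surfacing errors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250923)


@pytest.fixture
def one_factor_data(rng) -> pd.DataFrame:
    """Three indicators of one latent factor, 15% MCAR on two of them."""
    n = 400
    eta = rng.normal(0.0, 2.0, n)
    frame = pd.DataFrame({
        "x1": eta + rng.normal(0, 1, n) + 1.0,
        "x2": 0.8 * eta + rng.normal(0, 1, n) + 2.0,
        "x3": 1.2 * eta + rng.normal(0, 1, n) - 1.0,
    })
    frame.loc[rng.random(n) < 0.15, "x2"] = np.nan
    frame.loc[rng.random(n) < 0.15, "x3"] = np.nan
    return frame


def one_factor_spec(mean_structure: bool = True):
    from fusionern.sem import SEMSpec

    spec = SEMSpec()
    spec.add_observed("x1", "x2", "x3").add_latent("f")
    spec.loading("x1", "f", free=False, value=1.0)
    spec.loading("x2", "f")
    spec.loading("x3", "f")
    for obs in ("x1", "x2", "x3"):
        spec.variance(obs)
        spec.intercept(obs)
    spec.variance("f")
    spec.mean("f", free=False, value=0.0)
    return spec
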