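import dataclasses

import numpy as np
import pandas as pd
import pytest

import thermolag as tl


@pytest.fixture(scope="session")
def small_spec():
    """A reduced model keeping unit tests fast; structure mirrors the full one."""
    return tl.ModelSpec(var_df=3, lag_df=3, max_lag=14, time_df_per_year=4,
                        humidity_df=2, dewpoint_df=2)


@pytest.fixture(scope="session")
def sim_data():
    """Three years of J-surface synthetic data (fixed seed)."""
    config = dataclasses.replace(tl.SimConfig(), n_years=3.0)
    return tl.simulate_dataset(tl.TrueSurface(shape="J"), config, seed=42)


@pytest.fixture(scope="session")
def small_model(sim_data, small_spec):
    return tl.fit_model(sim_data, small_spec)


def zero_cb_model(model):
    """Copy of a fitted model with the cross-basis coefficients zeroed."""
    coef = model.coefficients.copy()
    coef.iloc[model.blocks["crossbasis"]] = 0.0
    return dataclasses.replace(model, coefficients=coef)
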