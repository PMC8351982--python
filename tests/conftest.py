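import numpy as np
import pytest

from coilcea import (
    HtiEfficacySpec,
    ModelConfig,
    ParameterDraw,
    default_parameter_table,
    run_psa,
)
from coilcea.parameters import MRS0_UTILITY_BANDS


@pytest.fixture(scope="session")
def specs():
    return default_parameter_table()


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def hti_uniform():
    return HtiEfficacySpec("uniform01")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240517)


def make_draw(rrr=0.5, overrides=None):
    """ParameterDraw at the published table means, selectively overridden."""
    values = {s.id: s.mean for s in default_parameter_table()}
    values[22] = -0.07
    values.update(overrides or {})
    offset = values[19] - 0.87
    bands = tuple(min(max(m + offset, 0.0), 1.0) for (_, _, m) in MRS0_UTILITY_BANDS)
    return ParameterDraw(values=values, rrr=rrr, mrs0_by_band=bands)


def make_inert_draw(utility=0.87, rrr=0.0):
    """Draw with every event probability zero: the cohort never leaves
    coiled(1, mRS0); used for closed-form annuity checks."""
    zero = {i: 0.0 for i in range(1, 12)}
    d = make_draw(rrr=rrr, overrides=zero)
    values = dict(d.values)
    values[19] = utility
    values[22] = 0.0
    return ParameterDraw(values=values, rrr=rrr,
                         mrs0_by_band=(utility,) * 4)


@pytest.fixture(scope="session")
def mean_draw():
    return make_draw()


@pytest.fixture(scope="session")
def base_psa(specs, config, hti_uniform):
    """A moderate base-case PSA shared by the analytics tests."""
    return run_psa(specs, hti_uniform, config, 2_000, seed=101)
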