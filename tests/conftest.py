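import numpy as np
import pytest

from pearlitr.config import LambdaConfig, NuisanceConfig, PearlConfig
from pearlitr.simulate import (
    ScenarioSpec,
    generate_scenario,
    oracle_outcome,
    oracle_propensity,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scenario1_small():
    """A small fully-linear scenario dataset with its generating spec."""
    spec = ScenarioSpec(scenario="I", n=200, p=6, xi=0.7, seed=7)
    return spec, generate_scenario(spec)


@pytest.fixture
def oracle_config():
    """Pipeline config with oracle nuisances and compact CV grids."""

    def make(spec, seed=0, **kwargs):
        nuis = NuisanceConfig(
            propensity_fn=oracle_propensity(spec), outcome_fns=oracle_outcome(spec)
        )
        lam = LambdaConfig(grid_size=8, cv_folds=3)
        defaults = dict(K=2, seed=seed, nuisance=nuis, lam=lam, lam_tilde=lam)
        defaults.update(kwargs)
        return PearlConfig(**defaults)

    return make
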