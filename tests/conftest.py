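"""Shared fixtures: micro-models and small synthetic cohorts."""

import numpy as np
import pytest

from nephrisk.nbc import NBCModel
from nephrisk.variables import VariableSpec


def make_binary_model(prior, cpts, horizon=24):
    """Model over binary variables from {name: (P(x=1|y0), P(x=1|y1))}."""
    specs = tuple(VariableSpec(name, "boolean") for name in cpts)
    arrays = {
        name: np.array([[1 - p0, p0], [1 - p1, p1]])
        for name, (p0, p1) in cpts.items()
    }
    return NBCModel(horizon_months=horizon, prior=prior, specs=specs, cpts=arrays)


@pytest.fixture
def micro_model():
    """One binary feature A: prior 0.2, P(A=1|Y=1)=0.8, P(A=1|Y=0)=0.3."""
    return make_binary_model(0.2, {"A": (0.3, 0.8)})


@pytest.fixture
def two_var_model():
    """Micro model plus a second, weaker feature B."""
    return make_binary_model(0.2, {"A": (0.3, 0.8), "B": (0.5, 0.6)})


@pytest.fixture(scope="session")
def registry_cohorts():
    """A small registry-like training/test cohort pair (session cache)."""
    from nephrisk.synth import registry_like_config, generate_cohort

    train = generate_cohort(registry_like_config(n=4000, seed=11), horizons=(6, 24))
    test = generate_cohort(registry_like_config(n=2000, seed=12), horizons=(6, 24))
    return train, test
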