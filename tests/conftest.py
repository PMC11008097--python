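import numpy as np
import pytest

from cqha.composite import Ingredients, assemble_composite
from cqha.synthetic import ModelCrystalSpec, make_model_crystal


@pytest.fixture(scope="session")
def default_crystal():
    """Default model crystal: 9% minimum offset, 50% curvature difference."""
    spec = ModelCrystalSpec()
    return spec, make_model_crystal(spec)


@pytest.fixture(scope="session")
def degenerate_crystal():
    """Low and high levels numerically identical (degeneracy checks)."""
    spec = ModelCrystalSpec(v0_low=920.0, b0_low=10.0)
    return spec, make_model_crystal(spec)


@pytest.fixture(scope="session")
def m1_model(default_crystal):
    _, c = default_crystal
    return assemble_composite(
        "M1", Ingredients(ev=c.ev_low, phonons=c.phonons_low), Ingredients()
    )


@pytest.fixture(scope="session")
def m1_table(m1_model):
    from cqha.thermo import composite_thermo

    return composite_thermo(m1_model, np.arange(0.0, 401.0, 5.0))
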