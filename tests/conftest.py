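import numpy as np
import pytest

from ntosim.model import (
    DesignSpec,
    FamilySpec,
    Normal,
    ScenarioConfig,
    VarietySpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def worked_example_config():
    """RCB scenario with a GM plant, comparator and three reference varieties
    drawn from normal populations, zero-inflated Poisson counts."""
    return ScenarioConfig(
        family=FamilySpec("poisson"),
        varieties=(
            VarietySpec("gm", "gm", 0.4, -0.3),
            VarietySpec("comparator", "comparator", 0.5, -0.2),
            VarietySpec(
                "ref", "reference_population", Normal(1.0, 1.0), Normal(-0.8, 0.5),
                n_reference=3,
            ),
        ),
        design=DesignSpec("rcb", 2, 0.1, 0.01),
    )


@pytest.fixture
def simple_crd():
    """Poisson CRD with three varieties, no random effects."""
    return ScenarioConfig(
        family=FamilySpec("poisson"),
        varieties=(
            VarietySpec("gm", "gm", float(np.log(8.0))),
            VarietySpec("comparator", "comparator", float(np.log(4.0))),
            VarietySpec("additional1", "additional", float(np.log(4.0))),
        ),
        design=DesignSpec("crd", 20),
    )
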