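import numpy as np
import pytest

from polyqsim.core import ModelDef, ReactionDef, SpeciesDef


@pytest.fixture
def two_species_model() -> ModelDef:
    """Minimal well-formed model: A -> B plus a constant source of A."""
    return ModelDef(
        species=[SpeciesDef("A", 10, "protein"), SpeciesDef("B", 0, "protein")],
        reactions=[
            ReactionDef("src", (), (("A", 1),), "k_src"),
            ReactionDef("conv", (("A", 1),), (("B", 1),), "k_conv"),
        ],
        parameters={"k_src": 1.0, "k_conv": 0.5},
        name="two_species",
    )


@pytest.fixture
def grid_48h() -> np.ndarray:
    return np.arange(1, 97) * 0.5
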