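import numpy as np
import pytest

from mapr import AttributeSystem, ValueFunction, load_system

# EQ-5D-like decrements: moderate problems cost 0.15-0.30, severe 0.60-1.00
GAMMA_53 = {
    "mobility:2": -0.25,
    "mobility:3": -0.90,
    "self_care:2": -0.20,
    "self_care:3": -0.75,
    "usual_activities:2": -0.15,
    "usual_activities:3": -0.60,
    "pain_discomfort:2": -0.30,
    "pain_discomfort:3": -1.00,
    "anxiety_depression:2": -0.20,
    "anxiety_depression:3": -0.80,
}

# fixed presented set whose design vectors span all 10 columns
SPANNING_STATES = [
    "21111", "31111", "12111", "13111", "11211", "11311",
    "11121", "11131", "11112", "11113", "22222", "33333",
]


@pytest.fixture(scope="session")
def system53() -> AttributeSystem:
    return load_system("eq5d3l")


@pytest.fixture(scope="session")
def vf53(system53) -> ValueFunction:
    return ValueFunction.from_mapping(system53, GAMMA_53)


@pytest.fixture(scope="session")
def gamma53(vf53) -> np.ndarray:
    return vf53.gamma


@pytest.fixture(scope="session")
def saturated_system() -> AttributeSystem:
    """One attribute with 8 levels: the dummy coding is saturated, one
    free parameter per non-best state."""
    return AttributeSystem(
        attributes=("severity",),
        levels=(tuple(f"level {k}" for k in range(1, 9)),),
    )
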