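import numpy as np
import pytest

from vlucea import ParameterBundle, Segment, TransitionSchedule, load_config
from vlucea.params import bundle_from_dict, bundle_to_dict


@pytest.fixture(scope="session")
def bundle() -> ParameterBundle:
    """The shipped base-case parameter bundle."""
    return load_config()


@pytest.fixture()
def raw_config(bundle) -> dict:
    """Mutable mapping form of the base case, for building perturbed
    bundles."""
    return bundle_to_dict(bundle)


@pytest.fixture()
def rebuild():
    return bundle_from_dict


def flat_schedule(
    arm: str = "early",
    heal: float = 0.1,
    recur: float = 0.01,
    mortality: float = 0.001,
) -> TransitionSchedule:
    """Single-segment schedule with constant probabilities, for closed-form
    checks."""
    return TransitionSchedule(
        arm=arm,
        heal_segments=(Segment(1, None, heal),),
        recur_segments=(Segment(1, None, recur),),
        mortality=mortality,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
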