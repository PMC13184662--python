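import numpy as np
import pytest

from coordsig import (
    PreferenceType,
    ScenarioConfig,
    SignalSpace,
    StrategyProfile,
    preset,
)


@pytest.fixture
def space_2d():
    """Two dimensions, one real signal each: four signal vectors/combinations."""
    return SignalSpace((1, 1))


@pytest.fixture
def space_1d():
    """One dimension with two real signals plus null."""
    return SignalSpace((2,))


@pytest.fixture
def two_type_nosignal():
    """Two-type baseline game with the signal space switched off."""
    return preset("two-type-base", {"signal_alphabet": [], "V": 2.0, "d": 0.5})


@pytest.fixture
def tiny_cfg(space_1d):
    """Minimal hand-built two-type scenario over one signalling dimension."""
    types = [
        PreferenceType(0, "Ummian", (2.0, 1.0), 0.5),
        PreferenceType(1, "Kishu", (1.0, 2.0), 0.5),
    ]
    return ScenarioConfig(
        types=types,
        action_labels=("umma", "kish"),
        space=space_1d,
        N=100,
        mu1=0.05,
        mu2=0.05,
        steps=500,
        seed=7,
    ).validate()


def profile(space, signal, actions):
    return StrategyProfile(space, tuple(signal), tuple(actions))


@pytest.fixture
def make_profile():
    return profile
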