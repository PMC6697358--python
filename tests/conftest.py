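"""Shared fixtures: attractor traces are expensive (tens of seconds of model
time each), so they are computed once per session and reused."""

import pytest

from respcpg import find_attractor, preset


@pytest.fixture(scope="session")
def oscillatory_trace():
    return find_attractor(preset("oscillatory"))


@pytest.fixture(scope="session")
def tonic_trace():
    return find_attractor(preset("tonic"))


@pytest.fixture(scope="session")
def pico_trace():
    return find_attractor(preset("baseline5_pico"))
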