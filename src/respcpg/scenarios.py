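"""Named model presets and seeded initial conditions.

The baseline parameter set fully specifies the model; presets bundle it with
the standard tunings used throughout the analyses: the intrinsically
oscillatory (c11 = -0.03) and intrinsically tonic (c11 = 0.01) pre-I
settings, weak/strong post-I-to-pre-I inhibition variants, and the 5-unit
network including PiCo.  Every non-default value carries a provenance note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .model_core import NetworkConfig, SharedParams, StateVector, UnitParams

# Baseline unit parameters.  pre-I and PiCo are excitatory and share
# conductances; early-I, post-I and aug-E are inhibitory adapting units.
_PRE_I = UnitParams(
    name="pre-I", excitatory=True,
    g_NaP=4.5, g_K=1.0, g_L=3.0, E_L=-65.0,
    theta_out=-32.0, sigma_out=-8.0,
)
_PICO = UnitParams(
    name="PiCo", excitatory=True,
    g_NaP=4.5, g_K=1.0, g_L=3.0, E_L=-65.0,
    theta_out=-20.0, sigma_out=-12.0,
)


def _inh_unit(name: str, tau_p: float) -> UnitParams:
    return UnitParams(
        name=name, excitatory=False,
        g_NaP=0.25, g_K=10.0, g_L=3.25, E_L=-60.0,
        theta_out=-30.0, sigma_out=-4.0,
        tau_p=tau_p, d_adapt=1.0,
    )


_EARLY_I = _inh_unit("early-I", 2000.0)
_POST_I = _inh_unit("post-I", 1500.0)
_AUG_E = _inh_unit("aug-E", 2000.0)

# Synaptic weights a_ji / b_ji (presynaptic j -> postsynaptic i) and tonic
# drives for the 4-unit network.
_A4 = {(1, 2): 0.6}
_B4 = {
    (3, 1): 0.125, (4, 1): 0.015,
    (3, 2): 0.27, (4, 2): 0.3,
    (2, 3): 0.6, (4, 3): 0.05,
    (2, 4): 0.3, (3, 4): 0.45,
}
_C1_4 = {1: -0.03, 2: 0.19, 3: 0.58, 4: 0.2}
_C2_4 = {1: 0.095, 2: 0.3, 3: 0.0, 4: 0.4}

# PiCo additions: excited by pre-I, inhibited by early-I and aug-E, exciting
# post-I; b43 drops from 0.05 to 0.02 when PiCo is included.
_A5 = {**_A4, (5, 3): 0.1, (1, 5): 0.2}
_B5 = {**_B4, (4, 3): 0.02, (2, 5): 0.2, (4, 5): 0.3}
_C1_5 = {**_C1_4, 5: 0.045}
_C2_5 = {**_C2_4, 5: 0.0}


@dataclass(frozen=True)
class Preset:
    name: str
    config: NetworkConfig
    description: str
    provenance: str


def _baseline4() -> NetworkConfig:
    return NetworkConfig(
        units=(_PRE_I, _EARLY_I, _POST_I, _AUG_E),
        shared=SharedParams(),
        a=dict(_A4), b=dict(_B4), c1=dict(_C1_4), c2=dict(_C2_4),
        include_pico=False,
    )


def _baseline5() -> NetworkConfig:
    return NetworkConfig(
        units=(_PRE_I, _EARLY_I, _POST_I, _AUG_E, _PICO),
        shared=SharedParams(),
        a=dict(_A5), b=dict(_B5), c1=dict(_C1_5), c2=dict(_C2_5),
        include_pico=True,
    )


def _presets() -> Dict[str, Preset]:
    base = _baseline4()
    return {
        "baseline4": Preset(
            "baseline4", base,
            "4-unit network (pre-I, early-I, post-I, aug-E), oscillatory "
            "pre-I tuning c11 = -0.03",
            "baseline parameter lists; c11 = -0.03 standard tuning",
        ),
        "baseline5_pico": Preset(
            "baseline5_pico", _baseline5(),
            "5-unit network including PiCo (a53 = 0.1, b43 = 0.02, "
            "c15 = 0.045)",
            "baseline lists with PiCo additions",
        ),
        "oscillatory": Preset(
            "oscillatory", base.with_c1(1, -0.03),
            "4-unit network, intrinsically oscillatory pre-I (c11 = -0.03)",
            "oscillatory tuning c11 = -0.03",
        ),
        "tonic": Preset(
            "tonic", base.with_c1(1, 0.01),
            "4-unit network, intrinsically tonic pre-I (c11 = 0.01)",
            "tonic tuning c11 = 0.01",
        ),
        "strong_b31": Preset(
            "strong_b31", base.with_weight("b", 3, 1, 0.175),
            "oscillatory tuning with increased post-I -> pre-I inhibition",
            "b31 = 0.175 variant",
        ),
        "weak_b31": Preset(
            "weak_b31", base.with_weight("b", 3, 1, 0.105),
            "oscillatory tuning with reduced post-I -> pre-I inhibition",
            "b31 = 0.105 variant",
        ),
    }


def preset_names() -> list:
    return sorted(_presets())


def preset_info(name: str) -> Preset:
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    return presets[name]


def preset(name: str) -> NetworkConfig:
    """Fully populated NetworkConfig for a named preset."""
    return preset_info(name).config


# Default and randomized initial conditions.  The default starts the network
# in a post-I-active configuration.
_IC_BOUNDS = {"V": (-70.0, -20.0), "h": (0.2, 0.9), "p": (0.0, 0.5)}


def default_initial_state(config: NetworkConfig) -> StateVector:
    V = np.full(config.n, -60.0)
    if config.n >= 3:
        V[2] = -30.0  # post-I starts active
    h = np.full(config.n, 0.6)
    p = np.full(config.n, 0.1)
    return StateVector(V, h, p)


def random_initial_state(config: NetworkConfig, seed: int) -> StateVector:
    """Uniform draws within documented bounds; same seed, same state."""
    rng = np.random.default_rng(seed)
    n = config.n
    V = rng.uniform(*_IC_BOUNDS["V"], size=n)
    h = rng.uniform(*_IC_BOUNDS["h"], size=n)
    p = rng.uniform(*_IC_BOUNDS["p"], size=n)
    return StateVector(V, h, p)
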