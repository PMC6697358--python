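"""Model-core tests: gating functions, currents, a duplicate-implementation
right-hand-side oracle, nullcline closed forms, and config round-trips."""

import math
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respcpg import (
    NetworkConfig,
    SharedParams,
    StateVector,
    UnitParams,
    preset,
    preset_names,
)
from respcpg.model_core import (
    CompiledNetwork,
    config_from_text,
    config_to_text,
    f_out,
    h_inf,
    isolated_unit_config,
    load_config,
    m_inf,
    n_inf,
    rhs,
    save_config,
    synaptic_inputs,
    tau_h,
    v_nullcline_dh_dV,
    v_nullcline_h,
)

SH = SharedParams()


# ------------------------------------------------------------------ gating --
def test_gating_midpoints_and_limits():
    assert h_inf(SH.theta_h, SH) == pytest.approx(0.5)
    assert m_inf(SH.theta_m, SH) == pytest.approx(0.5)
    assert n_inf(SH.theta_n, SH) == pytest.approx(0.5)
    assert tau_h(SH.theta_h, SH) == pytest.approx(SH.epsilon)
    # h_inf falls with V, m_inf and n_inf rise with V
    assert h_inf(-80.0, SH) > h_inf(-20.0, SH)
    assert m_inf(-80.0, SH) < m_inf(-20.0, SH)
    assert n_inf(-80.0, SH) < n_inf(-20.0, SH)
    assert 0.0 < h_inf(-60.0, SH) < 1.0


def test_f_out_midpoint_and_monotone():
    u = preset("baseline4").unit(1)
    assert f_out(u, u.theta_out) == pytest.approx(0.5)
    V = np.linspace(-80, 0, 50)
    assert np.all(np.diff(f_out(u, V)) > 0)


def test_explicit_gating_values():
    # hand-computed from the sigmoid definition
    assert h_inf(-40.0, SH) == pytest.approx(1.0 / (1.0 + math.exp(1.0)))
    assert tau_h(-40.0, SH) == pytest.approx(4000.0 / math.cosh(0.5))


# ------------------------------------------------------- duplicate-rhs oracle
def _reference_rhs(config: NetworkConfig, state: StateVector) -> StateVector:
    """Independent scalar reimplementation of the model equations."""
    sh = config.shared
    n = config.n

    def sig(x):
        return 1.0 / (1.0 + math.exp(-x))

    fo = []
    for k, u in enumerate(config.units):
        fo.append(sig(-(state.V[k] - u.theta_out) / u.sigma_out))

    dV = np.zeros(n)
    dh = np.zeros(n)
    dp = np.zeros(n)
    for k, u in enumerate(config.units):
        i = k + 1
        V = state.V[k]
        h = state.h[k]
        hinf = sig(-(V - sh.theta_h) / sh.sigma_h)
        if not u.has_dynamic_h:
            h = hinf
        inh = config.frozen_inh.get(i, 0.0)
        exc = config.c1.get(i, 0.0) + config.c2.get(i, 0.0)
        for (j, ii), w in config.b.items():
            if ii == i and not config.unit(j).excitatory:
                inh += w * fo[j - 1]
        for (j, ii), w in config.a.items():
            if ii == i and config.unit(j).excitatory:
                exc += w * fo[j - 1]
        m = sig(-(V - sh.theta_m) / sh.sigma_m)
        I_NaP = u.g_NaP * m * h * (V - sh.E_Na)
        if u.excitatory:
            nn = sig(-(V - sh.theta_n) / sh.sigma_n)
            I_K = u.g_K * nn ** 4 * (V - sh.E_K)
        else:
            I_K = u.g_K * state.p[k] * (V - sh.E_K)
        I_L = u.g_L * (V - u.E_L)
        I_synI = sh.g_synI * (V - sh.E_synI) * inh
        I_synE = sh.g_synE * (V - sh.E_synE) * exc
        dV[k] = -(I_NaP + I_K + I_L + I_synI + I_synE) / sh.C
        if u.has_dynamic_h:
            tau = sh.epsilon / math.cosh((V - sh.theta_h) / (2 * sh.sigma_h))
            dh[k] = (hinf - state.h[k]) / tau
        if not u.excitatory:
            dp[k] = (u.d_adapt * fo[k] - state.p[k]) / u.tau_p
    return StateVector(dV, dh, dp)


@pytest.mark.parametrize("preset_name", ["baseline4", "baseline5_pico"])
def test_rhs_matches_reference_implementation(preset_name):
    config = preset(preset_name)
    rng = np.random.default_rng(42)
    for _ in range(100):
        state = StateVector(
            V=rng.uniform(-80, 0, config.n),
            h=rng.uniform(0, 1, config.n),
            p=rng.uniform(0, 1, config.n),
        )
        got = rhs(config, state)
        want = _reference_rhs(config, state)
        for a, b in ((got.V, want.V), (got.h, want.h), (got.p, want.p)):
            np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-15)


def test_rhs_matches_reference_dynamic_h():
    config = preset("baseline4").with_unit_param(3, h_mode="dynamic")
    rng = np.random.default_rng(7)
    for _ in range(25):
        state = StateVector(
            V=rng.uniform(-80, 0, 4), h=rng.uniform(0, 1, 4),
            p=rng.uniform(0, 1, 4),
        )
        got = rhs(config, state)
        want = _reference_rhs(config, state)
        np.testing.assert_allclose(got.V, want.V, rtol=1e-12)
        np.testing.assert_allclose(got.h, want.h, rtol=1e-12, atol=1e-15)


@settings(max_examples=30, deadline=None)
@given(
    V=st.lists(st.floats(-90, 10), min_size=4, max_size=4),
    h=st.lists(st.floats(0, 1), min_size=4, max_size=4),
    p=st.lists(st.floats(0, 1), min_size=4, max_size=4),
)
def test_rhs_oracle_property(V, h, p):
    config = preset("baseline4")
    state = StateVector(np.array(V), np.array(h), np.array(p))
    got = rhs(config, state)
    want = _reference_rhs(config, state)
    np.testing.assert_allclose(got.V, want.V, rtol=1e-12, atol=1e-15)


def test_synaptic_inputs_definition(oscillatory_trace):
    """Total inhibition is the dimensionless weighted output sum."""
    tr = oscillatory_trace
    cfg = tr.config
    k = np.argmax(tr.inh_sum[0])
    state = StateVector(tr.V[:, k], tr.h[:, k], tr.p[:, k])
    inh, exc, I_synI, I_synE = synaptic_inputs(cfg, state, 1)
    b = cfg.b
    want = (b[(3, 1)] * f_out(cfg.unit(3), tr.V[2, k])
            + b[(4, 1)] * f_out(cfg.unit(4), tr.V[3, k]))
    assert inh == pytest.approx(want, rel=1e-12)
    sh = cfg.shared
    assert I_synI == pytest.approx(
        sh.g_synI * (tr.V[0, k] - sh.E_synI) * inh, rel=1e-12)


# --------------------------------------------------------------- nullclines --
def test_v_nullcline_zeroes_dV():
    u = preset("baseline4").unit(1)
    V = np.linspace(-70, -20, 21)
    h = v_nullcline_h(u, SH, 0.065, 0.02, V)
    cfg = isolated_unit_config(u, SH, 0.065, 0.02)
    for Vk, hk in zip(V, h):
        d = rhs(cfg, StateVector(np.array([Vk]), np.array([hk]),
                                 np.zeros(1)))
        assert abs(d.V[0]) < 1e-9


def test_v_nullcline_derivative_matches_finite_difference():
    u = preset("baseline4").unit(1)
    V = np.linspace(-65, -30, 15)
    eps = 1e-6
    analytic = v_nullcline_dh_dV(u, SH, 0.065, 0.0, V)
    fd = (v_nullcline_h(u, SH, 0.065, 0.0, V + eps)
          - v_nullcline_h(u, SH, 0.065, 0.0, V - eps)) / (2 * eps)
    np.testing.assert_allclose(analytic, fd, rtol=1e-5)


# ------------------------------------------------------------- config forms --
@pytest.mark.parametrize("name", sorted(preset_names()))
def test_config_text_round_trip(name):
    cfg = preset(name)
    again = config_from_text(config_to_text(cfg))
    assert again == cfg


def test_config_file_round_trip(tmp_path):
    cfg = preset("strong_b31")
    path = tmp_path / "net.cfg"
    save_config(cfg, path)
    assert load_config(path) == cfg


def test_packaged_baseline_matches_preset():
    data = resources.files("respcpg") / "data" / "baseline.cfg"
    assert config_from_text(data.read_text()) == preset("baseline4")


def test_packaged_pico_matches_preset():
    data = resources.files("respcpg") / "data" / "baseline_pico.cfg"
    assert config_from_text(data.read_text()) == preset("baseline5_pico")


# -------------------------------------------------------------- validation --
def test_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        UnitParams(name="x", excitatory=True, g_NaP=-1.0, g_K=1.0,
                   g_L=3.0, E_L=-65.0, theta_out=-32.0,
                   sigma_out=-8.0).validate()
    cfg = preset("baseline4")
    with pytest.raises((ValueError, KeyError)):
        cfg.with_weight("q", 1, 2, 0.5)


def test_scaled_inhibition_identity_and_targets():
    cfg = preset("baseline4")
    assert cfg.scaled_inhibition((3, 4), 1.0).b == cfg.b
    half = cfg.scaled_inhibition((3, 4), 0.5)
    assert half.b[(2, 3)] == pytest.approx(0.3)
    assert half.b[(3, 1)] == pytest.approx(0.125)  # non-target untouched


def test_compiled_pack_unpack_round_trip():
    cfg = preset("baseline5_pico")
    net = CompiledNetwork(cfg)
    rng = np.random.default_rng(3)
    state = StateVector(rng.uniform(-70, -20, 5), rng.uniform(0, 1, 5),
                        rng.uniform(0, 1, 5))
    back = net.unpack(net.pack(state))
    np.testing.assert_allclose(back.V, state.V)
    # dynamic-h entries preserved; quasi-steady replaced by h_inf(V)
    np.testing.assert_allclose(back.h[net.dynh_idx], state.h[net.dynh_idx])
    np.testing.assert_allclose(back.p[net.p_idx], state.p[net.p_idx])
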