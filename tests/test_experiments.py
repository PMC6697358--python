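"""Experiment pipelines: parameter mapping, block protocols, sweeps, and the
PiCo decoupling equivalence."""

import numpy as np
import pytest

from respcpg import preset
from respcpg.experiments import (
    BlockProtocol,
    compare_isolated_embedded,
    drive_sweep,
    get_parameter,
    inhibition_block,
    pico_suite,
    set_parameter,
)
from respcpg.rhythm_metrics import compute_metrics


def test_set_get_parameter_round_trip():
    cfg = preset("baseline4")
    for param, value in (("c11", -0.02), ("c13", 0.6), ("b31", 0.15)):
        assert get_parameter(set_parameter(cfg, param, value), param) == value
    assert get_parameter(cfg, "b31") == 0.125
    with pytest.raises(ValueError):
        set_parameter(cfg, "zz9", 1.0)


def test_block_protocol_identity_and_targets():
    cfg = preset("baseline4")
    p = BlockProtocol("BotC")
    assert p.apply(cfg, 1.0) == cfg
    half = BlockProtocol("preBotC").apply(cfg, 0.5)
    assert half.b[(3, 1)] == pytest.approx(0.0625)
    assert half.b[(3, 2)] == pytest.approx(0.135)
    assert half.b[(2, 3)] == pytest.approx(0.6)  # BotC inputs untouched
    assert half.c1 == cfg.c1  # drives never scaled
    with pytest.raises(ValueError):
        BlockProtocol("elsewhere")
    with pytest.raises(ValueError):
        p.apply(cfg, 1.5)


def test_compare_isolated_embedded_masking():
    """The embedded network oscillates where the isolated unit does not
    (masking), and its period differs from the isolated one."""
    df = compare_isolated_embedded([-0.05, -0.03, 0.01])
    row_osc = df[df.c11 == -0.03].iloc[0]
    assert row_osc.isolated_regime == "rhythmic"
    assert row_osc.embedded_regime == "rhythmic"
    assert abs(row_osc.embedded_T - row_osc.isolated_T) > 1.0
    row_tonic = df[df.c11 == 0.01].iloc[0]
    assert row_tonic.isolated_regime == "tonic"
    assert row_tonic.embedded_regime == "rhythmic"
    # at the low end of the isolated oscillatory range the network is not
    # rhythmic
    row_low = df[df.c11 == -0.05].iloc[0]
    assert row_low.isolated_regime == "rhythmic"
    assert row_low.embedded_regime != "rhythmic"


def test_drive_sweep_c11_direction():
    """More drive to pre-I shortens the cycle, mostly through T_E."""
    df = drive_sweep("c11", [-0.034, -0.03, -0.026])
    assert (df.regime == "rhythmic").all()
    assert df.three_phase_valid.all()
    T = df["T"].to_numpy()
    TE = df["T_E"].to_numpy()
    TI = df["T_I"].to_numpy()
    assert np.all(np.diff(T) < 0)
    assert np.all(np.diff(TE) < 0)
    # T_E change dominates the period change
    assert abs(TE[-1] - TE[0]) > 5 * abs(TI[-1] - TI[0])
    np.testing.assert_allclose(T, TI + TE, rtol=1e-9)


def test_c14_more_sensitive_than_c13():
    """Period responds more strongly to aug-E drive than to post-I drive."""
    d13 = drive_sweep("c13", [0.56, 0.60])
    d14 = drive_sweep("c14", [0.18, 0.22])
    s13 = abs(d13["T"].iloc[1] - d13["T"].iloc[0]) / 0.04
    s14 = abs(d14["T"].iloc[1] - d14["T"].iloc[0]) / 0.04
    assert s14 > s13
    # both raise the period via T_E
    assert d13["T"].iloc[1] > d13["T"].iloc[0]
    assert d14["T"].iloc[1] > d14["T"].iloc[0]


def test_inhibition_block_botc_tonic():
    res = inhibition_block(BlockProtocol("BotC"), [0.6, 0.8, 1.0], c11=0.01,
                           xtol=0.02)
    assert res.kappa_star < 0.8
    assert res.baseline.regime == "rhythmic"
    df = res.to_frame()
    assert set(df.kappa) == {0.6, 0.8, 1.0}
    # kappa* agrees with the coarse grid within one grid step
    grid_first_bad = 0.6
    assert abs(res.kappa_star - grid_first_bad) <= 0.2
    # period grows as inhibition is withdrawn toward the boundary
    assert res.boundary_metrics.T > res.baseline.T


def test_pico_output_disconnected_equivalence():
    """With a53 = 0 the 4 non-PiCo units behave exactly like the 4-unit
    network with b43 = 0.02."""
    from respcpg import find_attractor

    cfg5 = set_parameter(preset("baseline5_pico"), "a53", 0.0)
    cfg4 = preset("baseline4").with_weight("b", 4, 3, 0.02)
    m5 = compute_metrics(find_attractor(cfg5))
    m4 = compute_metrics(find_attractor(cfg4))
    assert m5.T == pytest.approx(m4.T, rel=1e-3)
    assert m5.amplitude == pytest.approx(m4.amplitude, rel=1e-3)


def test_pico_requires_pico_config():
    with pytest.raises(ValueError):
        pico_suite(preset("baseline4"))


def test_a53_period_change_is_expiratory():
    """The period change induced by a53 is carried by T_E."""
    df = drive_sweep("a53", [0.0, 0.2, 0.4], preset("baseline5_pico"))
    assert (df.regime == "rhythmic").all()
    dT = df["T"].iloc[-1] - df["T"].iloc[0]
    dTE = df["T_E"].iloc[-1] - df["T_E"].iloc[0]
    assert abs(dT) > 0.05  # a53 does move the period
    assert dTE == pytest.approx(dT, abs=0.1 * abs(dT) + 0.02)
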