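"""Phase-plane geometry: nullcline shapes, knee curves, fixed-point curves,
and escape-event projection."""

import numpy as np
import pytest

from respcpg import preset
from respcpg.model_core import SharedParams
from respcpg.phase_geometry import (
    fp_curve,
    knee_curve,
    project_escape,
    v_nullcline,
)
from respcpg.simulator import threshold_crossings

SH = SharedParams()
PRE_I = preset("baseline4").unit(1)
C2 = 0.095


def test_nullcline_shape_oscillatory_tuning():
    """With c11 = -0.03 the V-nullcline stays cubic over inh in [0, 0.15]."""
    for inh in np.linspace(0.0, 0.15, 16):
        nc = v_nullcline(PRE_I, SH, -0.03 + C2, float(inh))
        assert nc.shape == "cubic"


def test_nullcline_shape_changes_once_tonic_tuning():
    """With c11 = 0.01 the shape flips cubic->monotone exactly once, at the
    knee-curve termination inhibition."""
    kc = knee_curve(PRE_I, SH, 0.01 + C2, (0.0, 0.15))
    assert kc.termination is not None
    assert 0.0 < kc.termination < 0.02
    inh_grid = np.linspace(0.0, 0.15, 151)
    shapes = [v_nullcline(PRE_I, SH, 0.01 + C2, float(i)).shape
              for i in inh_grid]
    flips = sum(a != b for a, b in zip(shapes[:-1], shapes[1:]))
    assert flips == 1
    # the flip happens at the recorded termination
    k = next(i for i, (a, b) in enumerate(zip(shapes[:-1], shapes[1:]))
             if a != b)
    assert inh_grid[k] <= kc.termination <= inh_grid[k + 1]


def test_knee_curve_no_termination_oscillatory():
    kc = knee_curve(PRE_I, SH, -0.03 + C2, (0.0, 0.15))
    assert kc.termination is None
    assert kc.inh.size == 301
    # the left knee rises with inhibition (more inhibition, higher h needed)
    assert np.all(np.diff(kc.h_knee) > 0)


def test_knee_on_nullcline_fold():
    """At the knee, the nullcline's dh/dV vanishes."""
    from respcpg.model_core import v_nullcline_dh_dV

    kc = knee_curve(PRE_I, SH, -0.03 + C2, (0.0, 0.1), n_points=11)
    for inh, Vk in zip(kc.inh, kc.V_knee):
        assert abs(v_nullcline_dh_dV(PRE_I, SH, -0.03 + C2, float(inh),
                                     Vk)) < 1e-8


def test_fp_curve_consistent_with_find_fixed_points():
    from respcpg.unit_analysis import find_fixed_points

    pts = fp_curve(PRE_I, SH, -0.03 + C2, (0.0, 0.1), n_points=5)
    for inh, fp in pts:
        cand = find_fixed_points(PRE_I, SH, -0.03 + C2, inh)
        assert min(abs(fp.V - c.V) for c in cand) < 1e-9


def test_escape_events_per_cycle(oscillatory_trace):
    tr = oscillatory_trace
    kc = knee_curve(PRE_I, SH, -0.03 + C2, (0.0, 0.15))
    events, inh_path, h_path = project_escape(tr, 1, kc)
    assert events is not None
    ups = threshold_crossings(tr, 1, "V", -35.0, "up")
    # one escape per complete cycle, each preceding the inspiratory onset
    assert len(events) >= len(ups) - 2
    for ev in events:
        later = ups[ups >= ev.time - 1.0]
        assert later.size > 0
        assert later[0] - ev.time < 1500.0  # escape shortly before onset
    # escape values repeat across cycles
    vals = [ev.inh_sum for ev in events]
    assert np.ptp(vals) < 1e-3


def test_h_rises_while_below_fp_curve(oscillatory_trace):
    """During expiration h increases wherever the trajectory lies below the
    curve of fixed points (it relaxes toward the FP it would reach if
    inhibition were held fixed)."""
    tr = oscillatory_trace
    kc = knee_curve(PRE_I, SH, -0.03 + C2, (0.0, 0.15))
    events, inh_path, h_path = project_escape(tr, 1, kc)
    pts = fp_curve(PRE_I, SH, -0.03 + C2, (0.0, 0.12), n_points=121)
    inh_fp = np.array([i for i, _ in pts])
    h_fp = np.array([fp.h for _, fp in pts])
    downs = threshold_crossings(tr, 1, "V", -35.0, "down")
    d = downs[len(downs) // 2]
    ev = next(e for e in events if e.time > d)
    sel = (tr.t > d + 50.0) & (tr.t < ev.time - 50.0)
    below = h_path[sel] < np.interp(inh_path[sel], inh_fp, h_fp) - 1e-3
    dh = np.diff(tr.h[0, sel])
    assert below[:-1].any()
    assert np.all(dh[below[:-1]] > 0)
    # and h is higher at escape than at expiration onset
    i0 = np.searchsorted(tr.t, d)
    assert ev.h > tr.h[0, i0] + 0.1


def test_project_escape_none_on_steady():
    from respcpg import find_attractor
    from respcpg.model_core import isolated_unit_config

    cfg = isolated_unit_config(PRE_I, SH, -0.08 + C2)
    tr = find_attractor(cfg)
    kc = knee_curve(PRE_I, SH, -0.08 + C2, (0.0, 0.15))
    events, _, _ = project_escape(tr, 1, kc)
    assert events is None


def test_nullcline_rejects_e_na_grid():
    with pytest.raises(ValueError):
        v_nullcline(PRE_I, SH, 0.065, 0.0, np.array([-60.0, 50.0]))


def test_stronger_b31_escapes_at_higher_inhibition(oscillatory_trace):
    """Raising b31 to 0.175 moves the escape to larger inhibition and h."""
    from respcpg import find_attractor

    kc = knee_curve(PRE_I, SH, -0.03 + C2, (0.0, 0.25))
    base_ev, _, _ = project_escape(oscillatory_trace, 1, kc)
    tr = find_attractor(preset("strong_b31"))
    strong_ev, _, _ = project_escape(tr, 1, kc)
    assert strong_ev is not None
    assert strong_ev[0].inh_sum > base_ev[0].inh_sum
    assert strong_ev[0].h > base_ev[0].h
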