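"""Isolated-unit analysis: fixed points, Jacobian, Hopf detection, and the
eigenvalue-versus-simulation stability oracle."""

import numpy as np
import pytest

from respcpg import find_attractor, preset
from respcpg.model_core import (
    SharedParams,
    StateVector,
    isolated_unit_config,
    rhs,
)
from respcpg.unit_analysis import (
    _jacobian,
    classify_isolated,
    find_fixed_points,
    hopf_point,
)

SH = SharedParams()
PRE_I = preset("baseline4").unit(1)


def _rhs2(exc, inh, V, h):
    cfg = isolated_unit_config(PRE_I, SH, exc, inh)
    d = rhs(cfg, StateVector(np.array([V]), np.array([h]), np.zeros(1)))
    return np.array([d.V[0], d.h[0]])


def test_fixed_points_zero_rhs():
    for c11 in (-0.08, -0.03, 0.01):
        fps = find_fixed_points(PRE_I, SH, c11 + 0.095, 0.0)
        assert len(fps) in (1, 3)
        for fp in fps:
            np.testing.assert_allclose(
                _rhs2(c11 + 0.095, 0.0, fp.V, fp.h), 0.0, atol=1e-8)


def test_single_depolarized_fp_tonic_tuning():
    fps = find_fixed_points(PRE_I, SH, 0.01 + 0.095, 0.0)
    assert len(fps) == 1
    assert fps[0].stability == "stable"
    assert fps[0].V > -45.0  # depolarized


def test_jacobian_matches_finite_differences():
    exc, inh = 0.065, 0.01
    fp = find_fixed_points(PRE_I, SH, exc, inh)[0]
    J = _jacobian(PRE_I, SH, exc, inh, fp.V, fp.h)
    eps = 1e-6
    fd = np.zeros((2, 2))
    x0 = np.array([fp.V, fp.h])
    for j in range(2):
        dx = np.zeros(2)
        dx[j] = eps * (100.0 if j == 0 else 1.0)
        fp_ = x0 + dx
        fm_ = x0 - dx
        fd[:, j] = (_rhs2(exc, inh, *fp_) - _rhs2(exc, inh, *fm_)) / (2 * dx[j])
    np.testing.assert_allclose(J, fd, rtol=1e-4, atol=1e-10)


def test_hopf_points_bracket_oscillatory_interval():
    lo = hopf_point(PRE_I, SH, 0.0, (-0.08, -0.03))
    hi = hopf_point(PRE_I, SH, 0.0, (-0.03, 0.0))
    assert lo < hi
    assert -0.07 < lo < -0.05
    assert -0.02 < hi < -0.005


def test_stability_oracle_eigenvalues_vs_simulation():
    """Stable fixed point <=> simulation converges to it; unstable (with an
    oscillatory interval) <=> a periodic orbit appears."""
    for c11, expect in ((-0.08, "steady"), (-0.03, "periodic"),
                        (0.01, "steady")):
        fps = find_fixed_points(PRE_I, SH, c11 + 0.095, 0.0)
        stabilities = {fp.stability for fp in fps}
        tr = find_attractor(isolated_unit_config(PRE_I, SH, c11 + 0.095))
        assert tr.attractor_status == expect
        if expect == "steady":
            assert "stable" in stabilities
            stable = [fp for fp in fps if fp.stability == "stable"]
            assert min(abs(tr.V[0, -1] - fp.V) for fp in stable) < 1e-3
        else:
            # the tracked (unique) fixed point is unstable inside the
            # oscillatory interval
            assert len(fps) == 1 and fps[0].stability == "unstable"


def test_classify_isolated_three_regimes():
    assert classify_isolated(PRE_I, SH, -0.08 + 0.095) == "quiescent"
    assert classify_isolated(PRE_I, SH, -0.03 + 0.095) == "rhythmic"
    assert classify_isolated(PRE_I, SH, 0.01 + 0.095) == "tonic"


def test_inhibition_shifts_oscillatory_interval():
    """Weak frozen inhibition hyperpolarizes the unit, so more drive is
    needed: the lower Hopf point moves right (stronger inhibition removes
    the oscillatory interval entirely via its added linear conductance)."""
    lo0 = hopf_point(PRE_I, SH, 0.0, (-0.08, -0.03))
    lo1 = hopf_point(PRE_I, SH, 0.005, (-0.06, -0.02))
    assert lo1 > lo0
    with pytest.raises(ValueError):
        hopf_point(PRE_I, SH, 0.02, (-0.06, 0.06))
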