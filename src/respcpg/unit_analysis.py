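"""Isolated-unit dynamics: fixed points, linear stability, the drive
bifurcation diagram, and the two-parameter oscillatory/tonic transition curve.

An isolated excitatory unit under frozen synaptic sums is the planar system

    dV/dt = F(V, h) = -(I_NaP + I_K + I_L + I_synE + I_synI) / C
    dh/dt = G(V, h) = (h_inf(V) - h) / tau_h(V)

Fixed points are the intersections of the V-nullcline (h solving F = 0,
closed form since h enters F linearly) with h = h_inf(V).  As the tonic
drive c11 increases, the fixed point destabilizes and restabilizes through
a pair of Andronov-Hopf bifurcations accompanied by canard explosions, so
the interval of large-amplitude relaxation oscillations essentially
coincides with the interval where the fixed point is unstable.  Two boundary
definitions are therefore implemented and reported separately: the linear
Hopf condition (trace of the Jacobian = 0 with positive determinant) and a
simulation-detected onset of oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    NetworkConfig,
    SharedParams,
    StateVector,
    UnitParams,
    h_inf,
    isolated_unit_config,
    m_inf,
    n_inf,
    tau_h,
    v_nullcline_dh_dV,
    v_nullcline_h,
)
from .rhythm_metrics import RHYTHMIC_EXCURSION, TONIC_LEVEL, classify_regime
from .simulator import SolverOptions, find_attractor

V_SCAN = (-100.0, 20.0)
_N_SCAN = 2000


@dataclass(frozen=True)
class FixedPoint:
    V: float
    h: float
    stability: str                      # "stable" | "unstable"
    eigenvalues: Tuple[complex, complex]  # 1/ms
    branch: str                         # "left" | "middle" | "right"


@dataclass
class BifurcationDiagram:
    c11: np.ndarray
    fixed_points: List[FixedPoint]
    v_min: np.ndarray      # orbit envelope; nan where not oscillatory
    v_max: np.ndarray
    period: np.ndarray     # s; nan where not oscillatory
    oscillatory_interval: Optional[Tuple[float, float]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "c11": self.c11,
                "V_fp": [fp.V for fp in self.fixed_points],
                "h_fp": [fp.h for fp in self.fixed_points],
                "stability": [fp.stability for fp in self.fixed_points],
                "V_min": self.v_min,
                "V_max": self.v_max,
                "period_s": self.period,
            }
        )


@dataclass
class TransitionCurve:
    g_NaP: np.ndarray
    c11: np.ndarray
    kind: str       # "oscillatory-to-tonic" | "quiescent-to-oscillatory"
    method: str     # "linear-hopf" | "simulation-onset"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"g_NaP_nS": self.g_NaP, "c11": self.c11})


# --------------------------------------------------------------------------
# Planar subsystem and Jacobian
# --------------------------------------------------------------------------

def _jacobian(
    unit: UnitParams,
    shared: SharedParams,
    exc_sum: float,
    inh_sum: float,
    V: float,
    h: float,
) -> np.ndarray:
    """Analytic 2x2 Jacobian of (F, G) at (V, h)."""
    sh = shared
    m = float(m_inf(V, sh))
    dm = m * (1.0 - m) * (-1.0 / sh.sigma_m)
    nn = float(n_inf(V, sh))
    dn = nn * (1.0 - nn) * (-1.0 / sh.sigma_n)
    hi = float(h_inf(V, sh))
    dhi = hi * (1.0 - hi) * (-1.0 / sh.sigma_h)
    th = float(tau_h(V, sh))
    u = (V - sh.theta_h) / (2.0 * sh.sigma_h)
    dth = -sh.epsilon * np.sinh(u) / np.cosh(u) ** 2 / (2.0 * sh.sigma_h)

    dIdV = (
        unit.g_NaP * h * (dm * (V - sh.E_Na) + m)
        + unit.g_K * (4.0 * nn ** 3 * dn * (V - sh.E_K) + nn ** 4)
        + unit.g_L
        + sh.g_synE * exc_sum
        + sh.g_synI * inh_sum
    )
    dFdV = -dIdV / sh.C
    dFdh = -unit.g_NaP * m * (V - sh.E_Na) / sh.C
    dGdV = dhi / th - (hi - h) * dth / th ** 2
    dGdh = -1.0 / th
    return np.array([[dFdV, dFdh], [dGdV, dGdh]])


def _knee_voltages(
    unit: UnitParams, shared: SharedParams, exc_sum: float, inh_sum: float
) -> List[float]:
    """Voltages of the V-nullcline folds (roots of dh_null/dV) on the scan
    range, in increasing order."""
    V = np.linspace(*V_SCAN, _N_SCAN)
    d = v_nullcline_dh_dV(unit, shared, exc_sum, inh_sum, V)
    roots = []
    sgn = np.sign(d)
    for k in np.where(sgn[:-1] * sgn[1:] < 0)[0]:
        roots.append(
            brentq(
                lambda x: float(v_nullcline_dh_dV(unit, shared, exc_sum, inh_sum, x)),
                V[k],
                V[k + 1],
                xtol=1e-10,
            )
        )
    return roots


def find_fixed_points(
    unit: UnitParams,
    shared: SharedParams,
    exc_sum: float,
    inh_sum: float = 0.0,
) -> List[FixedPoint]:
    """All equilibria of the isolated planar unit under frozen inputs.

    Roots of h_null(V) = h_inf(V) are located by a dense sign scan with
    bisection refinement; each is returned with its Jacobian eigenvalues and
    a branch label relative to the nullcline folds.
    """
    V = np.linspace(*V_SCAN, _N_SCAN)
    r = v_nullcline_h(unit, shared, exc_sum, inh_sum, V) - h_inf(V, shared)

    def resid(x: float) -> float:
        return float(
            v_nullcline_h(unit, shared, exc_sum, inh_sum, x) - h_inf(x, shared)
        )

    roots: List[float] = []
    sgn = np.sign(r)
    for k in np.where(sgn[:-1] * sgn[1:] < 0)[0]:
        roots.append(brentq(resid, V[k], V[k + 1], xtol=1e-12))
    if not roots:
        raise RuntimeError(
            "no fixed point found on the scan range; widen V_SCAN"
        )
    knees = _knee_voltages(unit, shared, exc_sum, inh_sum)
    out = []
    for Vr in roots:
        hr = float(h_inf(Vr, shared))
        J = _jacobian(unit, shared, exc_sum, inh_sum, Vr, hr)
        eig = np.linalg.eigvals(J)
        stab = "stable" if np.all(eig.real < 0) else "unstable"
        if len(knees) >= 2:
            if Vr < knees[0]:
                branch = "left"
            elif Vr < knees[-1]:
                branch = "middle"
            else:
                branch = "right"
        else:
            # monotone nullcline: single branch; label by voltage relative
            # to the h-nullcline midpoint
            branch = "left" if Vr < shared.theta_h else "right"
        out.append(FixedPoint(Vr, hr, stab, (complex(eig[0]), complex(eig[1])), branch))
    return out


def _tracked_fp(
    unit, shared, exc_sum, inh_sum, previous: Optional[FixedPoint] = None
) -> FixedPoint:
    fps = find_fixed_points(unit, shared, exc_sum, inh_sum)
    if len(fps) == 1 or previous is None:
        return fps[0]
    return min(fps, key=lambda fp: abs(fp.V - previous.V))


def hopf_point(
    unit: UnitParams,
    shared: SharedParams,
    inh_sum: float,
    bracket: Tuple[float, float],
    c2: float = 0.095,
) -> float:
    """c11 where trace(J) = 0 with det(J) > 0 at the tracked fixed point.

    ``c2`` is the unit's fixed second drive; the frozen excitatory sum is
    c11 + c2.  Raises if the trace does not change sign over the bracket.
    """

    def tr(c11: float) -> float:
        fp = _tracked_fp(unit, shared, c11 + c2, inh_sum)
        J = _jacobian(unit, shared, c11 + c2, inh_sum, fp.V, fp.h)
        return float(np.trace(J))

    lo, hi = bracket
    if tr(lo) * tr(hi) > 0:
        raise ValueError("trace(J) does not change sign over the bracket")
    c11 = brentq(tr, lo, hi, xtol=1e-7)
    fp = _tracked_fp(unit, shared, c11 + c2, inh_sum)
    J = _jacobian(unit, shared, c11 + c2, inh_sum, fp.V, fp.h)
    if np.linalg.det(J) <= 0:
        raise ValueError("det(J) <= 0 at trace zero: saddle-node, not Hopf")
    return float(c11)


# --------------------------------------------------------------------------
# Simulation-based regime classification and boundaries
# --------------------------------------------------------------------------

_ISOLATED_OPTS = SolverOptions(transient=60000.0, record_window=40000.0,
                               max_total=240000.0)


# Minimum peak-to-peak voltage for a simulated orbit to count as a periodic
# attractor rather than residual transient ringing.  Near the upper Hopf
# point the stable orbit shrinks continuously, so boundary detection keys on
# orbit existence, not on a functional output excursion.
ORBIT_V_FLOOR = 0.5  # mV


def classify_isolated(
    unit: UnitParams,
    shared: SharedParams,
    exc_sum: float,
    inh_sum: float = 0.0,
    opts: SolverOptions = _ISOLATED_OPTS,
) -> str:
    """{'rhythmic', 'tonic', 'quiescent', 'undetermined'} for the isolated
    unit at frozen inputs, from a long simulation.

    'rhythmic' means a stable periodic orbit of any amplitude above a small
    voltage noise floor; steady states split into tonic/quiescent on the
    unit's output level.
    """
    cfg = isolated_unit_config(unit, shared, exc_sum, inh_sum)
    trace = find_attractor(cfg, opts)
    if trace.attractor_status == "periodic" and np.ptp(trace.V[0]) > ORBIT_V_FLOOR:
        return "rhythmic"
    if trace.attractor_status == "undetermined":
        return "undetermined"
    return "tonic" if trace.f_out[0, -1] > TONIC_LEVEL else "quiescent"


def oscillation_boundaries(
    unit: UnitParams,
    shared: SharedParams,
    g_NaP: Optional[float] = None,
    c2: float = 0.095,
    c11_range: Tuple[float, float] = (-0.12, 0.02),
    coarse_step: float = 0.005,
    xtol: float = 1e-4,
    opts: SolverOptions = _ISOLATED_OPTS,
) -> Optional[Tuple[float, float]]:
    """(c11_low, c11_high) bracketing the rhythmic interval of the isolated
    unit, each located by bisection on simulations; None if no oscillatory
    interval exists (e.g. g_NaP too small)."""
    if g_NaP is not None:
        unit = replace(unit, g_NaP=g_NaP)
    if unit.g_NaP <= 0:
        return None

    def regime(c11: float) -> str:
        return classify_isolated(unit, shared, c11 + c2, 0.0, opts)

    grid = np.arange(c11_range[0], c11_range[1] + coarse_step / 2, coarse_step)
    labels = [regime(c) for c in grid]
    if "rhythmic" not in labels:
        return None
    idx = [k for k, l in enumerate(labels) if l == "rhythmic"]
    lo_k, hi_k = idx[0], idx[-1]

    def bisect(a: float, b: float, rhythmic_side: str) -> float:
        # invariant: exactly one endpoint is rhythmic
        while b - a > xtol:
            m = 0.5 * (a + b)
            if (regime(m) == "rhythmic") == (rhythmic_side == "right"):
                b = m
            else:
                a = m
        return 0.5 * (a + b)

    if lo_k == 0:
        low = grid[0]
    else:
        low = bisect(grid[lo_k - 1], grid[lo_k], "right")
    if hi_k == len(grid) - 1:
        high = grid[-1]
    else:
        high = bisect(grid[hi_k], grid[hi_k + 1], "left")
    return float(low), float(high)


def bifurcation_diagram(
    unit: UnitParams,
    shared: SharedParams,
    c11_grid: np.ndarray,
    c2: float = 0.095,
    opts: SolverOptions = _ISOLATED_OPTS,
) -> BifurcationDiagram:
    """Fixed points, stability, and simulated orbit envelopes/periods
    against the tonic drive."""
    fps: List[FixedPoint] = []
    vmin = np.full(len(c11_grid), np.nan)
    vmax = np.full(len(c11_grid), np.nan)
    per = np.full(len(c11_grid), np.nan)
    prev = None
    for k, c11 in enumerate(c11_grid):
        prev = _tracked_fp(unit, shared, c11 + c2, 0.0, prev)
        fps.append(prev)
        cfg = isolated_unit_config(unit, shared, c11 + c2, 0.0)
        trace = find_attractor(cfg, opts)
        if (
            trace.attractor_status == "periodic"
            and np.ptp(trace.V[0]) > ORBIT_V_FLOOR
        ):
            vmin[k] = trace.V[0].min()
            vmax[k] = trace.V[0].max()
            per[k] = trace.cycle_periods.mean() / 1000.0
    interval = oscillation_boundaries(
        unit, shared, c2=c2,
        c11_range=(float(c11_grid[0]), float(c11_grid[-1])), opts=opts,
    )
    return BifurcationDiagram(np.asarray(c11_grid), fps, vmin, vmax, per, interval)


def continue_transition_curve(
    unit: UnitParams,
    shared: SharedParams,
    g_NaP_grid: np.ndarray,
    kind: str = "oscillatory-to-tonic",
    method: str = "linear-hopf",
    c2: float = 0.095,
    warm_start: bool = True,
) -> TransitionCurve:
    """Oscillation boundary in the (g_NaP, c11) plane.

    For each g_NaP the boundary c11 is found either from the linear Hopf
    condition or from simulation-detected oscillation onset; consecutive
    solutions warm-start the bracket.  The curve is truncated (with nan)
    where the boundary ceases to exist at small g_NaP.
    """
    if kind not in ("oscillatory-to-tonic", "quiescent-to-oscillatory"):
        raise ValueError(f"unknown kind {kind!r}")
    out = np.full(len(g_NaP_grid), np.nan)
    prev: Optional[float] = None
    for k, g in enumerate(g_NaP_grid):
        u = replace(unit, g_NaP=float(g))
        if g <= 0:
            continue
        try:
            if method == "linear-hopf":
                if prev is not None and warm_start:
                    brackets = [(prev - 0.01, prev + 0.01), (-0.12, 0.02)]
                else:
                    brackets = [(-0.12, 0.02)]
                val = None
                for br in brackets:
                    try:
                        val = _hopf_boundary(u, shared, br, kind, c2)
                        break
                    except ValueError:
                        continue
                if val is None:
                    continue
            else:
                bounds = oscillation_boundaries(u, shared, c2=c2)
                if bounds is None:
                    continue
                val = bounds[0] if kind == "quiescent-to-oscillatory" else bounds[1]
        except (ValueError, RuntimeError):
            continue
        out[k] = val
        prev = val
    return TransitionCurve(np.asarray(g_NaP_grid, float), out, kind, method)


def _hopf_boundary(
    unit: UnitParams,
    shared: SharedParams,
    bracket: Tuple[float, float],
    kind: str,
    c2: float,
) -> float:
    """The lower or upper Hopf point inside the bracket.

    trace(J) along c11 is negative-positive-negative; locate the sign
    changes on a scan and refine the requested one.
    """

    def tr(c11: float) -> float:
        fp = _tracked_fp(unit, shared, c11 + c2, 0.0)
        J = _jacobian(unit, shared, c11 + c2, 0.0, fp.V, fp.h)
        return float(np.trace(J))

    grid = np.linspace(bracket[0], bracket[1], 61)
    vals = np.array([tr(c) for c in grid])
    sgn = np.sign(vals)
    changes = np.where(sgn[:-1] * sgn[1:] < 0)[0]
    if changes.size == 0:
        raise ValueError("no Hopf point in bracket")
    k = changes[0] if kind == "quiescent-to-oscillatory" else changes[-1]
    if changes.size == 1:
        # only one boundary in the bracket; make sure it is the right one
        want_up = kind == "quiescent-to-oscillatory"
        is_up = vals[k] < 0 < vals[k + 1]
        if want_up != is_up:
            raise ValueError("requested boundary not inside bracket")
    c11 = brentq(tr, grid[k], grid[k + 1], xtol=1e-7)
    fp = _tracked_fp(unit, shared, c11 + c2, 0.0)
    J = _jacobian(unit, shared, c11 + c2, 0.0, fp.V, fp.h)
    if np.linalg.det(J) <= 0:
        raise ValueError("det(J) <= 0: saddle-node, not Hopf")
    return float(c11)
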