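"""Phase-plane geometry under frozen synaptic input: V- and h-nullclines,
the curve of left knees LK(inh), the curve of fixed points FP(inh), and
trajectory projections onto the (inhibition, h) plane.

During expiration the pre-I unit receives only its frozen tonic drive plus a
slowly declining weighted inhibition.  Against the inhibition level, both
the fold (knee) of the cubic V-nullcline and the fixed point trace out
curves; the inspiratory "escape" happens where the slowly rising h carries
the trajectory across the curve of left knees, after which V jumps to the
depolarized branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    SharedParams,
    UnitParams,
    h_inf,
    v_nullcline_dh_dV,
    v_nullcline_h,
)
from .simulator import INSPIRATORY_THRESHOLD, Trace, threshold_crossings
from .unit_analysis import FixedPoint, V_SCAN, _knee_voltages, find_fixed_points

H_CLIP = (-0.2, 1.2)


@dataclass
class NullclineCurve:
    V: np.ndarray
    h: np.ndarray
    exc_sum: float
    inh_sum: float
    unit_name: str
    shape: str              # "cubic" | "monotone"
    clipped: np.ndarray     # bool mask: sample fell outside H_CLIP

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"V_mV": self.V, "h": self.h, "clipped": self.clipped})


@dataclass
class KneeCurve:
    inh: np.ndarray
    V_knee: np.ndarray
    h_knee: np.ndarray
    side: str                        # "left" | "right"
    termination: Optional[float]     # inh where the fold ceases, if any

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"inh_sum": self.inh, "V_knee_mV": self.V_knee, "h_knee": self.h_knee}
        )

    def h_at(self, inh):
        """Knee h interpolated at the given inhibition levels (nan outside
        the curve's domain)."""
        return np.interp(inh, self.inh, self.h_knee, left=np.nan, right=np.nan)


@dataclass
class EscapeEvent:
    time: float       # ms
    inh_sum: float
    h: float


def v_nullcline(
    unit: UnitParams,
    shared: SharedParams,
    exc_sum: float,
    inh_sum: float,
    V_grid: Optional[np.ndarray] = None,
) -> NullclineCurve:
    """Closed-form V-nullcline h(V) at frozen inputs, with shape label.

    The shape is "cubic" when the curve has interior folds (dh/dV changes
    sign) and "monotone" otherwise.
    """
    if V_grid is None:
        V_grid = np.linspace(*V_SCAN, 1201)
    V_grid = np.asarray(V_grid, float)
    if np.any(np.isclose(V_grid, shared.E_Na)):
        raise ValueError("V grid must exclude E_Na")
    h = v_nullcline_h(unit, shared, exc_sum, inh_sum, V_grid)
    clipped = (h < H_CLIP[0]) | (h > H_CLIP[1])
    folds = _knee_voltages(unit, shared, exc_sum, inh_sum)
    shape = "cubic" if len(folds) >= 2 else "monotone"
    return NullclineCurve(
        V_grid, np.clip(h, *H_CLIP), exc_sum, inh_sum, unit.name, shape, clipped
    )


def knee_curve(
    unit: UnitParams,
    shared: SharedParams,
    exc_sum: float,
    inh_range: Tuple[float, float] = (0.0, 0.15),
    side: str = "left",
    n_points: int = 301,
) -> KneeCurve:
    """Track a fold of the V-nullcline over the inhibition level.

    The left knee is the lower-voltage fold.  Where the nullcline turns
    monotone the fold ceases; the termination inhibition is refined by
    bisection and recorded.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if inh_range[0] < 0:
        raise ValueError("inhibition range must be non-negative")
    inh_grid = np.linspace(inh_range[0], inh_range[1], n_points)

    def fold_V(inh: float) -> Optional[float]:
        folds = _knee_voltages(unit, shared, exc_sum, inh)
        if len(folds) < 2:
            return None
        return folds[0] if side == "left" else folds[-1]

    inh_out, Vk, hk = [], [], []
    exists = []
    for inh in inh_grid:
        v = fold_V(inh)
        exists.append(v is not None)
        if v is not None:
            inh_out.append(inh)
            Vk.append(v)
            hk.append(float(v_nullcline_h(unit, shared, exc_sum, inh, v)))
    termination = None
    exists = np.array(exists)
    if exists.any() and not exists.all():
        # refine the lowest inh at which the fold disappears adjacent to the
        # existing stretch
        k = np.where(exists)[0]
        edges = []
        if k[0] > 0:
            edges.append((inh_grid[k[0] - 1], inh_grid[k[0]]))
        if k[-1] < len(inh_grid) - 1:
            edges.append((inh_grid[k[-1]], inh_grid[k[-1] + 1]))
        lo, hi = edges[0]
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if (fold_V(mid) is None) == (fold_V(lo) is None):
                lo = mid
            else:
                hi = mid
        termination = 0.5 * (lo + hi)
    return KneeCurve(
        np.asarray(inh_out), np.asarray(Vk), np.asarray(hk), side, termination
    )


def fp_curve(
    unit: UnitParams,
    shared: SharedParams,
    exc_sum: float,
    inh_range: Tuple[float, float] = (0.0, 0.15),
    n_points: int = 301,
) -> List[Tuple[float, FixedPoint]]:
    """Fixed points tracked over the inhibition level (branch continuity by
    nearest-V matching)."""
    inh_grid = np.linspace(inh_range[0], inh_range[1], n_points)
    out: List[Tuple[float, FixedPoint]] = []
    prev: Optional[FixedPoint] = None
    for inh in inh_grid:
        fps = find_fixed_points(unit, shared, exc_sum, float(inh))
        if prev is None or len(fps) == 1:
            fp = fps[0]
        else:
            fp = min(fps, key=lambda f: abs(f.V - prev.V))
        out.append((float(inh), fp))
        prev = fp
    return out


def project_escape(
    trace: Trace,
    unit: int,
    knees: KneeCurve,
    fps: Optional[List[Tuple[float, FixedPoint]]] = None,
) -> Tuple[Optional[List[EscapeEvent]], np.ndarray, np.ndarray]:
    """Project a unit's trajectory to the (inhibition, h) plane and locate
    the escape events where it crosses the curve of left knees.

    Returns (events, inh_path, h_path).  One event per cycle: the first
    up-crossing of h(t) - h_LK(inh(t)) inside the expiratory window of that
    cycle.  ``None`` events when the trace is non-rhythmic or the knee curve
    is empty within the visited inhibition range.
    """
    k = unit - 1
    inh_path = trace.inh_sum[k]
    h_path = trace.h[k]
    if trace.attractor_status != "periodic" or knees.inh.size == 0:
        return None, inh_path, h_path
    margin = h_path - knees.h_at(inh_path)
    ups = threshold_crossings(trace, 1, "V", INSPIRATORY_THRESHOLD, "up")
    downs = threshold_crossings(trace, 1, "V", INSPIRATORY_THRESHOLD, "down")
    if ups.size < 2 or downs.size == 0:
        return None, inh_path, h_path
    events: List[EscapeEvent] = []
    for u_next in ups[1:]:
        earlier = downs[downs < u_next]
        if earlier.size == 0:
            continue
        d_prev = earlier[-1]
        sel = (trace.t >= d_prev) & (trace.t <= u_next + 1.0)
        idx = np.where(sel)[0]
        m = margin[idx]
        valid = ~np.isnan(m)
        cross = np.where((m[:-1] <= 0) & (m[1:] > 0) & valid[:-1] & valid[1:])[0]
        if cross.size == 0:
            continue
        j = idx[cross[0]]
        # linear refinement between samples j and j+1
        f = -margin[j] / (margin[j + 1] - margin[j])
        t_ev = trace.t[j] + f * (trace.t[j + 1] - trace.t[j])
        inh_ev = inh_path[j] + f * (inh_path[j + 1] - inh_path[j])
        h_ev = h_path[j] + f * (h_path[j + 1] - h_path[j])
        events.append(EscapeEvent(float(t_ev), float(inh_ev), float(h_ev)))
    return (events or None), inh_path, h_path
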