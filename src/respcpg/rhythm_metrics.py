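"""Rhythm observables: period, phase durations, amplitude, regime labels,
and validation of the three-phase activation pattern.

The inspiratory phase is delimited by up/down crossings of the pre-I
voltage through -35 mV; the period T is the mean inter-up-crossing interval,
T_I the mean up-to-down interval, and T_E = T - T_I.  Amplitude is the
max-minus-min excursion of the pre-I output sigmoid f_out(V_1) over the
analyzed cycles.  All durations are reported in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .simulator import INSPIRATORY_THRESHOLD, Trace, threshold_crossings, \
    _signal_crossings

# Classification thresholds.  Rhythmic excursions observed in practice are
# ~0.2-0.9, far above the 0.05 floor.  Steady-state outputs of the pre-I
# unit are below ~0.08 on the quiescent side of the lower Hopf point and
# above ~0.27 on the tonic side of the upper one, so the 0.15 split falls in
# the gap between the regimes.
RHYTHMIC_EXCURSION = 0.05
TONIC_LEVEL = 0.15


@dataclass
class RhythmMetrics:
    T: Optional[float]            # s
    T_I: Optional[float]          # s
    T_E: Optional[float]          # s
    amplitude: Optional[float]    # dimensionless
    regime: str                   # rhythmic | tonic | quiescent | undetermined
    three_phase_valid: Optional[bool]
    n_cycles_used: int


def classify_regime(
    trace: Trace,
    unit="network",
    excursion_threshold: float = RHYTHMIC_EXCURSION,
    tonic_level: float = TONIC_LEVEL,
) -> str:
    """Label the attractor trace for one unit or for the whole network.

    Rhythmic: the attractor is periodic and the unit's output excursion
    exceeds the threshold (for "network", the pre-I output is used).
    Otherwise tonic if the steady output exceeds 0.5 (for "network", if any
    unit's does), else quiescent.
    """
    if trace.attractor_status == "undetermined":
        return "undetermined"
    status = trace.attractor_status
    if status == "unchecked":
        from .simulator import _periodicity

        periodic, _ = _periodicity(trace)
        status = "periodic" if periodic else status
    k = 0 if unit == "network" else unit - 1
    if status == "periodic":
        if np.ptp(trace.f_out[k]) > excursion_threshold:
            return "rhythmic"
    final = trace.f_out[:, -1]
    if unit == "network":
        return "tonic" if np.any(final > tonic_level) else "quiescent"
    return "tonic" if final[k] > tonic_level else "quiescent"


def inspiratory_markers(trace: Trace) -> Tuple[np.ndarray, np.ndarray]:
    """(up, down) crossing times delimiting the inspiratory phase.

    Uses the -35 mV convention on V_1; oscillations too small to reach it
    (low g_NaP / near-Hopf orbits) fall back to crossings of the mid-range
    voltage, the same marker the periodicity check uses.
    """
    ups = threshold_crossings(trace, 1, "V", INSPIRATORY_THRESHOLD, "up")
    downs = threshold_crossings(trace, 1, "V", INSPIRATORY_THRESHOLD, "down")
    if ups.size < 2:
        v = trace.V[0]
        if np.ptp(v) > 0:
            mid = 0.5 * (v.min() + v.max())
            ups = _signal_crossings(trace.t, v, mid, "up")
            downs = _signal_crossings(trace.t, v, mid, "down")
    return ups, downs


def compute_metrics(trace: Trace) -> RhythmMetrics:
    """Extract rhythm metrics from an attractor trace (>= 4 cycles)."""
    regime = classify_regime(trace, "network")
    if regime != "rhythmic":
        return RhythmMetrics(None, None, None, None, regime, None, 0)
    ups, downs = inspiratory_markers(trace)
    if ups.size < 2:
        return RhythmMetrics(None, None, None, None, regime, None, 0)
    periods = np.diff(ups)
    n_cycles = len(periods)
    T = periods.mean() / 1000.0
    t_i = []
    for u in ups[:-1]:
        later = downs[downs > u]
        if later.size:
            t_i.append(later[0] - u)
    T_I = float(np.mean(t_i)) / 1000.0 if t_i else None
    T_E = T - T_I if T_I is not None else None
    # amplitude over the complete cycles analyzed
    mask = (trace.t >= ups[0]) & (trace.t <= ups[-1])
    amplitude = float(np.ptp(trace.f_out[0, mask]))
    if trace.n_units >= 4 and trace.attractor_status == "periodic":
        try:
            valid, _ = validate_three_phase(trace)
        except ValueError:
            valid = None
    else:
        valid = None
    return RhythmMetrics(float(T), T_I, T_E, amplitude, regime, valid, n_cycles)


def _onset_times(t, sig, min_dwell: float = 25.0) -> np.ndarray:
    """Up-crossings of a signal through half of its full range.

    A crossing counts as an activation onset only if the signal stays above
    the level for at least ``min_dwell`` ms, which discards the few-millisecond
    transient spike the aug-E unit emits while losing the competition with
    post-I at the inspiratory-to-expiratory transition.
    """
    lo, hi = sig.min(), sig.max()
    level = lo + 0.5 * (hi - lo)
    ups = _signal_crossings(t, sig, level, "up")
    downs = _signal_crossings(t, sig, level, "down")
    kept = []
    for u in ups:
        later = downs[downs > u]
        dwell = (later[0] - u) if later.size else (t[-1] - u)
        if dwell >= min_dwell:
            kept.append(u)
    return np.asarray(kept)


def validate_three_phase(
    trace: Trace, together_tol: float = 50.0
) -> Tuple[bool, List[List[Tuple[str, float]]]]:
    """Check the functional activation order in every complete cycle.

    Requirements per cycle: pre-I onset before or together with early-I
    (within ``together_tol`` ms), followed by post-I onset and then aug-E
    onset; and aug-E output exceeding post-I output at the last sample
    before the next inspiratory onset.  Onsets are each unit's up-crossing
    of its own output through half of its cycle range.
    """
    if trace.attractor_status != "periodic":
        raise ValueError("three-phase validation requires a rhythmic trace")
    if trace.n_units < 4:
        raise ValueError("three-phase validation requires the full network")
    names = [u.name for u in trace.config.units]
    n_check = 4
    insp, _ = inspiratory_markers(trace)
    if insp.size < 3:
        raise ValueError("not enough cycles for validation")
    onsets = [_onset_times(trace.t, trace.f_out[k]) for k in range(n_check)]
    all_orders: List[List[Tuple[str, float]]] = []
    ok = True
    # cycles delimited by inspiratory onsets; the inspiratory units get a
    # lead window so that pre-I/early-I onsets slightly preceding the -35 mV
    # crossing count toward the cycle they initiate, while the expiratory
    # units' onsets belong strictly inside the cycle (aug-E activates only
    # shortly before the next inspiration)
    lead = 200.0
    for c in range(insp.size - 1):
        cyc = []
        for k in range(n_check):
            off = lead if k < 2 else 0.0
            t0, t1 = insp[c] - off, insp[c + 1] - off
            within = onsets[k][(onsets[k] >= t0) & (onsets[k] < t1)]
            cyc.append((names[k], within[0] if within.size else np.nan))
        all_orders.append(cyc)
        times = [x[1] for x in cyc]
        if any(np.isnan(times)):
            ok = False
            continue
        o1, o2, o3, o4 = times
        if not (o1 <= o2 + together_tol and o2 < o3 < o4):
            ok = False
        # aug-E > post-I at end of expiration (sample before next onset)
        pre_idx = np.searchsorted(trace.t, insp[c + 1]) - 1
        if trace.f_out[3, pre_idx] <= trace.f_out[2, pre_idx]:
            ok = False
    return ok, all_orders


def metrics_row(metrics: RhythmMetrics, **params) -> dict:
    """One delimited-table row: swept parameters plus all metrics."""
    row = dict(params)
    row.update(
        T=metrics.T, T_I=metrics.T_I, T_E=metrics.T_E,
        amplitude=metrics.amplitude, regime=metrics.regime,
        three_phase_valid=metrics.three_phase_valid,
        n_cycles_used=metrics.n_cycles_used,
    )
    return row
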