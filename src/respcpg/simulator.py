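"""ODE integration to attractors, dense traces and threshold crossings.

The dynamics are slow-fast: voltage relaxes on a few milliseconds
(C/g ~ 5 ms) while the I_NaP inactivation h evolves on seconds
(epsilon = 4000 ms), so a stiff-capable adaptive integrator (LSODA) with a
capped step is used.  Attractors are located by discarding a transient and
then requiring either a steady state or a periodic orbit with tightly
repeatable cycle lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .model_core import CompiledNetwork, NetworkConfig, StateVector
from .scenarios import default_initial_state, random_initial_state

# Threshold on V_1 (mV) used to delimit the inspiratory phase.
INSPIRATORY_THRESHOLD = -35.0


@dataclass(frozen=True)
class SolverOptions:
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = 10.0       # ms
    transient: float = 60000.0   # ms discarded before recording
    record_dt: float = 1.0       # ms
    seed: Optional[int] = None   # randomized initial conditions when set
    record_window: float = 40000.0   # ms recorded for attractor analysis
    max_total: float = 400000.0  # ms cap on total simulated time

    def validate(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.transient < 0:
            raise ValueError("transient must be non-negative")


@dataclass
class Trace:
    """Time-stamped solution with derived outputs.

    Arrays are (n_units, n_samples); ``h`` holds the effective inactivation
    (quasi-steady entries filled with h_inf(V)).  ``attractor_status`` is set
    by :func:`find_attractor` to one of {"periodic", "steady",
    "undetermined", "unchecked"}.
    """

    t: np.ndarray
    V: np.ndarray
    h: np.ndarray
    p: np.ndarray
    f_out: np.ndarray
    inh_sum: np.ndarray
    config: NetworkConfig
    opts: SolverOptions
    final_packed: np.ndarray
    attractor_status: str = "unchecked"
    cycle_periods: Optional[np.ndarray] = None

    @property
    def n_units(self) -> int:
        return self.V.shape[0]

    def to_frame(self):
        """Delimited-table form: one row per sample."""
        import pandas as pd

        names = [u.name for u in self.config.units]
        data = {"t_ms": self.t}
        for k, nm in enumerate(names):
            data[f"V_{nm}"] = self.V[k]
            data[f"h_{nm}"] = self.h[k]
            data[f"p_{nm}"] = self.p[k]
            data[f"f_out_{nm}"] = self.f_out[k]
            data[f"inh_sum_{nm}"] = self.inh_sum[k]
        return pd.DataFrame(data)


class IntegrationError(RuntimeError):
    """Integration failure; carries the last valid packed state."""

    def __init__(self, message: str, last_state: Optional[np.ndarray] = None):
        super().__init__(message)
        self.last_state = last_state


def _solve(net: CompiledNetwork, y0, t_span, opts: SolverOptions, t_eval=None):
    sol = solve_ivp(
        net.rhs,
        t_span,
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=opts.rel_tol,
        atol=opts.abs_tol,
        max_step=opts.max_step,
    )
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else None
        raise IntegrationError(f"integration failed: {sol.message}", last)
    return sol


def _build_trace(
    net: CompiledNetwork, t: np.ndarray, Y: np.ndarray, opts: SolverOptions
) -> Trace:
    n, nd = net.n, len(net.dynh_idx)
    V = Y[:n]
    from .model_core import h_inf

    h = h_inf(V, net.shared)
    h[net.dynh_idx] = Y[n : n + nd]
    p = np.zeros_like(V)
    p[net.p_idx] = Y[n + nd :]
    fo = net.outputs(V)
    inh, _ = net.sums(V)
    return Trace(
        t=t - t[0],
        V=V,
        h=h,
        p=p,
        f_out=fo,
        inh_sum=inh,
        config=net.config,
        opts=opts,
        final_packed=Y[:, -1].copy(),
    )


def integrate(
    config: NetworkConfig,
    state0: StateVector,
    duration: float,
    opts: SolverOptions = SolverOptions(),
) -> Trace:
    """Integrate for ``duration`` ms after discarding ``opts.transient`` ms."""
    opts.validate()
    if np.any(state0.V < -100) or np.any(state0.V > 60):
        raise ValueError("initial V outside physical bounds [-100, 60] mV")
    if np.any(state0.h < 0) or np.any(state0.h > 1) or np.any(state0.p < 0):
        raise ValueError("initial h or p outside bounds")
    net = CompiledNetwork(config)
    y0 = net.pack(state0)
    if opts.transient > 0:
        sol = _solve(net, y0, (0.0, opts.transient), opts, t_eval=[opts.transient])
        y0 = sol.y[:, -1]
    t_eval = np.arange(0.0, duration + 0.5 * opts.record_dt, opts.record_dt)
    sol = _solve(net, y0, (0.0, float(t_eval[-1])), opts, t_eval=t_eval)
    return _build_trace(net, sol.t, sol.y, opts)


def threshold_crossings(
    trace: Trace,
    unit: int,
    variable: str = "V",
    level: float = INSPIRATORY_THRESHOLD,
    direction: str = "up",
) -> np.ndarray:
    """Times (ms) where the signal crosses ``level`` in ``direction``.

    Crossing times are refined by monotone cubic (PCHIP) interpolation of
    the recorded samples, giving sub-sample accuracy without event solving.
    """
    if trace.t.size == 0:
        raise ValueError("empty trace")
    sig = {"V": trace.V, "f_out": trace.f_out}[variable][unit - 1]
    return _signal_crossings(trace.t, sig, level, direction)


def _signal_crossings(t, sig, level, direction="up") -> np.ndarray:
    y = np.asarray(sig, float) - level
    s = np.sign(y)
    if direction == "up":
        idx = np.where((s[:-1] <= 0) & (s[1:] > 0))[0]
    elif direction == "down":
        idx = np.where((s[:-1] >= 0) & (s[1:] < 0))[0]
    else:
        raise ValueError("direction must be 'up' or 'down'")
    if idx.size == 0:
        return np.array([])
    interp = PchipInterpolator(t, y, extrapolate=False)
    out = []
    for k in idx:
        a, b = t[k], t[k + 1]
        ya, yb = y[k], y[k + 1]
        if ya == 0.0:
            out.append(a)
            continue
        try:
            out.append(brentq(interp, a, b))
        except ValueError:
            # PCHIP can round a marginal sign change away; fall back to
            # linear interpolation between the bracketing samples.
            out.append(a + (b - a) * (-ya) / (yb - ya))
    return np.asarray(sorted(out))


def _periodicity(trace: Trace) -> Tuple[bool, Optional[np.ndarray]]:
    """Periodic iff >= 4 complete cycles with period CV < 0.1%.

    Cycles are marked by V_1 up-crossings of the inspiratory threshold;
    orbits that never reach -35 mV (small oscillations near a Hopf point)
    fall back to crossings of the mid-range voltage.
    """
    ups = threshold_crossings(trace, 1, "V", INSPIRATORY_THRESHOLD, "up")
    if ups.size < 5:
        v = trace.V[0]
        if np.ptp(v) < 1e-6:
            return False, None
        mid = 0.5 * (v.min() + v.max())
        ups = _signal_crossings(trace.t, v, mid, "up")
        if ups.size < 5:
            return False, None
    periods = np.diff(ups)
    cv = periods.std() / periods.mean()
    return bool(cv < 1e-3), periods


def _is_steady(trace: Trace) -> bool:
    """Max V excursion over the last 5 s below 1e-3 mV for every unit."""
    mask = trace.t >= trace.t[-1] - 5000.0
    return bool(np.all(np.ptp(trace.V[:, mask], axis=1) < 1e-3))


def find_attractor(
    config: NetworkConfig,
    opts: SolverOptions = SolverOptions(),
    state0: Optional[StateVector] = None,
) -> Trace:
    """Integrate to an attractor and return a trace labelled as
    "periodic", "steady" or "undetermined".

    Starts from ``state0`` if given, from a seeded random state if
    ``opts.seed`` is set, and from the standard post-I-active state
    otherwise.  Re-runs with extended transient up to ``opts.max_total``
    total simulated time when neither criterion is met.
    """
    if state0 is None:
        if opts.seed is not None:
            state0 = random_initial_state(config, opts.seed)
        else:
            state0 = default_initial_state(config)
    total = opts.transient + opts.record_window
    trace = integrate(config, state0, opts.record_window, opts)
    while True:
        periodic, periods = _periodicity(trace)
        if periodic:
            trace.attractor_status = "periodic"
            trace.cycle_periods = periods
            return trace
        if _is_steady(trace):
            trace.attractor_status = "steady"
            return trace
        if total >= opts.max_total:
            trace.attractor_status = "undetermined"
            return trace
        # extend: continue from the end of the previous window
        net = CompiledNetwork(config)
        state0 = net.unpack(trace.final_packed)
        ext = replace(opts, transient=opts.record_window,
                      record_window=2 * opts.record_window)
        total += ext.transient + ext.record_window
        trace = integrate(config, state0, ext.record_window, ext)
        opts = ext
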