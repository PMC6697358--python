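"""Analysis pipelines over the network model: isolated-vs-embedded
comparison, (g_NaP, c11) grids with the intrinsic-regime transition curve,
one-parameter drive sweeps, inhibition-block protocols, and the PiCo suite.

Sweeps warm-start each point from the previous point's final state so that
the continuation stays on one attractor branch; grid sweeps recheck a few
random points from a cold start to guard against hysteresis artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import CompiledNetwork, NetworkConfig, SharedParams, StateVector
from .rhythm_metrics import RhythmMetrics, compute_metrics, metrics_row
from .scenarios import default_initial_state, preset
from .simulator import SolverOptions, Trace, find_attractor
from .unit_analysis import (
    classify_isolated,
    continue_transition_curve,
    TransitionCurve,
)

log = logging.getLogger("respcpg.experiments")

# Warm-started sweep points sit close to the attractor already, so a shorter
# transient suffices; find_attractor extends automatically if the periodicity
# check fails.
_SWEEP_OPTS = SolverOptions(transient=60000.0, record_window=30000.0,
                            max_total=300000.0)
_WARM_OPTS = SolverOptions(transient=20000.0, record_window=30000.0,
                           max_total=300000.0)

# Parameters accepted by drive_sweep / rhythm_preserving_range, mapped onto
# config editing operations.
_DRIVE_PARAMS = ("c11", "c12", "c13", "c14", "c15")
_WEIGHT_PARAMS = {"b31": ("b", 3, 1), "a53": ("a", 5, 3)}


def set_parameter(config: NetworkConfig, param: str, value: float) -> NetworkConfig:
    """Return a config with one named sweep parameter replaced."""
    if param in _DRIVE_PARAMS:
        return config.with_c1(int(param[2]), float(value))
    if param in _WEIGHT_PARAMS:
        kind, j, i = _WEIGHT_PARAMS[param]
        return config.with_weight(kind, j, i, float(value))
    if param == "g_NaP1":
        return config.with_unit_param(1, g_NaP=float(value))
    raise ValueError(
        f"unknown sweep parameter {param!r}; expected one of "
        f"{_DRIVE_PARAMS + tuple(_WEIGHT_PARAMS) + ('g_NaP1',)}"
    )


def get_parameter(config: NetworkConfig, param: str) -> float:
    if param in _DRIVE_PARAMS:
        return config.c1.get(int(param[2]), 0.0)
    if param in _WEIGHT_PARAMS:
        kind, j, i = _WEIGHT_PARAMS[param]
        table = config.a if kind == "a" else config.b
        return table.get((j, i), 0.0)
    if param == "g_NaP1":
        return config.unit(1).g_NaP
    raise ValueError(f"unknown sweep parameter {param!r}")


@dataclass
class SweepResult:
    """Rectangular (g_NaP, c11) grid of rhythm metrics with regime labels.

    ``metrics[i][j]`` corresponds to ``g_NaP_grid[i]``, ``c11_grid[j]``.
    ``isolated_regime`` labels the isolated pre-I unit at the same
    parameters; ``rhythm_loss_edges`` lists (i, j) cells that are rhythmic
    but have a non-rhythmic neighbor.
    """

    g_NaP_grid: np.ndarray
    c11_grid: np.ndarray
    metrics: List[List[RhythmMetrics]]
    network_regime: np.ndarray          # (nG, nC) of str
    isolated_regime: np.ndarray         # (nG, nC) of str
    transition_curve: Optional[TransitionCurve]
    rhythm_loss_edges: List[Tuple[int, int]]
    hysteresis_flags: List[Tuple[int, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.g_NaP_grid):
            for j, c in enumerate(self.c11_grid):
                row = metrics_row(self.metrics[i][j], g_NaP=float(g),
                                  c11=float(c))
                row["network_regime"] = self.network_regime[i, j]
                row["isolated_regime"] = self.isolated_regime[i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def rhythmic_mask(self) -> np.ndarray:
        return self.network_regime == "rhythmic"


@dataclass(frozen=True)
class BlockProtocol:
    """Multiplicative scaling of the inhibitory weights onto one group.

    ``preBotC`` scales the inhibition onto units 1 and 2 (b31, b41, b32,
    b42); ``BotC`` scales the inhibition onto units 3 and 4 (b23, b43, b24,
    b34).  Tonic drives are never scaled: the perturbation modeled is
    postsynaptic receptor antagonism.
    """

    target: str  # "preBotC" | "BotC"

    def __post_init__(self):
        if self.target not in ("preBotC", "BotC"):
            raise ValueError("target must be 'preBotC' or 'BotC'")

    @property
    def target_units(self) -> Tuple[int, int]:
        return (1, 2) if self.target == "preBotC" else (3, 4)

    def apply(self, config: NetworkConfig, kappa: float) -> NetworkConfig:
        if not 0.0 < kappa <= 1.0:
            raise ValueError("kappa must lie in (0, 1]")
        if kappa == 1.0:
            return config
        return config.scaled_inhibition(self.target_units, kappa)


@dataclass
class BlockResult:
    protocol: BlockProtocol
    kappa: np.ndarray
    metrics: List[RhythmMetrics]
    kappa_star: float                  # smallest rhythm-preserving kappa
    baseline: RhythmMetrics            # kappa = 1
    boundary_metrics: RhythmMetrics    # at the smallest rhythmic kappa

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, m in zip(self.kappa, self.metrics):
            row = metrics_row(m, kappa=float(k))
            if m.T is not None and self.baseline.T:
                row["T_rel"] = m.T / self.baseline.T
            if m.amplitude is not None and self.baseline.amplitude:
                row["amplitude_rel"] = m.amplitude / self.baseline.amplitude
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def period_ratio(self) -> Optional[float]:
        if self.boundary_metrics.T is None or not self.baseline.T:
            return None
        return self.boundary_metrics.T / self.baseline.T

    @property
    def amplitude_drop_percent(self) -> Optional[float]:
        if self.boundary_metrics.amplitude is None or not self.baseline.amplitude:
            return None
        return 100.0 * (1.0 - self.boundary_metrics.amplitude
                        / self.baseline.amplitude)


def _attractor(
    config: NetworkConfig,
    warm: Optional[np.ndarray],
    opts_cold: SolverOptions = _SWEEP_OPTS,
    opts_warm: SolverOptions = _WARM_OPTS,
) -> Trace:
    """Attractor trace, warm-started from a packed end state when given."""
    if warm is not None:
        net = CompiledNetwork(config)
        if warm.size == net.pack(default_initial_state(config)).size:
            return find_attractor(config, opts_warm, net.unpack(warm))
    return find_attractor(config, opts_cold)


def _log_point(**params) -> None:
    log.info("run %s", " ".join(f"{k}={v:.6g}" if isinstance(v, float)
                                else f"{k}={v}" for k, v in params.items()))


def compare_isolated_embedded(
    c11_grid: Sequence[float],
    config: Optional[NetworkConfig] = None,
    opts: SolverOptions = _SWEEP_OPTS,
) -> pd.DataFrame:
    """Period and amplitude of the isolated pre-I unit versus the full
    network, over a c11 grid.

    Isolated metrics come from the 2-variable pre-I subsystem at frozen
    drive; embedded metrics from the 4-unit network with the same c11.
    Non-rhythmic points carry NaN metrics and a regime label.
    """
    if config is None:
        config = preset("baseline4")
    shared = config.shared
    pre_i = config.unit(1)
    c2 = config.c2.get(1, 0.0)
    rows = []
    warm = None
    for c11 in np.asarray(c11_grid, float):
        _log_point(stage="isolated", c11=float(c11))
        from .model_core import isolated_unit_config

        iso_cfg = isolated_unit_config(pre_i, shared, float(c11) + c2, 0.0)
        iso = find_attractor(iso_cfg, opts)
        iso_m = compute_metrics(iso)
        iso_regime = classify_isolated(pre_i, shared, float(c11) + c2, 0.0, opts)

        _log_point(stage="embedded", c11=float(c11))
        cfg = config.with_c1(1, float(c11))
        tr = _attractor(cfg, warm)
        warm = tr.final_packed
        emb_m = compute_metrics(tr)
        rows.append({
            "c11": float(c11),
            "isolated_regime": iso_regime,
            "isolated_T": iso_m.T, "isolated_amplitude": iso_m.amplitude,
            "embedded_regime": emb_m.regime,
            "embedded_T": emb_m.T, "embedded_amplitude": emb_m.amplitude,
        })
    return pd.DataFrame(rows)


def _isolated_labels(
    config: NetworkConfig,
    g_NaP_grid: np.ndarray,
    c11_grid: np.ndarray,
    curve_low: TransitionCurve,
    curve_high: TransitionCurve,
) -> np.ndarray:
    """Isolated pre-I regime per grid cell from the two Hopf boundary
    curves: quiescent below the lower boundary, oscillatory between,
    tonic above (in c11)."""
    out = np.empty((len(g_NaP_grid), len(c11_grid)), dtype=object)
    for i, g in enumerate(g_NaP_grid):
        lo, hi = curve_low.c11[i], curve_high.c11[i]
        for j, c in enumerate(c11_grid):
            if np.isnan(lo) or np.isnan(hi):
                # no oscillatory interval at this g_NaP: split on the upper
                # boundary if present, otherwise classify by simulation
                if not np.isnan(hi):
                    out[i, j] = "tonic" if c > hi else "quiescent"
                else:
                    out[i, j] = classify_isolated(
                        replace(config.unit(1), g_NaP=float(g)),
                        config.shared, float(c) + config.c2.get(1, 0.0),
                    )
            elif c < lo:
                out[i, j] = "quiescent"
            elif c > hi:
                out[i, j] = "tonic"
            else:
                out[i, j] = "oscillatory"
    return out


def grid_sweep(
    g_NaP_grid: Sequence[float],
    c11_grid: Sequence[float],
    config: Optional[NetworkConfig] = None,
    opts: SolverOptions = _SWEEP_OPTS,
    recheck_points: int = 10,
    recheck_seed: int = 0,
    include_curve: bool = True,
) -> SweepResult:
    """Rhythm metrics of the full network over a (g_NaP,exc, c11) grid.

    Each column (fixed c11) is swept downward in g_NaP with warm starts, so
    the continuation follows the rhythmic branch from the unblocked side, as
    in a progressive-blockade experiment.  The isolated pre-I regime is
    labeled from the two Hopf-boundary curves; rhythmic cells adjacent to
    non-rhythmic ones are reported as rhythm-loss edges.
    """
    if config is None:
        config = preset("baseline4")
    gg = np.asarray(g_NaP_grid, float)
    cc = np.asarray(c11_grid, float)
    order = np.argsort(gg)[::-1]  # descending g_NaP
    metrics: List[List[Optional[RhythmMetrics]]] = [
        [None] * len(cc) for _ in gg
    ]
    regime = np.empty((len(gg), len(cc)), dtype=object)
    for j, c in enumerate(cc):
        warm = None
        for i in order:
            g = gg[i]
            _log_point(stage="grid", g_NaP=float(g), c11=float(c))
            cfg = config.with_unit_param(1, g_NaP=float(g)).with_c1(1, float(c))
            tr = _attractor(cfg, warm)
            warm = tr.final_packed
            m = compute_metrics(tr)
            metrics[i][j] = m
            regime[i, j] = m.regime

    curve_low = curve_high = None
    if include_curve:
        c2 = config.c2.get(1, 0.0)
        curve_high = continue_transition_curve(
            config.unit(1), config.shared, gg, "oscillatory-to-tonic", c2=c2)
        curve_low = continue_transition_curve(
            config.unit(1), config.shared, gg, "quiescent-to-oscillatory", c2=c2)
        isolated = _isolated_labels(config, gg, cc, curve_low, curve_high)
    else:
        isolated = np.full((len(gg), len(cc)), "unlabeled", dtype=object)

    rhythmic = regime == "rhythmic"
    edges = []
    for i in range(len(gg)):
        for j in range(len(cc)):
            if not rhythmic[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < len(gg) and 0 <= jj < len(cc) and not rhythmic[ii, jj]:
                    edges.append((i, j))
                    break

    result = SweepResult(gg, cc, metrics, regime, isolated,
                         curve_high, edges)

    # cold-start recheck against hysteresis on a few random rhythmic cells
    if recheck_points > 0 and rhythmic.any():
        rng = np.random.default_rng(recheck_seed)
        candidates = np.argwhere(rhythmic)
        pick = candidates[rng.choice(len(candidates),
                                     min(recheck_points, len(candidates)),
                                     replace=False)]
        for i, j in pick:
            cfg = config.with_unit_param(1, g_NaP=float(gg[i])) \
                        .with_c1(1, float(cc[j]))
            cold = compute_metrics(find_attractor(cfg, opts))
            warm_m = metrics[i][j]
            if (cold.T is None or warm_m.T is None
                    or abs(cold.T - warm_m.T) > 0.01 * warm_m.T):
                result.hysteresis_flags.append((int(i), int(j)))
                log.warning("hysteresis recheck mismatch at g_NaP=%.3g "
                            "c11=%.3g", gg[i], cc[j])
    return result


def rhythm_preserving_range(
    param: str,
    config: Optional[NetworkConfig] = None,
    search: Tuple[float, float] = (-1.0, 2.0),
    xtol: float = 5e-4,
    opts: SolverOptions = _SWEEP_OPTS,
) -> Tuple[float, float]:
    """(low, high) endpoints of the rhythm-preserving interval of one
    parameter around its baseline value, located by expanding steps plus
    bisection.  Raises if the baseline itself is non-rhythmic.
    """
    if config is None:
        config = preset("baseline4")
    base = get_parameter(config, param)

    def rhythmic(v: float) -> bool:
        cfg = set_parameter(config, param, v)
        return compute_metrics(find_attractor(cfg, opts)).regime == "rhythmic"

    if not rhythmic(base):
        raise ValueError(f"baseline {param}={base} is not rhythmic")

    def bisect(good: float, bad: float) -> float:
        while abs(bad - good) > xtol:
            mid = 0.5 * (good + bad)
            if rhythmic(mid):
                good = mid
            else:
                bad = mid
        return good

    def edge(direction: float, limit: float) -> float:
        step = max(abs(base), 0.05) * 0.25
        good, probe = base, base
        while True:
            probe = probe + direction * step
            if (direction > 0 and probe > limit) or (direction < 0 and probe < limit):
                probe = limit
            if not rhythmic(probe):
                return bisect(good, probe)
            good = probe
            if probe == limit:
                return limit
            step *= 2.0

    return edge(-1.0, search[0]), edge(+1.0, search[1])


def drive_sweep(
    param: str,
    values: Optional[Sequence[float]] = None,
    config: Optional[NetworkConfig] = None,
    n_points: int = 21,
    opts: SolverOptions = _SWEEP_OPTS,
) -> pd.DataFrame:
    """Rhythm metrics against one drive or weight parameter.

    When ``values`` is omitted, the grid spans the rhythm-preserving range
    found by bisection, padded 10% into the non-rhythmic region so that the
    loss boundaries appear in the output.
    """
    if config is None:
        config = preset("baseline4")
    if values is None:
        lo, hi = rhythm_preserving_range(param, config, opts=opts)
        pad = 0.1 * (hi - lo)
        values = np.linspace(lo - pad, hi + pad, n_points)
    rows = []
    warm = None
    for v in np.asarray(values, float):
        _log_point(stage="drive_sweep", param=param, value=float(v))
        cfg = set_parameter(config, param, float(v))
        tr = _attractor(cfg, warm)
        warm = tr.final_packed
        rows.append(metrics_row(compute_metrics(tr), **{param: float(v)}))
    return pd.DataFrame(rows)


def inhibition_block(
    protocol: BlockProtocol,
    kappa_grid: Sequence[float],
    config: Optional[NetworkConfig] = None,
    c11: Optional[float] = None,
    xtol: float = 0.005,
    opts: SolverOptions = _SWEEP_OPTS,
) -> BlockResult:
    """Metrics versus the inhibition scale kappa, plus the loss-of-rhythm
    boundary kappa* located by bisection to ``xtol`` (0.5% default).

    Sweeps kappa downward from 1 with warm starts; the bisection bracket is
    the last rhythmic / first non-rhythmic pair, or (grid minimum, 0) when
    the whole grid stays rhythmic.
    """
    if config is None:
        config = preset("baseline4")
    if c11 is not None:
        config = config.with_c1(1, float(c11))
    kk = np.sort(np.asarray(kappa_grid, float))[::-1]
    if kk[0] > 1.0 + 1e-9 or kk[-1] <= 0.0:
        raise ValueError("kappa grid must lie in (0, 1]")
    kk = np.minimum(kk, 1.0)

    def run(kappa: float, warm: Optional[np.ndarray]) -> Tuple[RhythmMetrics, Trace]:
        _log_point(stage="block", target=protocol.target, kappa=float(kappa))
        tr = _attractor(protocol.apply(config, float(kappa)), warm)
        return compute_metrics(tr), tr

    metrics: List[RhythmMetrics] = []
    warm = None
    last_good: Optional[float] = None
    first_bad: Optional[float] = None
    warm_at_good: Optional[np.ndarray] = None
    boundary: Optional[RhythmMetrics] = None
    for k in kk:
        m, tr = run(k, warm)
        warm = tr.final_packed
        metrics.append(m)
        if m.regime == "rhythmic":
            if first_bad is None:
                last_good = k
                warm_at_good = tr.final_packed
                boundary = m
        elif first_bad is None and last_good is not None:
            first_bad = k
    if last_good is None or boundary is None:
        raise ValueError("no rhythmic point on the kappa grid")

    lo = first_bad if first_bad is not None else 0.0
    hi = last_good
    warm_b = warm_at_good
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if mid <= 0:
            break
        m, tr = run(mid, warm_b)
        if m.regime == "rhythmic":
            hi = mid
            warm_b = tr.final_packed
            boundary = m
        else:
            lo = mid
    kappa_star = hi

    baseline = metrics[0] if kk[0] == 1.0 else run(1.0, None)[0]
    return BlockResult(protocol, kk, metrics, float(kappa_star),
                       baseline, boundary)


def pico_suite(
    config: Optional[NetworkConfig] = None,
    a53_values: Sequence[float] = np.linspace(0.0, 0.4, 9),
    c15_values: Sequence[float] = np.linspace(-0.06, 0.10, 9),
    c13_values: Optional[Sequence[float]] = None,
    opts: SolverOptions = _SWEEP_OPTS,
) -> Dict[str, pd.DataFrame]:
    """PiCo analyses: period versus PiCo-to-post-I drive a53, versus PiCo
    tonic drive c15 (with the isolated-PiCo regime annotated), and the c13
    rhythm range compared with and without PiCo.
    """
    if config is None:
        config = preset("baseline5_pico")
    if not config.include_pico:
        raise ValueError("pico_suite requires a PiCo-containing config")
    out: Dict[str, pd.DataFrame] = {}

    out["a53"] = drive_sweep("a53", a53_values, config, opts=opts)

    c15_rows = []
    warm = None
    pico = config.unit(5)
    c25 = config.c2.get(5, 0.0)
    for v in np.asarray(c15_values, float):
        cfg = set_parameter(config, "c15", float(v))
        tr = _attractor(cfg, warm)
        warm = tr.final_packed
        row = metrics_row(compute_metrics(tr), c15=float(v))
        row["pico_isolated_regime"] = classify_isolated(
            pico, config.shared, float(v) + c25, 0.0)
        c15_rows.append(row)
    out["c15"] = pd.DataFrame(c15_rows)

    if c13_values is None:
        lo5, _ = rhythm_preserving_range("c13", config, search=(0.0, 1.2),
                                         opts=opts)
        lo4, _ = rhythm_preserving_range("c13", preset("baseline4"),
                                         search=(0.0, 1.2), opts=opts)
        c13_values = np.linspace(min(lo5, lo4) * 0.95, 0.7, 9)
        out["c13_range"] = pd.DataFrame(
            [{"network": "with_pico", "c13_low": lo5},
             {"network": "without_pico", "c13_low": lo4}])
    out["c13_with_pico"] = drive_sweep("c13", c13_values, config, opts=opts)
    out["c13_without_pico"] = drive_sweep("c13", c13_values,
                                          preset("baseline4"), opts=opts)
    return out
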