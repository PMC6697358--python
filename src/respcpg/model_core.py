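"""Core model: unit and network parameterization and the ODE right-hand side.

The network consists of non-spiking units representing synchronized neuronal
populations of the respiratory central pattern generator: an excitatory
inspiratory unit (pre-I) in the pre-Boetzinger complex, three inhibitory
units (early-I, post-I, aug-E) and, optionally, an excitatory
post-inspiratory unit (PiCo).  Each unit's membrane potential V obeys

    C dV/dt = -I_NaP - I_K - I_L - I_synI - I_synE

where I_NaP = g_NaP * m_inf(V) * h * (V - E_Na) is a persistent sodium
current whose slow inactivation variable h supplies the relaxation-oscillator
mechanism, I_K is a delayed-rectifier potassium current for excitatory units
(gated by n_inf(V)^4, no extra state) or a strong adaptation current gated by
a dedicated variable p for inhibitory units, and the synaptic currents are
graded functions of presynaptic output sigmoids f_out(V_j):

    I_synI = g_synI * (V - E_synI) * sum_j b_ji * f_out,inh(V_j)
    I_synE = g_synE * (V - E_synE) * [sum_j a_ji * f_out(V_j) + c_1i + c_2i]

Units convention throughout: mV, ms, nS, pF, pA (nS*mV = pA; pA/pF = mV/ms).
All weights and drives (a, b, c) are dimensionless.

By default the inhibitory units' h is held quasi-steady (h := h_inf(V)), so
the 4-unit network is an eight-dimensional dynamical system; a ``dynamic``
h_mode integrates dh/dt for the inhibitory units as well.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
from scipy.special import expit

UNIT_NAMES = ("pre-I", "early-I", "post-I", "aug-E", "PiCo")


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SharedParams:
    """Parameters common to all units.

    Sign conventions: sigma_h > 0 (h_inf decreasing in V, inactivation);
    sigma_m, sigma_n < 0 (activation sigmoids increasing in V).
    """

    C: float = 20.0          # pF
    E_Na: float = 50.0       # mV
    E_K: float = -85.0       # mV
    E_synE: float = 0.0      # mV
    E_synI: float = -75.0    # mV
    theta_h: float = -48.0   # mV
    sigma_h: float = 8.0     # mV
    theta_m: float = -37.0   # mV
    sigma_m: float = -6.0    # mV
    theta_n: float = -29.0   # mV
    sigma_n: float = -4.0    # mV
    epsilon: float = 4000.0  # ms, h time-constant scale
    g_synE: float = 10.0     # nS
    g_synI: float = 60.0     # nS

    def validate(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.g_synE < 0 or self.g_synI < 0:
            raise ValueError("synaptic conductances must be non-negative")
        if self.sigma_h <= 0:
            raise ValueError("sigma_h must be positive (h inactivates with V)")
        if self.sigma_m >= 0 or self.sigma_n >= 0:
            raise ValueError("sigma_m and sigma_n must be negative")


@dataclass(frozen=True)
class UnitParams:
    """Parameters of one unit.

    Inhibitory units carry an adaptation variable p with time constant tau_p
    and drive coefficient d_adapt; their h may be integrated (``dynamic``) or
    substituted as h_inf(V) (``quasi-steady``, the default).
    """

    name: str
    excitatory: bool
    g_NaP: float             # nS
    g_K: float               # nS
    g_L: float               # nS
    E_L: float               # mV
    theta_out: float         # mV
    sigma_out: float         # mV (negative: output increases with V)
    tau_p: Optional[float] = None      # ms, inhibitory only
    d_adapt: Optional[float] = None    # dimensionless, inhibitory only
    h_mode: str = "quasi-steady"       # inhibitory only

    def validate(self) -> None:
        if self.name not in UNIT_NAMES:
            raise ValueError(f"unknown unit name {self.name!r}")
        for g in (self.g_NaP, self.g_K, self.g_L):
            if g < 0:
                raise ValueError("conductances must be non-negative")
        if not self.excitatory:
            if self.tau_p is None or self.tau_p <= 0:
                raise ValueError("inhibitory units need tau_p > 0")
            if self.d_adapt is None or self.d_adapt < 0:
                raise ValueError("inhibitory units need d_adapt >= 0")
            if self.h_mode not in ("quasi-steady", "dynamic"):
                raise ValueError("h_mode must be 'quasi-steady' or 'dynamic'")
        else:
            if self.tau_p is not None or self.d_adapt is not None:
                raise ValueError("excitatory units have no p variable")

    @property
    def has_dynamic_h(self) -> bool:
        return self.excitatory or self.h_mode == "dynamic"


@dataclass(frozen=True)
class NetworkConfig:
    """Complete network parameterization.

    ``units`` are indexed 1..n in the fixed order pre-I, early-I, post-I,
    aug-E and (optionally) PiCo.  ``a[(j, i)]`` is the excitatory weight from
    presynaptic unit j to postsynaptic unit i; ``b[(j, i)]`` the inhibitory
    weight.  ``c1[i]`` (tunable) and ``c2[i]`` (fixed) are tonic drives.
    ``frozen_inh[i]`` adds a constant to unit i's weighted inhibition sum;
    it is used to study a unit under frozen synaptic input.
    """

    units: Tuple[UnitParams, ...]
    shared: SharedParams = field(default_factory=SharedParams)
    a: Mapping[Tuple[int, int], float] = field(default_factory=dict)
    b: Mapping[Tuple[int, int], float] = field(default_factory=dict)
    c1: Mapping[int, float] = field(default_factory=dict)
    c2: Mapping[int, float] = field(default_factory=dict)
    frozen_inh: Mapping[int, float] = field(default_factory=dict)
    include_pico: bool = False

    @property
    def n(self) -> int:
        return len(self.units)

    def unit(self, i: int) -> UnitParams:
        """Unit by 1-based index."""
        if not 1 <= i <= self.n:
            raise KeyError(f"unit index {i} out of range 1..{self.n}")
        return self.units[i - 1]

    def validate(self) -> None:
        self.shared.validate()
        for u in self.units:
            u.validate()
        names = [u.name for u in self.units]
        if names != list(UNIT_NAMES[: self.n]):
            raise ValueError(f"units must be ordered {UNIT_NAMES[:self.n]}, got {names}")
        if self.include_pico != (self.n == 5):
            raise ValueError("include_pico inconsistent with unit count")
        for (j, i), w in self.a.items():
            if not self.unit(j).excitatory:
                raise ValueError(f"a[{j},{i}]: presynaptic unit {j} is not excitatory")
            self.unit(i)
            if w < 0:
                raise ValueError("excitatory weights must be non-negative")
        for (j, i), w in self.b.items():
            if self.unit(j).excitatory:
                raise ValueError(f"b[{j},{i}]: presynaptic unit {j} is not inhibitory")
            self.unit(i)
            if w < 0:
                raise ValueError("inhibitory weights must be non-negative")
        for m in (self.c1, self.c2, self.frozen_inh):
            for i in m:
                self.unit(i)

    # -- convenience constructors for parameter variations ----------------

    def with_c1(self, i: int, value: float) -> "NetworkConfig":
        c1 = dict(self.c1)
        c1[i] = value
        return replace(self, c1=c1)

    def with_weight(self, kind: str, j: int, i: int, value: float) -> "NetworkConfig":
        if kind == "a":
            a = dict(self.a)
            a[(j, i)] = value
            return replace(self, a=a)
        if kind == "b":
            b = dict(self.b)
            b[(j, i)] = value
            return replace(self, b=b)
        raise ValueError("kind must be 'a' or 'b'")

    def with_unit_param(self, i: int, **changes) -> "NetworkConfig":
        units = list(self.units)
        units[i - 1] = replace(units[i - 1], **changes)
        return replace(self, units=tuple(units))

    def scaled_inhibition(self, targets: Iterable[int], kappa: float) -> "NetworkConfig":
        """Scale all inhibitory weights onto the target units by kappa."""
        targets = set(targets)
        b = {ji: (w * kappa if ji[1] in targets else w) for ji, w in self.b.items()}
        return replace(self, b=b)


# --------------------------------------------------------------------------
# Gating, output and current functions
# --------------------------------------------------------------------------

def h_inf(V, shared: SharedParams):
    """Steady-state I_NaP inactivation, 1/(1+exp[(V-theta_h)/sigma_h])."""
    return expit(-(np.asarray(V, float) - shared.theta_h) / shared.sigma_h)


def tau_h(V, shared: SharedParams):
    """I_NaP inactivation time constant, epsilon/cosh[(V-theta_h)/(2 sigma_h)]."""
    return shared.epsilon / np.cosh(
        (np.asarray(V, float) - shared.theta_h) / (2.0 * shared.sigma_h)
    )


def m_inf(V, shared: SharedParams):
    """Instantaneous I_NaP activation."""
    return expit(-(np.asarray(V, float) - shared.theta_m) / shared.sigma_m)


def n_inf(V, shared: SharedParams):
    """Instantaneous delayed-rectifier activation (excitatory units)."""
    return expit(-(np.asarray(V, float) - shared.theta_n) / shared.sigma_n)


def gating(kind: str, V, shared: SharedParams):
    """Dispatch on {'h_inf', 'tau_h', 'm_inf', 'n_inf'}."""
    try:
        fn = {"h_inf": h_inf, "tau_h": tau_h, "m_inf": m_inf, "n_inf": n_inf}[kind]
    except KeyError:
        raise ValueError(f"unknown gating kind {kind!r}") from None
    return fn(V, shared)


def f_out(unit: UnitParams, V):
    """Output sigmoid of a unit, 1/(1+exp[(V-theta_out)/sigma_out]).

    sigma_out < 0 for all units, so output increases with V.
    """
    return expit(-(np.asarray(V, float) - unit.theta_out) / unit.sigma_out)


def intrinsic_currents(unit: UnitParams, V, h, p, shared: SharedParams):
    """(I_NaP, I_K, I_L) in pA at the given state.

    Excitatory units use n_inf(V)^4 for I_K and ignore p; inhibitory units
    use the adaptation gate p.
    """
    I_NaP = unit.g_NaP * m_inf(V, shared) * h * (np.asarray(V, float) - shared.E_Na)
    if unit.excitatory:
        I_K = unit.g_K * n_inf(V, shared) ** 4 * (V - shared.E_K)
    else:
        I_K = unit.g_K * p * (V - shared.E_K)
    I_L = unit.g_L * (V - unit.E_L)
    return I_NaP, I_K, I_L


# --------------------------------------------------------------------------
# State container and packing
# --------------------------------------------------------------------------

@dataclass
class StateVector:
    """Instantaneous state: per-unit V, h and p (length-n arrays).

    ``h`` entries of quasi-steady inhibitory units and ``p`` entries of
    excitatory units are carried for convenience but are not integrated.
    """

    V: np.ndarray
    h: np.ndarray
    p: np.ndarray

    def copy(self) -> "StateVector":
        return StateVector(self.V.copy(), self.h.copy(), self.p.copy())


class CompiledNetwork:
    """Precomputed array form of a NetworkConfig for fast rhs evaluation.

    Packed state layout: [V_1..V_n, h of dynamic-h units in unit order,
    p of inhibitory units in unit order].
    """

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        n = config.n
        sh = config.shared
        self.n = n
        self.exc_mask = np.array([u.excitatory for u in config.units])
        self.inh_mask = ~self.exc_mask
        self.dynh_idx = np.array(
            [k for k, u in enumerate(config.units) if u.has_dynamic_h], dtype=int
        )
        self.p_idx = np.array(
            [k for k, u in enumerate(config.units) if not u.excitatory], dtype=int
        )
        self.g_NaP = np.array([u.g_NaP for u in config.units])
        self.g_K = np.array([u.g_K for u in config.units])
        self.g_L = np.array([u.g_L for u in config.units])
        self.E_L = np.array([u.E_L for u in config.units])
        self.theta_out = np.array([u.theta_out for u in config.units])
        self.sigma_out = np.array([u.sigma_out for u in config.units])
        self.tau_p = np.array(
            [u.tau_p if u.tau_p is not None else 1.0 for u in config.units]
        )
        self.d_adapt = np.array(
            [u.d_adapt if u.d_adapt is not None else 0.0 for u in config.units]
        )
        # weight matrices: W[j, i] = weight from presynaptic j to postsynaptic i
        self.A = np.zeros((n, n))
        for (j, i), w in config.a.items():
            self.A[j - 1, i - 1] = w
        self.B = np.zeros((n, n))
        for (j, i), w in config.b.items():
            self.B[j - 1, i - 1] = w
        self.c_sum = np.array(
            [config.c1.get(i, 0.0) + config.c2.get(i, 0.0) for i in range(1, n + 1)]
        )
        self.frozen_inh = np.array(
            [config.frozen_inh.get(i, 0.0) for i in range(1, n + 1)]
        )
        self.shared = sh
        self.n_states = n + len(self.dynh_idx) + len(self.p_idx)

    # -- packing -----------------------------------------------------------

    def pack(self, state: StateVector) -> np.ndarray:
        return np.concatenate(
            [state.V, state.h[self.dynh_idx], state.p[self.p_idx]]
        )

    def unpack(self, y: np.ndarray) -> StateVector:
        n, nd = self.n, len(self.dynh_idx)
        V = np.asarray(y[:n], float)
        h = h_inf(V, self.shared)
        h[self.dynh_idx] = y[n : n + nd]
        p = np.zeros(n)
        p[self.p_idx] = y[n + nd :]
        return StateVector(V, h, p)

    # -- pieces ------------------------------------------------------------

    def outputs(self, V: np.ndarray) -> np.ndarray:
        """Per-unit output sigmoids f_out(V_i); works on (n,) or (n, T)."""
        th = self.theta_out
        sg = self.sigma_out
        if V.ndim == 2:
            th = th[:, None]
            sg = sg[:, None]
        return expit(-(V - th) / sg)

    def sums(self, V: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(inh_sum, exc_sum) per unit: weighted presynaptic outputs + drives.

        inh_sum_i = sum_j b_ji f_out,inh(V_j) [+ frozen term];
        exc_sum_i = sum_j a_ji f_out(V_j) + c_1i + c_2i.
        """
        fo = self.outputs(V)
        f_inh = np.where(
            self.inh_mask[:, None] if V.ndim == 2 else self.inh_mask, fo, 0.0
        )
        f_exc = np.where(
            self.exc_mask[:, None] if V.ndim == 2 else self.exc_mask, fo, 0.0
        )
        if V.ndim == 2:
            inh = self.B.T @ f_inh + self.frozen_inh[:, None]
            exc = self.A.T @ f_exc + self.c_sum[:, None]
        else:
            inh = self.B.T @ f_inh + self.frozen_inh
            exc = self.A.T @ f_exc + self.c_sum
        return inh, exc

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Packed right-hand side; autonomous (t is unused)."""
        sh = self.shared
        n, nd = self.n, len(self.dynh_idx)
        V = y[:n]
        hinf = expit(-(V - sh.theta_h) / sh.sigma_h)
        h = hinf.copy()
        h[self.dynh_idx] = y[n : n + nd]
        p = np.zeros(n)
        p[self.p_idx] = y[n + nd :]

        fo = expit(-(V - self.theta_out) / self.sigma_out)
        f_inh = np.where(self.inh_mask, fo, 0.0)
        f_exc = np.where(self.exc_mask, fo, 0.0)
        inh_sum = self.B.T @ f_inh + self.frozen_inh
        exc_sum = self.A.T @ f_exc + self.c_sum

        m = expit(-(V - sh.theta_m) / sh.sigma_m)
        I_NaP = self.g_NaP * m * h * (V - sh.E_Na)
        nn = expit(-(V - sh.theta_n) / sh.sigma_n)
        I_K = np.where(
            self.exc_mask,
            self.g_K * nn ** 4 * (V - sh.E_K),
            self.g_K * p * (V - sh.E_K),
        )
        I_L = self.g_L * (V - self.E_L)
        I_synI = sh.g_synI * (V - sh.E_synI) * inh_sum
        I_synE = sh.g_synE * (V - sh.E_synE) * exc_sum

        dV = -(I_NaP + I_K + I_L + I_synI + I_synE) / sh.C
        tau = sh.epsilon / np.cosh((V - sh.theta_h) / (2.0 * sh.sigma_h))
        dh = (hinf - h) / tau
        dp = (self.d_adapt * f_inh - p) / self.tau_p
        return np.concatenate([dV, dh[self.dynh_idx], dp[self.p_idx]])


def make_rhs(config: NetworkConfig) -> CompiledNetwork:
    return CompiledNetwork(config)


def synaptic_inputs(
    config: NetworkConfig, state: StateVector, i: int
) -> Tuple[float, float, float, float]:
    """(inh_sum, exc_sum, I_synI, I_synE) for unit i (1-based).

    inh_sum is the dimensionless "total level of inhibition" received by the
    unit; the currents multiply the sums by conductance and driving force.
    """
    u = config.unit(i)  # raises KeyError on bad index
    net = CompiledNetwork(config)
    inh, exc = net.sums(np.asarray(state.V, float))
    V_i = state.V[i - 1]
    sh = config.shared
    I_synI = sh.g_synI * (V_i - sh.E_synI) * inh[i - 1]
    I_synE = sh.g_synE * (V_i - sh.E_synE) * exc[i - 1]
    return float(inh[i - 1]), float(exc[i - 1]), float(I_synI), float(I_synE)


def rhs(config: NetworkConfig, state: StateVector, t: float = 0.0) -> StateVector:
    """Time derivative of the state (dV in mV/ms; dh, dp per ms).

    Entries of non-integrated variables (quasi-steady h, excitatory p) are
    returned as 0.
    """
    net = CompiledNetwork(config)
    y = net.pack(state)
    if len(y) != net.n_states:
        raise ValueError("state dimension mismatch")
    dy = net.rhs(t, y)
    n, nd = net.n, len(net.dynh_idx)
    dV = dy[:n]
    dh = np.zeros(n)
    dh[net.dynh_idx] = dy[n : n + nd]
    dp = np.zeros(n)
    dp[net.p_idx] = dy[n + nd :]
    return StateVector(dV, dh, dp)


# --------------------------------------------------------------------------
# Isolated-unit helpers
# --------------------------------------------------------------------------

def isolated_unit_config(
    unit: UnitParams,
    shared: SharedParams,
    exc_sum: float,
    inh_sum: float = 0.0,
) -> NetworkConfig:
    """One-unit network with frozen synaptic sums treated as parameters."""
    return NetworkConfig(
        units=(unit,),
        shared=shared,
        c1={1: exc_sum},
        frozen_inh={1: inh_sum},
    )


def v_nullcline_h(
    unit: UnitParams,
    shared: SharedParams,
    exc_sum: float,
    inh_sum: float,
    V,
):
    """h solving dV/dt = 0 at frozen synaptic sums (closed form; h enters
    dV/dt linearly through I_NaP).  Excitatory (2-variable) units only."""
    if not unit.excitatory:
        raise ValueError("closed-form nullcline applies to excitatory units")
    if unit.g_NaP <= 0:
        raise ValueError("g_NaP must be positive for the h-form of the nullcline")
    V = np.asarray(V, float)
    R = (
        unit.g_K * n_inf(V, shared) ** 4 * (V - shared.E_K)
        + unit.g_L * (V - unit.E_L)
        + shared.g_synE * (V - shared.E_synE) * exc_sum
        + shared.g_synI * (V - shared.E_synI) * inh_sum
    )
    D = unit.g_NaP * m_inf(V, shared) * (V - shared.E_Na)
    return -R / D


def v_nullcline_dh_dV(
    unit: UnitParams,
    shared: SharedParams,
    exc_sum: float,
    inh_sum: float,
    V,
):
    """Analytic derivative of the closed-form nullcline h(V)."""
    V = np.asarray(V, float)
    nn = n_inf(V, shared)
    dn = nn * (1.0 - nn) * (-1.0 / shared.sigma_n)
    R = (
        unit.g_K * nn ** 4 * (V - shared.E_K)
        + unit.g_L * (V - unit.E_L)
        + shared.g_synE * (V - shared.E_synE) * exc_sum
        + shared.g_synI * (V - shared.E_synI) * inh_sum
    )
    dR = (
        unit.g_K * (4.0 * nn ** 3 * dn * (V - shared.E_K) + nn ** 4)
        + unit.g_L
        + shared.g_synE * exc_sum
        + shared.g_synI * inh_sum
    )
    m = m_inf(V, shared)
    dm = m * (1.0 - m) * (-1.0 / shared.sigma_m)
    D = unit.g_NaP * m * (V - shared.E_Na)
    dD = unit.g_NaP * (dm * (V - shared.E_Na) + m)
    return -(dR * D - R * dD) / D ** 2


# --------------------------------------------------------------------------
# Config file serialization (key-value sections, round-trip exact)
# --------------------------------------------------------------------------

_UNIT_FIELDS = (
    "excitatory", "g_NaP", "g_K", "g_L", "E_L", "theta_out", "sigma_out",
    "tau_p", "d_adapt", "h_mode",
)
_SHARED_FIELDS = (
    "C", "E_Na", "E_K", "E_synE", "E_synI", "theta_h", "sigma_h",
    "theta_m", "sigma_m", "theta_n", "sigma_n", "epsilon", "g_synE", "g_synI",
)


def config_to_text(config: NetworkConfig) -> str:
    """Serialize a NetworkConfig to a structured key-value text format."""
    cp = configparser.ConfigParser()
    cp.optionxform = str
    cp["network"] = {
        "units": ", ".join(u.name for u in config.units),
        "include_pico": str(config.include_pico),
    }
    cp["shared"] = {k: repr(getattr(config.shared, k)) for k in _SHARED_FIELDS}
    for u in config.units:
        sec = f"unit.{u.name}"
        cp[sec] = {}
        for k in _UNIT_FIELDS:
            v = getattr(u, k)
            if v is None:
                continue
            cp[sec][k] = repr(v) if isinstance(v, float) else str(v)
    cp["excitatory_weights"] = {
        f"a_{j}_{i}": repr(w) for (j, i), w in sorted(config.a.items())
    }
    cp["inhibitory_weights"] = {
        f"b_{j}_{i}": repr(w) for (j, i), w in sorted(config.b.items())
    }
    cp["drives"] = {}
    for i, v in sorted(config.c1.items()):
        cp["drives"][f"c1_{i}"] = repr(v)
    for i, v in sorted(config.c2.items()):
        cp["drives"][f"c2_{i}"] = repr(v)
    if config.frozen_inh:
        cp["frozen_inhibition"] = {
            f"inh_{i}": repr(v) for i, v in sorted(config.frozen_inh.items())
        }
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def config_from_text(text: str) -> NetworkConfig:
    cp = configparser.ConfigParser()
    cp.optionxform = str
    cp.read_string(text)
    shared = SharedParams(**{k: float(cp["shared"][k]) for k in _SHARED_FIELDS})
    names = [s.strip() for s in cp["network"]["units"].split(",")]
    units = []
    for name in names:
        sec = cp[f"unit.{name}"]
        kw = dict(name=name, excitatory=sec.getboolean("excitatory"))
        for k in ("g_NaP", "g_K", "g_L", "E_L", "theta_out", "sigma_out"):
            kw[k] = float(sec[k])
        if not kw["excitatory"]:
            kw["tau_p"] = float(sec["tau_p"])
            kw["d_adapt"] = float(sec["d_adapt"])
            kw["h_mode"] = sec.get("h_mode", "quasi-steady")
        units.append(UnitParams(**kw))

    def _pairs(section: str, prefix: str) -> Dict[Tuple[int, int], float]:
        out: Dict[Tuple[int, int], float] = {}
        if section in cp:
            for key, val in cp[section].items():
                _, j, i = key.split("_")
                out[(int(j), int(i))] = float(val)
        return out

    c1: Dict[int, float] = {}
    c2: Dict[int, float] = {}
    if "drives" in cp:
        for key, val in cp["drives"].items():
            which, i = key.split("_")
            (c1 if which == "c1" else c2)[int(i)] = float(val)
    frozen: Dict[int, float] = {}
    if "frozen_inhibition" in cp:
        for key, val in cp["frozen_inhibition"].items():
            frozen[int(key.split("_")[1])] = float(val)
    cfg = NetworkConfig(
        units=tuple(units),
        shared=shared,
        a=_pairs("excitatory_weights", "a"),
        b=_pairs("inhibitory_weights", "b"),
        c1=c1,
        c2=c2,
        frozen_inh=frozen,
        include_pico=cp["network"].getboolean("include_pico"),
    )
    cfg.validate()
    return cfg


def save_config(config: NetworkConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(config_to_text(config))


def load_config(path) -> NetworkConfig:
    with open(path) as fh:
        return config_from_text(fh.read())
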