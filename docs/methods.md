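# Methods

## Model

Each unit `i` is an activity-based reduction of a neural population.
Voltage obeys

```
C dV_i/dt = -I_NaP,i - I_K,i - I_L,i - I_synI,i - I_synE,i
```

with

```
I_NaP,i = g_NaP,i m_inf(V_i) h_i (V_i - E_Na)
I_K,i   = g_K,i n_inf(V_i)^4 (V_i - E_K)     (excitatory units)
I_K,i   = g_K,i p_i (V_i - E_K)              (inhibitory units)
I_L,i   = g_L,i (V_i - E_L,i)
I_synI,i = g_synI (V_i - E_synI) * [ sum_j b_ji f_out(V_j) ]   (j inhibitory)
I_synE,i = g_synE (V_i - E_synE) * [ sum_j a_ji f_out(V_j) + c_1i + c_2i ]
```

Sigmoids: `x_inf(V) = 1/(1+exp((V-theta_x)/sigma_x))` for `x in {m, n, h}`
and for the output `f_out` (all `sigma_out < 0`, so output rises with `V`).
Slow variables:

```
dh_i/dt = (h_inf(V_i) - h_i) / tau_h(V_i),  tau_h = epsilon / cosh((V-theta_h)/(2 sigma_h))
dp_i/dt = (d_i f_out(V_i) - p_i) / tau_p,i            (inhibitory units)
```

Inhibitory-unit `h` is quasi-steady by default (`h := h_inf(V)`), making the
4-unit network 8-dimensional (4 V, 1 h for pre-I... plus 3 p; the 5-unit
network is 10-dimensional).  A `h_mode="dynamic"` switch integrates those
`h` as well; the baseline attractor changes by < 0.5% in period.

The dimensionless quantity `inh_i = sum_j b_ji f_out(V_j)` is reported as
the "total inhibition" received by unit `i`; the current multiplies it by
`g_synI (V_i - E_synI)`.

Units: mV, ms, nS, pF, pA.

### Baseline parameters

Shared: `C = 20 pF`, `E_Na = 50`, `E_K = -85`, `E_synE = 0`, `E_synI = -75`
mV; `theta_h = -48`, `sigma_h = 8`, `theta_m = -37`, `sigma_m = -6`,
`theta_n = -29`, `sigma_n = -4` mV; `epsilon = 4000 ms`; `g_synE = 10`,
`g_synI = 60` nS.

Excitatory units (pre-I, PiCo): `g_NaP = 4.5`, `g_K = 1`, `g_L = 3` nS,
`E_L = -65 mV`; output `theta_out = -32, sigma_out = -8` (pre-I),
`-20, -12` (PiCo).

Inhibitory units (early-I, post-I, aug-E): `g_NaP = 0.25`, `g_K = 10`,
`g_L = 3.25` nS, `E_L = -60 mV`, `theta_out = -30`, `sigma_out = -4`,
`tau_p = 2000 / 1500 / 2000 ms`.  The adaptation coefficient `d_i` is set
to 1 (no value is fixed by the model definition; it only rescales `p`
against `g_K`).

Weights and drives are stored in the presets (`respcpg presets show
baseline4`) and exported in `src/respcpg/data/*.cfg`.  The standard tunings
are `c11 = -0.03` (intrinsically oscillatory pre-I) and `c11 = 0.01`
(intrinsically tonic).  With PiCo: `a53 = 0.1`, `b43` drops from 0.05 to
0.02, `c15 = 0.045`, `c25 = 0` (not otherwise specified).

## Numerics

- LSODA (`scipy.integrate.solve_ivp`) with `rtol = 1e-8`, `atol = 1e-10`,
  `max_step = 10 ms`.  The system is slow-fast (V relaxes in ~5 ms, h in
  seconds); the period is stable to < 0.1% under 100x looser tolerances.
- Attractors: 60 s transient discarded, 40 s recorded; "periodic" requires
  >= 4 complete cycles with period CV < 0.1%, "steady" requires V
  peak-to-peak < 1e-3 mV over the last 5 s; otherwise the run is extended
  up to 400 s total.
- The inspiratory phase is delimited by V_1 crossings of -35 mV, refined by
  monotone cubic interpolation.  Orbits too small to reach -35 mV (low
  g_NaP, near-Hopf) fall back to mid-range V_1 crossings for both the
  periodicity check and the metrics.
- Regime labels: "rhythmic" = periodic with pre-I output excursion > 0.05;
  steady states split at output 0.15 into tonic/quiescent (isolated pre-I
  steady outputs are <= 0.08 on the quiescent side and >= 0.27 on the tonic
  side, so the label is insensitive to the exact split).
- Three-phase validity per cycle: pre-I onset before or with early-I
  (50 ms tolerance), then post-I, then aug-E onsets (each unit's output
  up-crossing of half its cycle range, ignoring dwells < 25 ms, which
  discards aug-E's few-millisecond transient at the
  inspiratory-to-expiratory transition), and aug-E output > post-I output
  at the end of expiration.

## Analyses

- **Isolated unit.** The 2-variable pre-I subsystem at frozen input sums.
  Fixed points by bracketed root finding on a 2000-point V scan (the
  nullcline `h(V)` is closed-form since `h` enters linearly); stability
  from the analytic 2x2 Jacobian.  Hopf points solve `trace(J) = 0` with
  `det(J) > 0`.  Simulated oscillation boundaries bisect regime changes to
  1e-4 in `c11`; because the lower Hopf has a canard explosion and the
  upper one is supercritical, boundary detection keys on orbit existence
  (V peak-to-peak > 0.5 mV), not output excursion.  Linear and simulated
  boundaries agree to ~5e-4.
- **Phase-plane geometry.** The curve of left knees `h_LK(inh)` tracks the
  lower fold of the V-nullcline against frozen inhibition; the escape event
  of a cycle is the first up-crossing of `h(t) - h_LK(inh(t))` through zero
  inside the expiratory window, linearly refined.
- **Sweeps.** Warm-started continuation (each point starts from the
  previous final state), with cold-start rechecks at random points flagged
  on mismatch.  Grid sweeps continue each `c11` column downward in `g_NaP`
  from the unblocked side because the low-`g_NaP` region is bistable
  (rhythmic orbit coexisting with quiescence); this matches a
  progressive-blockade protocol.
- **Inhibition block.** Multiplicative scaling `kappa` of the inhibitory
  weights onto the target group (preBötC: b31, b41, b32, b42; BötC: b23,
  b43, b24, b34); drives are never scaled (the perturbation modeled is
  postsynaptic antagonism).  The loss-of-rhythm boundary `kappa*` is
  bisected to 0.5%.

## Reference-value discrepancies

Two external reference values do not reproduce; both are documented as
expected failures in `tests/test_acceptance.py`:

1. **Escape inhibition, oscillatory tuning (reference 0.09).**  The
   computed value is 0.0103 (both h modes).  The reference is geometrically
   impossible for this model: `h_LK(0.09) = 5.44` and `h_LK(0.03) = 1.37`,
   both above the physical bound `h <= 1`, so no trajectory can cross the
   left-knee curve at inhibition 0.09.  The companion reference values
   recorded at the same instant — inhibition to post-I 0.0525 and to aug-E
   0.0542 — are reproduced here (0.0574 / 0.0572) and, propagated through
   the printed weights (`inh_1 = 0.125 f_3 + 0.015 f_4`), imply escape
   inhibition ~0.01-0.015, consistent with the computed value.  The
   reference figure is most plausibly a typo for ~0.009-0.010.  The tonic
   counterpart (reference 0.012) reproduces at 0.0146.
2. **Maximum period on the c11 sweep (reference "above 7 s").**  The
   computed maximum is 6.97 s on the warm-continued rhythmic branch at
   `c11 = -0.0384` (6.76 s from cold starts), i.e. "about 7 s" but not
   strictly above it.

## Limitations

- Activity-based units: no spiking, no population heterogeneity.
- The `d_i = 1` convention and quasi-steady inhibitory `h` are defaults,
  not fitted; both are exposed as parameters.
- Sweep grid resolutions are configurable defaults; published axis limits
  for the sweeps are not fully specified anywhere, so loss boundaries are
  located by bisection rather than read off a fixed grid.
- The rhythm-loss boundary under blocks can be hysteretic; `kappa*` refers
  to the warm-continued rhythmic branch.
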