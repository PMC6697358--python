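# respcpg

A reduced model of the mammalian respiratory central pattern generator
(CPG) and the analysis toolkit around it: rhythm metrics, isolated-unit
bifurcation structure, phase-plane escape geometry, and the parameter-sweep
experiments that show how network interactions mask the intrinsic dynamics
of the inspiratory pacemaker population.

## The model

Four (optionally five) neural populations are each reduced to an
activity-based unit with a persistent-sodium current `I_NaP`:

| unit | region | role | type |
|---|---|---|---|
| 1 pre-I | preBötC | inspiratory rhythm generator | excitatory |
| 2 early-I | preBötC | early-inspiratory | inhibitory |
| 3 post-I | BötC | post-inspiratory | inhibitory |
| 4 aug-E | BötC | augmenting-expiratory | inhibitory |
| 5 PiCo (optional) | PiCo | post-inspiratory complex | excitatory |

Each unit carries a voltage `V` with `I_NaP`, a potassium current, a leak
and synaptic currents.  The slow variables are the `I_NaP` inactivation `h`
(time constant `epsilon = 4 s`) for excitatory units and an adaptation gate
`p` (`tau_p = 1.5-2 s`) for inhibitory units; inhibitory-unit `h` is
quasi-steady by default, giving an 8-dimensional system for the 4-unit
network.  Output is a sigmoid `f_out(V)`; the "total inhibition" received
by a unit is the dimensionless weighted sum of presynaptic inhibitory
outputs.

The pre-I unit is a conditional pacemaker: depending on its tonic drive
`c11` it is intrinsically quiescent, oscillatory (`c11` in about
`(-0.060, -0.011)`, bounded by Andronov-Hopf bifurcations with a canard
explosion at the lower end), or tonically active.  Embedded in the network,
all of these tunings produce an essentially identical three-phase
respiratory rhythm — inspiration, post-inspiration, late expiration — in
which inspiratory onset occurs when slowly decaying inhibition releases the
pre-I unit across the left knee of its voltage nullcline ("escape").

## Worked example

```python
from respcpg import preset, find_attractor, compute_metrics

trace = find_attractor(preset("oscillatory"))   # c11 = -0.03
m = compute_metrics(trace)
print(f"T = {m.T:.3f} s, T_I = {m.T_I:.3f} s, T_E = {m.T_E:.3f} s, "
      f"amplitude = {m.amplitude:.3f}, three-phase: {m.three_phase_valid}")
# T = 5.267 s, T_I = 1.162 s, T_E = 4.105 s, amplitude = 0.829, three-phase: True

print(f"peak inhibition to pre-I: {trace.inh_sum[0].max():.4f}")
# peak inhibition to pre-I: 0.0941
```

The escape geometry:

```python
from respcpg.model_core import SharedParams
from respcpg.phase_geometry import knee_curve, project_escape

pre_i = trace.config.unit(1)
knees = knee_curve(pre_i, SharedParams(), exc_sum=-0.03 + 0.095)
events, inh_path, h_path = project_escape(trace, 1, knees)
print(f"escape at inhibition {events[0].inh_sum:.4f}, h = {events[0].h:.4f}")
# escape at inhibition 0.0103, h = 0.6083
```

Same things from the command line:

```
respcpg presets list
respcpg simulate --preset tonic --out trace.csv
respcpg sweep c11 --lo -0.038 --hi 0.0 --n 20 --out c11_sweep.csv
respcpg grid --gnap 1.7 4.1 0.1 --c11-grid -0.006 0.004 0.002 --out grid.csv
respcpg block BotC --c11 0.01 --out block.csv
respcpg bifurcate --out bif.csv
respcpg phaseplane --preset oscillatory --out-prefix pp/osc
```

## Key results reproduced

- Isolated pre-I oscillatory interval `c11` in `(-0.0596, -0.0114)`, with
  the linear Hopf condition agreeing with long-simulation bisection.
- Masking: embedded period/amplitude vary smoothly across the intrinsic
  transition curve; the network rhythm persists where the isolated unit is
  quiescent or tonic.
- Escape mechanism: cycle-by-cycle crossing of the left-knee curve in the
  (inhibition, h) plane; peak/escape inhibition levels on the baseline
  attractors.
- Riluzole analogue: over `c11 in [-0.006, 0.004]`, `g_NaP in [1.7, 4.1]`
  the pre-I amplitude falls from 0.75 to 0.20 while the period stays within
  ~20%.
- Inhibition block: BötC inhibition can fall to ~65% of baseline under the
  tonic tuning but only ~93% under the oscillatory one; preBötC block
  reduces amplitude ~37% at the rhythm boundary.

See `docs/methods.md` for model equations, numerical choices, and known
discrepancies of reference values.

## Reproduction

```
python -m pytest tests/                      # unit + property + acceptance
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion; two
expected-failure tests document reference values that do not reproduce
(see `docs/methods.md`).  The acceptance script recomputes every target
from scratch and writes `{"t1": {"value": ..., "n": ...}, ...}`.
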