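# ecogame

An eco-epidemiological predator–prey model with evolutionary game dynamics:
susceptible prey **S**, infected prey **I**, and a predator **P** whose
recruitment is damped at low density by a weak Allee effect, coupled to a
behavioural strategy level **x ∈ [0, 1]** that measures how strongly the prey
population adopts disease-control behaviour and (optionally) evolves by
replicator dynamics.

```
dS/dt = [ r − bS − cI − β(x)·I/(a+S) − α₁P/(σ+S) ] · S
dI/dt = [ β(x)·S/(a+S) − α₂P/(d+I) − μ ] · I
dP/dt = [ (c₁α₁S/(σ+S) + c₂α₂I/(d+I)) · P/(θ+P) − m ] · P
dx/dt = x(1−x) · ( −C_S·S + I + C_P·P )        (dynamic-strategy mode)
```

with transmission `β(x) = max(β₀(1 − e·x), 0)` and the Allee factor
`P/(θ+P)` defined to be exactly 1 when `θ = 0`.

The package provides:

- **model core** — validated parameter/state containers and the vector field
  (`ModelParameters`, `StateVector`, `ode_rhs`),
- **simulation engine** — adaptive (scipy RK45) and fixed-step RK4
  integrators with invariant enforcement, extinction detection, and
  bit-exact trajectory CSV round trips (`simulate`, `detect_extinction`),
- **equilibrium & stability analysis** — multistart Newton equilibrium
  location, analytic Jacobians, eigenvalue classification
  (`find_equilibria`, `coexistence_equilibrium`, `jacobian`),
- **bifurcation analysis** — attractor classification (steady point / limit
  cycle / period-doubled / chaotic / extinctions), Benettin Lyapunov
  exponents, 1-D/2-D parameter scans, and Hopf-threshold bisection
  (`classify_attractor`, `scan_1d`, `scan_2d`, `hopf_threshold`),
- **scenario presets** — the named study scenarios `fig1` … `fig10`
  (`get_preset`, `list_presets`),
- **CLI** — `ecogame simulate | equilibria | scan1d | scan2d | hopf |
  report | presets`, every run writing a reproducibility manifest.

## Worked example

```python
from ecogame import (SolverConfig, classify_attractor, coexistence_equilibrium,
                     get_preset, hopf_threshold, simulate)

preset = get_preset("fig3")                 # beta0=0.95, x fixed at 0
solver = SolverConfig(method="fixed-step-RK4", dt_fixed=0.01,
                      t_end=6000.0, transient=3000.0, n_report=6001)

for theta in (0.0, 0.3):
    params = preset.params.with_updates(theta=theta)
    summary = classify_attractor(simulate(params, preset.state0, solver))
    print(f"theta={theta}: regime={summary.regime}, "
          f"extinct={summary.extinct}, "
          f"S amplitude={summary.amplitude('S'):.3f}")

eq = coexistence_equilibrium(preset.params)
print(f"coexistence equilibrium: S*={eq.state.S:.4f}, I*={eq.state.I:.4f}, "
      f"P*={eq.state.P:.4f} ({eq.label})")

x_crit = hopf_threshold(preset.params, "x", bracket=(0.2, 0.8))
print(f"stability flip of the coexistence state at x = {x_crit:.6f}")
```

Output:

```
theta=0.0: regime=period_doubled, extinct=(), S amplitude=0.703
theta=0.3: regime=extinct_P, extinct=('P',), S amplitude=0.479
coexistence equilibrium: S*=0.9170, I*=0.1075, P*=3.4053 (saddle)
stability flip of the coexistence state at x = 0.362376
```

Without an Allee effect all three populations coexist on a cycle; θ=0.3
starves the predator while both prey classes keep oscillating; and raising
the fixed strategy level stabilises the coexistence equilibrium once
x ≳ 0.3624 (equivalently, once the effective transmission β₀(1−x) drops
below ≈ 0.6057).

The same from the command line:

```bash
$ ecogame hopf --preset fig5 --param x --bracket 0.2,0.8
critical x = 0.3623756409

$ ecogame scan1d --preset fig1 --param beta0 --from 0.5 --to 0.95 --n 10 \
      --out scan.csv
$ ecogame report scan.csv --out report.md --plot diagram.png
```

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end scientific claims. Three of
them fail by design and are kept failing deliberately: under the documented
parameter set the package finds the stability flip at x ≈ 0.362 (not 0.42),
finds the predator rather than the infection driven extinct by a strong
Allee effect at β₀ = 0.95, and finds predator survival at *high* (not low)
susceptible-control cost in the (C_S, e) phase diagram. Each computation is
cross-checked by two independent methods inside the failing test itself; see
`docs/methods.md` (Limitations) for the mechanism behind each divergence.
The unit suites (`test_model_core`, `test_simulate`, `test_equilibria`,
`test_bifurcation`, `test_presets`, `test_cli`) are all green.

## Layout

```
src/ecogame/        params, model, _kernels, simulate, equilibria,
                    bifurcation, presets, cli
tests/              unit suites + test_acceptance.py
scripts/acceptance.py
docs/methods.md     models, numerical choices, limitations
```
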