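# Methods

## Model

State: susceptible prey S, infected prey I, predator P (densities ≥ 0) and a
strategy level x ∈ [0, 1], the fraction-like intensity of disease-control
behaviour in the prey population.

```
dS/dt = [ r − bS − cI − β(x)·I/(a+S) − α₁P/(σ+S) ] · S
dI/dt = [ β(x)·S/(a+S) − α₂P/(d+I) − μ ] · I
dP/dt = [ (c₁α₁S/(σ+S) + c₂α₂I/(d+I)) · P/(θ+P) − m ] · P
dx/dt = x(1−x) · G(S, I, P),   G = −C_S·S + I + C_P·P
```

Modelling conventions adopted by this package:

- **Transmission** `β(x) = β₀(1 − e·x)`, clamped at 0 (a warning is logged
  when the clamp engages). `e·x = 0` returns `β₀` exactly.
- **Allee factor** `P/(θ+P)` multiplies predator recruitment only (a weak
  Allee effect: growth is damped, never negative, at low density). `θ = 0`
  is defined to give factor 1 exactly, including at `P = 0`, so the
  Allee-free model is recovered without a removable singularity.
- **Replicator payoff** `G = −C_S·S + I + C_P·P`: disease-control behaviour
  is costly in proportion to the healthy prey stock and favoured by
  infection pressure and predation pressure. `G` is isolated in
  `ecogame.model.payoff_gain` so alternative payoff readings can be swapped
  in one place.
- In fixed-strategy mode (`x_mode="fixed"`) the fourth equation is replaced
  by `dx/dt = 0`; x acts as a constant that only modulates β.
- `x = 0` and `x = 1` are replicator fixed points; all coordinate faces
  (S=0, I=0, P=0) are flow-invariant. These are enforced exactly by the
  vector field and tested as invariants.

## Parameters

Default constants shared by all registered scenarios (dimensionless time in
prey-growth units; densities in arbitrary biomass units):

| name | default | meaning |
|---|---|---|
| r | 1.0 | susceptible prey intrinsic growth rate |
| b | 1.0 | intra-class competition (carrying capacity K = r/b = 1) |
| c | 0.01 | effect of infected on susceptible prey |
| β₀ | scenario | baseline transmission rate |
| e | 1.0 | strategy effectiveness in β(x) = β₀(1 − e·x) |
| a | 0.3636 | incidence half-saturation |
| α₁, α₂ | 0.01, 0.05 | predator attack rates on S and I |
| σ, d | 15.0, 0.5 | Holling type-II half-saturations for S and I |
| c₁, c₂ | 2.0, 1.0 | conversion efficacies |
| μ | 0.4 | infected prey death rate |
| m | 0.01 | predator death rate |
| θ | scenario | Allee parameter (0 = Allee-free) |
| C_S, C_P | scenario | payoff weights of S and P |

Initial state (S, I, P) = (0.99, 0.01, 0.01) for every scenario; x(0) = 0.5
for dynamic-strategy runs, x fixed at the scenario's value otherwise.
Validation: a, σ, d strictly positive (denominators); all rates finite and
non-negative; θ ≥ 0.

## Numerical integration

- **Adaptive** (default): scipy `solve_ivp` RK45, rtol 1e-8 / atol 1e-10.
- **Fixed-step RK4**: classical RK4, default dt 1e-3 (the scan default uses
  dt 0.005–0.01), JIT-compiled with numba when available. Used for long
  horizons and as an independent cross-check: both schemes must agree to
  1e-5 relative at t = 200 (tested).
- Output is sampled on a uniform grid of `n_report` points regardless of
  internal steps; peak detection downstream relies on this.
- Components below −atol are clamped to 0 (x to [0, 1]) with a logged event;
  genuine trajectories stay non-negative, so clamping only removes
  integrator noise at the 1e-10 level.
- Trajectory CSVs are written at 17 significant digits and read back with
  round-trip float parsing, giving bit-exact IO.

## Equilibria and stability

Equilibria are located by damped Newton iteration (analytic Jacobian,
backtracking line search, residual tolerance 1e-13) from closed-form seeds
(trivial, prey-only K = r/b, planar endemic S* = μa/(β−μ)) plus a multistart
grid over [0, K]³ (and x ∈ {0, 0.5, 1} in full mode); duplicates are merged
at distance 1e-6 and every reported equilibrium is re-verified to residual
≤ 1e-10. Stability labels (`stable_node`, `stable_focus`, `saddle`,
`unstable`, `non_hyperbolic`) come from the analytic Jacobian's eigenvalues,
with a hyperbolicity band of 1e-7 on the leading real part. The analytic
Jacobian is tested against central finite differences (≤ 1e-6 relative on
random states), and the θ = 0 degeneracy is handled explicitly.

Existence facts under the default constants worth knowing when choosing
brackets:

- The infection can invade the prey-only state only when
  β > μ(a+K)/K ≈ 0.5454; below that (e.g. β₀ = 0.5 at x = 0) **no interior
  coexistence equilibrium exists** and (K, 0, 0) is the global attractor.
- Along the fixed strategy x at β₀ = 0.95, the interior equilibrium loses
  stability at x ≈ 0.36238, is destroyed (P* → 0) at x ≈ 0.4185, and the
  invasion boundary sits at x ≈ 0.4257. Because x enters only through
  β = β₀(1−x), sweeping x is algebraically identical to sweeping β; the
  crossing satisfies β* = β₀(1−x*) ≈ 0.60574, an identity used as an
  internal consistency oracle in the tests.

## Attractor classification

`classify_attractor` labels the post-transient dynamics with this order of
precedence (thresholds in `ClassifierConfig`):

1. **Extinctions** — a compartment that drops below `extinction_eps` (1e-8)
   and stays below is flagged; regimes `extinct_I`, `extinct_P`,
   `extinct_I_and_P`. The `dynamics` field separately labels the surviving
   compartments' behaviour.
2. **Steady point** — all surviving amplitudes below `point_tol` (1e-4).
3. **Chaotic** — largest Lyapunov exponent above `chaos_tol` (0.005).
4. **Limit cycle vs period-doubled** — local maxima are clustered at
   relative tolerance 1e-3; one cluster per compartment ⇒ period-1 cycle,
   more ⇒ period-doubled.

The trajectory must extend at least twice its transient cut, and a
settledness check (last-10% vs preceding-10% amplitude within 20%) warns
when the horizon is too short.

**Lyapunov exponents** use two-trajectory Benettin renormalisation:
companion offset 1e-8, renormalisation every 1 time unit, RK4 dt 0.01 over
the post-transient window. On a limit cycle the estimate sits near 0 (the
neutral direction), which is why `chaos_tol` is a band, not 0. The estimator
returns "not applicable" when the reference trajectory collapses.

## Hopf threshold

`hopf_threshold` bisects the maximum real part of the Jacobian eigenvalues
at the interior coexistence equilibrium, tracking the branch by Newton
continuation from the previous point. A bracket endpoint where the interior
equilibrium does not exist counts as the non-oscillatory side (the branch
has merged with a boundary equilibrium there); if the branch disappears
before the eigenvalues cross zero, the returned value is the existence
boundary rather than a Hopf point.

## Horizons and critical slowing down

Horizons are the package's own accuracy choices:

- default time-series runs: t_end 500, transient 250;
- scans: t_end 1000, transient 500 (`fixed-step-RK4`, dt 0.005);
- extinction questions: t_end 2000–3000 (predator collapse completes around
  t ≈ 1400–2100 in the Allee scenarios);
- scan-based confirmation of the stability flip along x: t_end 26000,
  transient 13000.

The long last figure is forced by critical slowing down: the leading real
part grows only ≈ 0.049 per unit x past the crossing, so at x* + 0.02 the
focus decays at rate ~1e-3 and needs ≳ 10⁴ time units to fall below
`point_tol`. At plotting-scale horizons (~10³) the weakly stable focus still
*looks* oscillatory up to x ≈ 0.42 even though the eigenvalue crossing is at
0.3624. The same applies to β₀ = 0.6 at x = 0 (max Re λ ≈ −3e-4): the
equilibrium is stable by eigenvalues but oscillates visibly for thousands of
time units, and the classifier reports it oscillatory at the documented scan
horizons.

## Limitations and known divergences

- **Stability flip along x**: eigenvalue bisection and the long-horizon scan
  flip agree on x* ≈ 0.3624 (β* ≈ 0.6057), not 0.42. Nearby sit the
  equilibrium-destruction boundary (0.4185) and the invasion boundary
  (0.4257); a finite-horizon amplitude criterion also flips near 0.42. The
  acceptance test for the 0.42 value is left failing rather than retuned.
- **Allee-driven eradication**: at β₀ = 0.95 the predator cannot persist on
  susceptible prey alone (maximum intake c₁α₁K/(σ+K) ≈ 0.00125 < m = 0.01),
  so any outcome with I extinct but P surviving is impossible
  asymptotically. Faithful long-horizon dynamics give coexistence for
  θ ∈ {0, 0.01} (min I ≈ 1.2e-3) and **predator** extinction for
  θ ∈ {0.3, 0.5}. The acceptance test asserting infection eradication is
  left failing.
- **(C_S, e) phase diagram at β₀ = 0.95, θ = 0**: with the payoff
  G = −C_S·S + I + C_P·P, high C_S drives x → 0, which keeps transmission at
  β₀, sustains I, and feeds P — so the predator survives at *high* C_S and
  dies near (C_S = 0, e = 1). The low-C_S-survival assertion is left
  failing. (At β₀ = 0.7, θ = 0.1 the all-cells predator-extinction claim
  does hold and its test passes.)
- **No chaos found**: every probed scenario cell yields Lyapunov estimates
  ≤ 0 (stable points ≈ −0.04, cycles ≈ −1e-3); the `chaotic` label is
  exercised in tests only via an injected exponent.
- Regime labels are horizon-dependent near bifurcation points (see critical
  slowing down above); scans pin their solver settings in the output sidecar
  so labels are reproducible.
- The classifier's period-doubling count is based on peak-level clustering
  at a fixed relative tolerance; cycles with nearly equal successive maxima
  can be under-counted.
- Replicator dynamics are only meaningful for x ∈ [0, 1]; the model is not
  intended for parameter regimes where populations exceed O(10) biomass
  units, and no units calibration to field data is implied.
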