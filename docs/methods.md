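# Methods

## The model

An active Brownian particle (ABP) of unit mass carries an internal energy
depot `e(t)` that is pumped from the environment at a constant flux `q`,
leaks by internal dissipation at rate `c`, and is converted into kinetic
energy at the velocity-dependent rate `d2 v²`:

    de/dt = q − c e − d2 v² e.

The converted energy feeds back into the motion as a propulsive force
`d2 e v`, so the velocity obeys

    dv/dt = −γ0 v + d2 e v − v η1(t) + η2(t),      dx/dt = v,

where `γ0` is the Stokes drag. Two Gaussian white noises act on the
velocity: a *multiplicative* one, `η1`, entering through the coupling
`h1(v) = −v` (random variation of the drag coefficient, intensity `M1`) and
an *additive* one, `η2`, with coupling `h2(v) = 1` (internal agitation,
intensity `M2`). Their correlations are

    ⟨ηi(t) ηj(t′)⟩ = 2 Mij δ(t − t′),   M11 = M1, M22 = M2,
    M12 = μ √(M1 M2),   μ ∈ [−1, 1].

Setting `de/dt = 0` (adiabatic elimination) gives the quasi-stationary depot
`e_qs(v) = q/(c + d2 v²)` and the *reduced* velocity equation
`dv = f(v) dt − v∘dW1 + dW2` with the nonlinear drag

    γ(v) = γ0 − d2 q/(c + d2 v²),      f(v) = −γ(v) v.

In the active regime `d2 q > γ0 c` the drag is negative at small speeds
(`γ(0) = −180` at the reference parameters), `f` has stable zeros at
`v± = ±√(q/γ0 − c/d2)` and an unstable zero at 0, and the deterministic
velocity potential `U(v) = γ0 v²/2 − (q/2) ln(1 + d2 v²/c)` (anchored at
`U(0)=0`; only differences are physical) is a symmetric double well.

## Stochastic-calculus convention

All dynamics are interpreted in the **Stratonovich** sense. The convention
is forced by the structure of the effective drift: with couplings
`h1 = −v`, `h2 = 1` the Stratonovich noise-induced drift is `M1 v − M12`,
so that at `μ = 0` only the multiplicative intensity modifies the effective
drag and the additive noise contributes no drift at all — the defining
property of this model family. An Itô reading would produce no
noise-induced drift and a different stationary law. The integrator (below)
converges to the Stratonovich solution, so the stochastic and analytic
layers share one convention throughout.

## Fokker–Planck layer

For the reduced dynamics the Fokker–Planck equation has

    F(v) = f(v) + M1 v − μ √(M1 M2),
    G(v) = M1 v² − 2 μ √(M1 M2) v + M2,

with stationary density `Q_st(v) = N exp(−U_FP(v))` and effective potential

    U_FP(v) = ln G(v) − ∫₀ᵛ F(u)/G(u) du,   U_FP(0) = 0.

`G` is strictly positive for `|μ| < 1` (discriminant `4 M1 M2 (μ²−1) < 0`);
at `|μ| = 1` it has a double root at `v* = sign(μ)√(M2/M1)` where the
density formula is singular. The cross term breaks the `v → −v` symmetry:
for `μ > 0` the positive-velocity well of `U_FP` is the deeper one, which
is the origin of the noise-induced net transport and of the velocity
reversal when `μ` changes sign. The exact mirror law — the solution at
`−μ` is the `v → −v` image of the solution at `+μ` — is used as an oracle
throughout the test suite.

Numerics: the cumulative integral of `F/G` is evaluated panel-wise with an
8-node Gauss–Legendre rule on each cell of the velocity grid (the integrand
is smooth for `|μ| < 1`, so the quadrature error is far below the
trapezoidal normalization error). The default grid is uniform on
`[−1.2, 1.2]` with 2001 points, wide margins around `v± = ±0.3`; if the
boundary cells carry more than 1e−8 of probability mass the grid is widened
geometrically before a truncation error is raised. The zero-flux identity
`d/dv[G Q_st] = F Q_st` is checked with a fourth-order finite difference;
the residual at the reference noise sets is ~4e−7 of the flux scale. At
`|μ| = 1` the density is computed on the side of the G-root containing the
origin (all stationary mass lives there; the density vanishes faster than
any power at the root); a grid that cannot be reduced to such a one-sided
grid raises a degenerate-noise error.

## Integrator

Correlated Wiener increments with covariance
`[[2 M1 dt, 2 M12 dt], [2 M12 dt, 2 M2 dt]]` are generated through the
lower-triangular square-root factor of the covariance; at `|μ| = 1` the
factor is rank-1 and `dW2` is a deterministic multiple of `dW1` (an error is
raised if `M1 = 0` with `|μ| = 1`, where the correlation is undefined).

Time stepping is the stochastic Heun (predictor–corrector) scheme — the
"stochastic second-order Runge–Kutta": the predictor takes an Euler step,
the corrector averages drift and diffusion coefficients at the current and
predictor states, and **the same increments are reused in both stages**,
which makes the scheme converge to the Stratonovich solution. Three
variants are integrated: the full `(x, v, e)` system, the reduced `(x, v)`
system, and the equivalent single-noise Langevin equation
`dv = [F(v) − G′(v)/2] dt + √G(v) ∘ dW` (drift chosen so its Stratonovich
Fokker–Planck equation has drift `F` and diffusion `G`; `dW` has variance
`2 dt`). The depot is clamped at zero whenever a step would make it
negative; clamp events are counted and reported (at the reference
parameters the clamp fraction is < 1e−4 of steps).

Ensembles draw one RNG child stream per trajectory from the master seed
(`numpy` `SeedSequence.spawn`), so results are bit-reproducible and
independent of trajectory execution order. Initial `v` and `x` are uniform
on `[−1, 1]` by default (the reference protocol, `dt = 0.01`, 500
trajectories of 1e5 steps; the desk scale used in tests is 100–300
trajectories of 2e4–6e4 steps). The depot starts at `e_qs(v(0))` by default
— consistent with the quasi-stationary picture — with `e(0) = q/c`
available as an alternative. The horizon count of the reference protocol is
interpreted as 1e5 *time steps*: the model has no periodic forcing that
would define a period.

## Metastability, and which variant answers which question

A central empirical fact shapes the package's experiment design. At the
reference parameters the two layers of the model are **not** equivalent:

* In the **reduced** dynamics the wells of `U_FP` are 10–35 units deep at
  the figure noise levels, so inter-well Kramers times are of order
  `e^{ΔU}` ≳ 1e6 — far beyond any feasible horizon. A uniformly initialized
  reduced ensemble never hops (0 hops observed in 1e5 steps); its velocity
  histogram keeps the 50/50 well weights of the initial condition, and its
  position variance grows ballistically (`Var[x] ≈ v±² t²`) because the two
  sub-populations drift apart.
* In the **full** dynamics the depot is *slow* (relaxation rate
  `c + d2 v² ≈ 0.1` at the wells versus `|f′(v±)| = 36` for the reduced
  velocity). Moreover `e_qs(v±) = γ0/d2` exactly, so at the fixed points the
  linear damping `−γ0 v + d2 e v` cancels: the wells of the full system are
  soft, trajectories hop freely (≈1.2e4 hops per 30×1e5-step ensemble at
  `M1 = 0.5`), and the ensemble genuinely mixes. The quasi-stationary
  elimination is a structural simplification here, not a quantitative
  limit; it becomes quantitative when parameters make the depot fast
  (e.g. `γ0 = 2, q = 2, c = 5, d2 = 20`, where full and reduced histograms
  agree to KS < 0.02 — this is the regime the test suite uses to validate
  the elimination itself).

Consequently:

* **Transport observables** (mean velocity, mean position, depot energy —
  the μ-, M1- and M2-sweeps) are estimated from the **full** system, which
  is the dynamics the reference protocol integrates and the only variant
  that exhibits the velocity reversal at finite horizons.
* **Effective diffusion** is estimated from the **reduced** dynamics with
  initial velocities drawn from the analytic stationary law (inverse-CDF
  sampling). Started from the stationary law, the ensemble is a
  measure-preservation test of the integrator and the late-time variance
  growth measures the spread about the drift within the occupied state:
  at `|μ| = 1` the noise amplitude `√G` vanishes inside the occupied well,
  trajectories never cross the G-root, and the motion is pure drift
  (`D_eff ≈ 1e−7`); at `μ = 0` both wells are occupied and the spread is
  maximal. A uniform start would instead measure the initial-condition
  dichotomy at every μ and show no suppression at all.
* **SDE ↔ FPE consistency** is likewise checked with stationary-law
  initialization (KS distance ≈ 0.009 at `dt = 0.01`, halving when `dt`
  halves — the expected weak-convergence behaviour).

## Estimators

* Mean velocity: average over retained steps (after a burn-in of 20% of the
  run, the package default; stationarity is visible in first/second-half
  agreement) and trajectories; the SE is the between-trajectory standard
  deviation of per-trajectory means over `√n_traj` — trajectories are
  independent replicates.
* Mean position: ensemble mean of `x` at a stored time; with drift it grows
  as `⟨v⟩ t`, an identity asserted in the tests.
* Depot observables: both `⟨e⟩` and the conversion rate `d2 ⟨e v²⟩` are
  reported (the scalar summary of the depot's feed into the motion admits
  either reading); at stationarity they satisfy the energy balance
  `q − c⟨e⟩ − d2⟨e v²⟩ = 0`, asserted within 3 SE.
* Effective diffusion: `D_eff = ½ × slope` of the ensemble variance of
  `x(t)` over the final half of the run, by least squares. Using the
  variance *about the ensemble mean* removes the common drift. The
  regression SE is reported as a fit diagnostic (successive variance
  samples are correlated, so it understates the Monte-Carlo error);
  negative point estimates are possible in fit noise and returned as-is.
* Sign change: linear interpolation of the zero crossing of `⟨v⟩(μ)`,
  taking the crossing nearest the origin when noise produces several; the
  SE is a bootstrap over trajectories (200 resamples).

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| γ0 | 20.0 | Stokes drag (1/time) |
| q | 2.0 | depot influx |
| c | 0.01 | depot dissipation rate (1/time) |
| d2 | 1.0 | conversion rate coefficient |
| M1, M2 | 0.5, 0.05 | multiplicative / additive noise intensity |
| μ | 0.0 | cross-correlation intensity |
| dt | 0.01 | integrator step |
| n_traj × n_steps | 500 × 1e5 | reference protocol (`--scale paper`) |
| | 100 × 2e4 | desk scale (`--scale test`, default) |

The physical defaults are the reference figure-caption values; the desk
scale is the package's own choice of a reduced ensemble whose standard
errors still resolve the shape properties being tested (300 × 3e4 is used
for the flattest curves, the M1- and M2-sweeps of the mean velocity).

## Known limitations

* The desk-scale mean-velocity amplitudes of the full dynamics at
  `M1 = 0.01` are small (|⟨v⟩| ≲ 0.013 at `|μ| = 0.9`); resolving the
  reversal requires the ensemble sizes noted above.
* At `M1 = 2–3` (strong multiplicative noise) the full-system mean velocity
  at `μ = 0.5` is *negative* at the reference horizon (−0.024, stable under
  `dt` refinement), so the sweep over `M1` rises and then falls through
  zero rather than staying positive; the interior-maximum (bell) property
  holds and is what the shape test asserts.
* The equivalent single-noise variant reproduces the reduced dynamics in
  distribution, not pathwise; comparisons are distributional (two-sample
  KS on autocorrelation-thinned samples).
* `D_eff` from finite horizons is a window statistic: in the metastable
  `μ = 0` reduced regime the variance growth is still ballistic at the end
  of the window, so the value reported there is a lower bound on the
  (astronomically large) asymptotic coefficient; the suppression at
  `|μ| = 1` is by 7–8 orders of magnitude regardless.
* The synthetic dynamics are the model itself; no aspect of real
  cell-motility or molecular-motor data (finite sampling, measurement
  noise, inertia of real tracers) is emulated, so passing tests validate
  the model's internal consistency and its documented phenomenology, not
  agreement with experiments.
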