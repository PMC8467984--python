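# Methods

## The models

Two generalisations of the Lotka–Volterra predator–prey system are
covered, distinguished by the functional response of the interaction:

* **predator saturation** — interaction terms `b·x1·x2/(1 + A·x1)` and
  `f·x1·x2/(1 + A·x1)`: with abundant prey, per-predator consumption is
  limited by the predator population, not the prey supply;
* **predator competition** — interaction terms `b·x1·x2/(1 + B·x2)` and
  `f·x1·x2/(1 + B·x2)`: a large predator population competes for a
  limited prey supply.

Both carry a weak prey self-competition term `−s·x1²`.  The parameters
`s`, `A`, `B` and all noise intensities are treated as *effective*
(perturbation-order-absorbed) quantities `s_eff`, `A_eff`, `B_eff`, …;
no explicit small parameter appears anywhere.  Introducing barred
parameters (ā, b̄, f̄) maps either model onto the unified form

    dx1/dt = x1 [ ā − b̄x2 − (s_eff/f̄)(−c + f̄x1) + g1(x1,x2) ],
    dx2/dt = x2 [ −c + f̄x1 + g2(x1,x2) ],

with exactly computable residual rates g1, g2.  For the saturation case
the map is closed-form (`f̄ = f − c·A_eff`, `b̄ = b·f̄/f`,
`ā = a − s_eff·c/f̄`); for the competition case it reduces to the
positive root of one quadratic in b̄.  The reparametrisation is *exact*:
the test-suite checks the unified-form per-capita rates against the
original models at 1e−12 over random parameter draws, which is also how
the b̄-definition ambiguity (two inequivalent published spellings) was
resolved — only `b̄ = b·f̄/f` reproduces the original vector field
identically.

## Noise model

Environmental fluctuations perturb the prey growth rate and predator
death rate through two independent channels, each a sum of

* Gaussian white noise with autocorrelation `2Dᵢ·δ(τ)` (stored as the
  half-intensity `Dᵢ`; configuration files may quote the printed
  convention `2Dᵢ` instead), and
* Poisson white noise: jumps arriving at mean rate `λᵢ` whose magnitudes
  are zero-mean Gaussian with variance `mᵢ = E[Yᵢ²]` (so fourth moments
  are `3mᵢ²` throughout).  A jump multiplies the affected population by
  `e^Y`.

The total effective intensity of a channel is `2Dᵢ + λᵢmᵢ`.  At fixed
intensity, large-λ/small-m forcing approaches Gaussian forcing; the
sparse-jump regime (small λ, large m) is where the jump-specific
corrections matter.

## Stochastic averaging

The unperturbed unified system is the classic LV oscillator with first
integral

    r(x1,x2) = f̄x1 − c − c·ln(f̄x1/c) + b̄x2 − ā − ā·ln(b̄x2/ā) ≥ 0 ,

zero exactly at the coexistence point (c/f̄, ā/b̄).  Under weak noise, r
drifts slowly while the state circulates quickly along the orbit, so the
generator of R(t) may be averaged over one quasi-period T(r).  In log
coordinates the unperturbed flow is canonical Hamiltonian with
Hamiltonian r; all orbit integrations run there (conservation at the
1e−9 level over a period, positivity automatic).  Orbit averages ⟨h⟩(r)
and T(r) are computed by adaptive integration (DOP853, rtol 1e−10, atol
1e−12) with return-section event detection — a short arming segment
moves the start point off the section so the event cannot fire at t = 0;
the singular turning-point quadrature form of the period is retained
only as a cross-check oracle (two-route agreement ≤1e−6).  Levels are
tabulated on a log-dense grid of `n_levels` (default 160) points from
`1e−4·ā·c` to an automatically extended `r_max`, preceded by the
analytic r = 0 node (point orbit: T is the harmonic period
`2π/√(ā c)`, every average is the integrand at the equilibrium); cubic
splines interpolate all columns.

The averaged generator of R is a fourth-order (GFPK) operator whose
coefficients combine orbit averages of the jump-response Taylor
polynomials (`A11 = f̄x1 − c`, `A1k = f̄x1/k!`, predator analogues) with
the noise parameters — drift Ā₁₁, diffusion Ā₂₁ at leading order, and
jump-only Ā₁₂, Ā₂₂, Ā₃₁, Ā₄₁ carrying the fourth-moment weights
`3mᵢ²λᵢ`.  The drift correction U0 (self-competition + unified-form
residuals + Itô/Wong–Zakai terms) equals the generator of the correction
dynamics applied to R; the tests verify this against Richardson-
extrapolated finite-difference derivatives at 1e−8.  The orbit table
itself is noise-independent (the Gaussian part of ⟨U0⟩ reduces to
`D1·f̄⟨x1⟩ + D2·b̄⟨x2⟩`), so one table serves a whole noise scan.

## Stationary solution

The stationary density of r solves the averaged GFPK equation with
boundary conditions chosen as zero probability flux at r → 0⁺ and decay
at infinity (standard for a nonnegative first-integral process with an
inaccessible boundary; the source of the method leaves them
unspecified).  The expansion `p_R = p0 + p2` is order-separated:

* `p0 ∝ exp(∫2Ā₁₁/Ā₂₁)/Ā₂₁` — the zero-flux solution of the leading
  pair, identical to the stationary density under Gaussian forcing of
  equal intensity (the *Gaussian approximation* p_G).  Near r = 0,
  `p0 ~ r^(κ−1)` with `κ = 2Ā₁₁(0)/Ā₂₁'(0)`; for this model family κ = 1
  identically (numerator and denominator collapse to the same
  combination `c(2D₁+λ₁m₁) + ā(2D₂+λ₂m₂)`, up to the factor 2), so p0
  is finite at the origin.  The solver computes κ numerically, handles
  the regular case Ā₂₁(0) > 0 separately (used by synthetic-coefficient
  tests), and raises a regime error when the density is not
  normalizable.
* the odd-order correction vanishes: it solves the same homogeneous
  equation as p0 with the same boundary conditions, and the
  order-matched normalisation forces the admissible multiple of p0 to
  zero.
* `p2` solves the once-integrated first-order equation
  `½Ā₂₁p2' + (½Ā₂₁' − Ā₁₁)p2 = S` (integration constant zero by decay),
  by variation of constants with p0 as homogeneous solution,
  `p2 = p0·(K + ∫2S/(Ā₂₁p0))`; K is fixed by `∫p2 dr = 0`.  The printed
  form of the hierarchy carries an apparent typo (the O(ε⁴) drift
  coefficient in the diffusion slot); the operator used here is the
  leading (Ā₁₁, Ā₂₁) pair, consistent with the p0 equation.  All
  derivatives of coefficient·p0 products are expanded through the
  analytic log-derivative `p0'/p0 = 2Ā₁₁/Ā₂₁ − Ā₂₁'/Ā₂₁` plus spline
  derivatives of the coefficients, avoiding repeated numerical
  differentiation of the density.  S/p0 is evaluated directly, so the
  construction remains conditioned where p0 underflows.

`p_R` may go slightly negative in far tails; the negative mass fraction
is recorded in diagnostics (warned above 1e−4, never clipped — clipping
would silently bias the L2 comparisons).  The level grid is extended
geometrically until the estimated p0 tail mass beyond `r_max` is below
1e−8.

## Observables

Conditioned on r the state is uniform in orbit *time*, giving the joint
density `p(x1,x2) = p_R(r)/(T(r)·x1·x2)`.  Marginals integrate the joint
density over the companion coordinate on a log-spaced Simpson grid
(1201 points) capped at the level containing all but 1e−6 of the p_R
mass; marginal grids default to 400 points spanning the capped extents.
Moments reuse the orbit averages, `E[h] = ∫p_R(r)⟨h⟩(r)dr` — in
particular `E[X1] = c/f̄` and `E[X2] = ā/b̄` *exactly within the averaged
theory*, independent of the noise.  "Relative fluctuation" is exported
in both readings — coefficient of variation `√Var/E` (the default
interpretation) and `Var/E` — since the source notation is ambiguous;
the reported parameter trends hold for either.  The discrepancy metric
between two marginals is the squared-L2 norm `∫(p_a − p_b)²dx` on the
union grid.

A consequence worth stating: at constant Poisson intensity `λ·m`, p_G is
independent of λ, and every jump term in the p2 equation carries the
weight `3m²λ = 3(λm)²/λ`, so within this construction the L2 discrepancy
scales *exactly* as `1/λ²` along a constant-intensity scan.  Published
reference values for this scan deviate from that scaling between their
two smallest arrival rates, where the corrections are largest; the
corresponding comparisons are therefore expected to agree in magnitude
but not within tight tolerances at every rate.

## Monte Carlo validation

The simulator integrates the *original* models (exact drift, no
unified-form truncation) in log coordinates, where both noise types act
additively: Gaussian increments `√(2Dᵢ dt)·N(0,1)` and per-step
compound-Poisson jump increments `N(0, n·mᵢ)` with `n ~ Poisson(λᵢ dt)`
— exact in distribution because jumps are additive in log space, which
is why per-step compounding replaces event-time splitting at no cost in
correctness.  The deterministic drift advances with a classical RK4
stage: a first-order drift step measurably inflates the stationary
spread of this weakly-dissipative near-Hamiltonian flow (prey variance
−11% when halving dt twice under Euler, ~1% under RK4).  Defaults: dt =
2e−3 of the harmonic period, 100 paths, total time 2000 with burn-in
400, recording every 5th step (≈1.7M pooled samples, well under a
minute).  Paths leaving |ln x| > 60 are flagged and excluded (>1%
flagged is an error).  Bootstrap errors of means resample whole paths,
the independent unit.

A limitation surfaced by the validation: the averaged theory predicts
`E[X1] = c/f̄` for any noise level, while the exact stationary identity
of the true saturation model is `E[X1/(1+A_eff·X1)] = c/f` (the
simulator reproduces it to ~1e−4).  The difference — a
fluctuation-induced mean shift of order `A_eff·Var[X1]`, about 1% at the
sparse-jump reference noise — is a genuine bias of first-order
averaging, far exceeding the Monte Carlo standard error of a converged
run.  Distribution-shape comparisons (the perturbation marginal closer
to the empirical one than the Gaussian approximation) are unaffected.

## What the built-in generators do and do not emulate

All studies here are synthetic: parameter sets are the published
reference ecosystems, and the Monte Carlo generator realises exactly the
stochastic model the theory averages (multiplicative Gaussian +
compound-Poisson forcing with Gaussian magnitudes).  Passing tests
demonstrate internal consistency of averaging, perturbation and
simulation — they do not validate the model family against field data,
non-Gaussian jump magnitudes, correlated channels, demographic
(finite-population) stochasticity, or extinction dynamics (the averaged
description has an inaccessible boundary at r = 0 and cannot represent
absorption at zero population).

## Numerical defaults and their rationale

| knob | default | why |
| --- | --- | --- |
| `n_levels` | 160 | coefficient-spline third derivatives feed the p2 source; 160 log nodes hold the FD-oracle agreement at ~1e−4 while a full solve stays ≈1 s |
| `n_r` | 2400 | dense solution grid; doubling changes p_R by <1e−6 in L1 |
| `ivp_rtol/atol` | 1e−10 / 1e−12 | orbit means then hold at 1e−8, period two-route agreement at 1e−6 |
| `tail_tol` | 1e−8 | p0 mass ignored beyond the grid |
| `marginal_points`, `quad_points` | 400, 1201 | L2 values stable to <1e−3 relative under doubling |
| MC `dt` | 2e−3·harmonic period | λ·dt ≪ 1 for all studied rates; RK4 makes drift error negligible at this step |

Problem sizes in the acceptance script (160 levels, three arrival rates
per model) keep a full from-scratch reproduction of both reference scans
around ten seconds; all quantities it prints are computed at run time.
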