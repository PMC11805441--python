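# Methods

## The modelling problem

Calmodulin (CaM) translates intracellular Ca²⁺ signals into downstream
signalling. Its four EF-hand sites are organized into two lobes — the
C-terminal lobe binding slower with higher affinity, the N-terminal lobe
faster with lower affinity — and the literature contains kinetic schemes of
very different structure for the same molecule. This package implements a
common-benchmark comparison of six such schemes:

| id | structure | states | rate parameters |
|----|-----------|--------|-----------------|
| S1 | whole molecule, two ions per step | 3 | 4 |
| S2 | whole molecule, one lumped + two single steps | 4 | 6 |
| S3 | whole molecule, fully sequential | 5 | 8 |
| S4 | independent lobes, lumped two-ion steps (QSS-reduced) | 4 | 8 |
| S5 | independent lobes, identical sites | 6 (lobe species) | 8 |
| S6 | independent lobes, distinct sites | 8 (lobe species) | 16 |

All kinetics are mass action; two-ion steps are third order (flux ∝
[Ca]²[species]). Units are M and ms throughout: bimolecular on-rates in
M⁻¹ms⁻¹, termolecular on-rates in M⁻²ms⁻¹, dissociation constants in M or
M² according to the step's order. Rate constants are carried in log₁₀ and
reverse rates are always derived from K_D = k_off/k_on, so a scheme's free
parameters are its forward rates and K_Ds.

Lobe-structured schemes (S5, S6) are simulated as independent lobe species
(six and eight states instead of nine and sixteen molecule states), which
is exact as long as no downstream molecule binds whole calmodulin.
Molecule-level quantities (fully/partially bound CaM) are reconstructed
from lobe fractions by independence.

Identical-sites parameterizations differ between published sources by
statistical factors of two (intrinsic-site vs macroscopic constants).
`RateSet` carries explicit `double_forward` / `double_reverse` flags; the
packaged intrinsic-site entry doubles the first on-rates and second
off-rates on import so that one canonical ODE serves both conventions.

### The QSS reduction (S5 → S4)

For one lobe chain A ⇌ B ⇌ C (rates k₁,k₂ then k₃,k₄), setting dB/dt = 0
gives B = (k₁[Ca]A + k₄C)/(k₂ + k₃[Ca]) and the lumped two-ion step

    k_on_eff  = k₁k₃ / (k₂ + k₃[Ca]),   k_off_eff = k₂k₄ / (k₂ + k₃[Ca]),

whose ratio is K_D1·K_D2 at every [Ca] — the reduction preserves the lobe's
lumped equilibrium exactly and errs only dynamically. The compiled RHS
keeps the full [Ca]-dependent denominators (nothing is frozen at a
reference [Ca]). Validity is a property of the intermediate's speed *and
occupancy*: the test suite shows the reduction reproducing the full chain
to <1% of total CaM when intermediates are fast and sparse (N-lobe-like)
and failing by >5% when they are slow and heavily populated (C-lobe-like),
and the distinct-sites simulation under flash conditions shows the C lobe's
singly bound states still evolving at 35 ms while the N lobe's have settled.

### Equilibrium

With free Ca²⁺ clamped (titration conditions) the CaM subsystem is linear.
Chain schemes (and S4, whose two paths to full occupancy share a consistent
cycle product) use the detailed-balance path product Π [Ca]ⁿ/K_D. The
distinct-sites diamonds are *not* constrained to thermodynamic cycle
closure (all 16 constants are free, matching the published parameter
count), so their steady state is computed as the null space of the clamped
rate matrix, which is correct off cycle closure. Both routes are verified
against an independent long-time ODE-relaxation oracle to 10⁻⁶ relative.

## Forward model of a flash experiment

A recording is: equilibrate the solution (CaM, DMn, OGB-5N, total Ca),
instantaneously convert a fraction U of DMn — free and Ca-bound alike —
into its low-affinity photoproduct, and integrate the stiff mass-action
system. The pre-flash equilibrium is solved in closed form: free Ca is the
root of the scalar total-Ca balance (all binding curves are monotone in
free Ca), so the initial state is exact to root-finder tolerance.

The uncaged fraction is U(η) = 1/(1+e^(−η)), a logistic map of the
per-recording random effect; the published linear uncaging model
(0.0011·PCD − 0.39 + x) is provided for comparison only, since its output
escapes [0, 1]. The fluorescence observable is the ratio
([OGB5N] + R[CaOGB5N])/(same at t=0) with R = F_max/F_min = 39.364. The
formula evaluates to 1 at t = 0 although the quantity is conventionally
called ΔF/F₀; the implementation follows the ratio definition literally
and keeps the conventional name.

Buffer rate constants are not part of the fitted parameter set and are not
printed with the schemes; the packaged defaults are Faas-style placeholder
values (DMn: k_on 3·10⁴ M⁻¹ms⁻¹, K_D 5 nM; photoproduct: K_D 3 mM with
fast release; OGB-5N: K_D 35 µM) and are configurable. The solver is
LSODA (stiff-capable) through a numba-compiled RHS; default tolerances are
rtol 10⁻⁸ and atol 10⁻¹³ M — the tightest absolute tolerance that double
precision supports robustly for nanomolar species; fitting uses relaxed
(10⁻⁶/10⁻¹²) tolerances and all reported evaluations the defaults.

## The NLME model

Fixed effects Θ: the scheme's log₁₀ rates θ, random-effect prior
parameters (μ, ω), and two observation-noise SDs — σ_dyn for the
fluorescence ratio and σ_eq for Ca-per-CaM (two observables with different
scales need separate noise parameters; both are fitted). The only random
effect is η_n, the flash strength of recording n: rates carry no
per-recording individualization. Observation noise is additive Gaussian
for both observables; equilibrium points carry no random effects and enter
every training set in full.

Priors (all in log₁₀ space): S1/S2 wide uniforms U(2,9) on forward rates
and U(−9,−4) on K_Ds (in each step's own units — the M² interval is taken
literally); S3 the same forward-rate uniforms with N(r,1) on K_Ds centered
on the published titration constants; S4/S5 N(r,1) centered on the
flash-photolysis-derived values; S6 N(r,1) centered on the distinct-sites
stopped-flow values. μ is restricted to [−5,5] and ω to [1,∞) with a
N(0,1) prior — the minimal restriction that stops the MAP conditional
objective from inflating the random-effect distribution instead of
fitting the data (the unrestricted ML estimate of ω collapses below 1 for
tightly clustered η, which the test suite demonstrates).

The fitting objective is the MAP conditional log-likelihood, maximized
jointly over Θ and all η_n. For AIC the η integral is replaced per
recording by its Laplace approximation — scalar η makes the curvature a
single second derivative — with the equilibrium likelihood added
unchanged; the approximation is verified against the closed-form conjugate
Gaussian marginal to 10⁻⁶.

### Optimization

Bounded quasi-Newton (L-BFGS-B) over the packed vector
[θ, log σ_dyn, log σ_eq, μ, ω, η…]; box bounds implement the uniform prior
supports and the μ/ω domain restrictions directly, rather than smooth
reparameterizations — equivalent constraints with a simpler objective.
Gradients exploit the hierarchical structure: rate parameters use forward
finite differences (one full data pass each), each η_n re-solves only its
own recording, and σ, μ, ω have closed-form partials.

Three stages precede the main optimization, all deterministic:

1. an equilibrium pre-fit places the K_Ds by fitting the titration alone
   (closed form, no ODE solves);
2. η is initialized per recording by scalar MAP given the initial rates;
3. a warm-up phase runs with the noise SDs frozen, preventing the
   optimizer from inflating a noise term instead of fitting the
   corresponding observable.

Multistart initial conditions are stratified: uniform-prior forward rates
share one stratum index per start, so the starts sweep the slow→fast
kinetic axis together. This is deliberate — the dominant nonconvexity is a
family of wrong-timescale local optima ("buffers-only" fits with adjusted
flash strengths), and independent per-parameter draws rarely place any
start in the all-fast corner. K_Ds and normal-prior parameters are drawn
from their priors. Fits are ranked by validation RMSE when a validation
split exists, else by final objective.

Convergence tolerances: projected-gradient 10⁻⁶, relative objective
10⁻⁸, iteration caps per study size (100 for the 4-parameter recovery
study, 40 for the 12-parameter one, 20–25 inside the model-selection
sweep). The spread of multistart outcomes, not a single run, is the unit
of analysis — as in the parameter-correlation study.

### Data splitting and preprocessing

Train/validation/test splits are stratified by solution group (every group
contributes a training recording), deterministic from a seed, defaulting
to 70/15/15. Dense early sampling is thinned before fitting (keep every
2nd point before 1 ms), applied identically to synthetic and real-format
data; log-spaced grids already balance the sub-ms spike against the
tens-of-ms tail, so the thinning is mild.

## Model comparison

RMSE is the square root of the *mean* squared residual (the conventional
definition the acronym names; per-trace errors are then comparable across
lengths). Cohen's d uses the pooled standard deviation. AIC is 2k − 2L
with L the Laplace marginal log-likelihood evaluated on held-out
recordings (η re-optimized per held-out recording, as marginalization
requires) plus the equilibrium data, which has no splits; k counts the
scheme's rate parameters plus σ_dyn, μ and ω. Relative likelihoods are
exp(ΔAIC/2) against the better model.

## Synthetic data

The generator emulates the study's generative situation with known ground
truth. Seven solution groups span CaM 2–100 µM, DMn 1.5–4.5 mM and OGB-5N
20–100 µM; total Ca loads DMn at 25%. That loading is deliberate: strong
flashes then exhaust part of the remaining chelator capacity and leave a
sustained elevated free-Ca plateau (as in the real recordings, where
strong-flash traces equilibrate at high fluorescence), while weak flashes
are fully re-buffered. The sustained phases are what make on-rates
identifiable separately from the flash strengths; with fully re-buffered
transients the rate information compresses into the sub-millisecond spike
and trades off against η. Flash strengths are drawn η ~ N(μ, ω²), sorted
ascending within a group (a sequence of pulses of increasing strength);
defaults μ = 0, ω = 1, σ_dyn = 0.02, σ_eq = 0.1. The equilibrium titration
is 107 log-spaced points over 10⁻⁷–5.5·10⁻⁵ M free Ca, clipped to [0,4].
Sampling uses a log-spaced 0.02–40 ms grid (48 points) resolving spike and
tail alike. η draws and noise draws come from independent seeded streams,
so the same flash strengths are generated with or without noise.

Ground-truth rates default to the packaged best-fit parameter sets per
scheme, with one exception: the S1 (two-ion two-step) best fit sits on its
prior boundary with a second on-rate of 10⁴ M⁻²ms⁻¹, whose step relaxes on
a ~10⁶ ms timescale — dynamically inert in any uncaging window and hence
unrecoverable in principle, which would make a recovery study vacuous. The
S1 synthetic truth is instead a structurally similar fast-cooperative set
(k₁ = 10⁸, K_D1 = 10⁻⁸·⁶ M², k₃ = 10⁷·⁷, K_D2 = 10⁻⁸·⁸ M²) chosen, before
any fitting, so that both steps leave a kinetic fingerprint in the data.

What the generator does *not* emulate: the exact published solution-group
compositions (not printed in the main text), photobleaching, shot noise,
instrument dead time, or multiplicative noise. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to real-instrument artifacts.

## Parameter analysis

Across multistart/multiseed fits of lobe-structured schemes, the lobes are
only identified up to a swap, so the lobe with the lower first-binding
K_D (for S4, the lower lumped K_D1·K_D2) is relabeled C before any
across-fit statistic. Partial correlations are computed from the inverse
correlation matrix of the log₁₀ parameters, with an escalating ridge
fallback near singularity; p-values are two-sided t with n − p degrees of
freedom. Linear (Pearson) partial correlation on log₁₀ parameters is the
default since the analysis already operates in log space; a rank
(Spearman) variant is available by flag. Raw p < 0.05 marks significance
by default; Benjamini–Hochberg is available but off by default.

## Numerical choices and degenerate inputs

Concentrations are clipped at zero inside the RHS before evaluating
fluxes. Zero total Ca short-circuits the equilibrium solve to the fully
unbound state. Degenerate variance in Welch's test returns (±∞, 0) or
(0, 1) for identical samples. Titration grids must be positive and
increasing; the spike-train protocol requires at least one spike. AUCs use
the trapezoid rule on a 0.1 ms grid; spikes are instantaneous free-Ca
increments (the simplest pulse shape consistent with "Ca injections"),
with pulse width configurable in principle through the segment integrator.

## Problem sizes used in validation

The recovery studies run at 7 groups × 4 flashes (28 recordings, ~30
points each after thinning) with 5 multistarts; the model-selection study
runs 10 seeds at 2 groups × 3 flashes with a 70/30 train/test split
(three flashes per group so every training set spans a range of flash
strengths) and reduced starts, a size at which the structural gap between
the distinct-sites scheme and the lumped schemes is still decisive. The
acceptance script runs the same studies at the same or slightly reduced
sizes and reports the measured quantities; nothing in it is asserted
against fixed constants.

## Known limitations

* The MAP conditional objective is multimodal; the stratified multistart
  finds the dominant basin reliably in the validated studies but carries
  no global guarantee.
* Finite-difference rate gradients cost one data pass per parameter;
  16-parameter schemes are therefore the practical ceiling at desk scale.
* The Laplace marginal assumes a single, positively curved optimum per
  recording's η; multimodal per-recording posteriors would need
  quadrature.
* Buffer kinetics are fixed, not fitted; misspecified buffer constants
  would bias rate estimates in real-data applications.
* The equilibrium observable ignores the competing indicator used in the
  real titration (the abscissa is free Ca, so the indicator cancels only
  if free Ca is measured exactly).
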