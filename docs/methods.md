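# Methods

## The model

`kintraffic` models the collective traffic of kinesin-1 motors along a
single microtubule protofilament as a driven lattice gas. A protofilament
is a 1D lattice of binding sites of length a = 8.4 nm (one tubulin
heterodimer). Each motor is a rigid dimer occupying two adjacent sites
(front head and back head); we label a motor's position by its front head,
so the dimer density ρ (probability that a site carries a front head) is
bounded by 1/2, the fully decorated lattice.

Kinetics (all rates in s⁻¹, continuous time, Poisson):

- **Stepping.** An active motor hops one site toward the plus end at rate
  ν, provided the target site is empty (hard-core exclusion). The free
  velocity is V₀ = νa.
- **Langmuir kinetics.** Motors attach from a well-mixed reservoir at rate
  ω_A = ω_a·c per pair of adjacent empty sites (c is the bulk motor
  concentration in nM), and detach spontaneously at rate ω_D.
- **Facilitated (motor-induced) detachment.** When a motor runs into the
  back of another, the trailing motor's detachment rate is enhanced by an
  additional rate θ ("bounce-off"). A configuration switch implements the
  kick-off alternative (leading motor leaves instead); both produce the
  same collective behaviour, and bounce-off is the default.
- **Pausing (optional variant).** A bound motor switches into an inactive
  state at rate r_inactivation and back at rate r_activation. Inactive
  motors cannot step but still block others and keep both detachment
  channels. Attachment always delivers an active motor. Because only the
  switching rates of this mechanism are established experimentally, we
  made the minimal choices: inactivation also accrues while a motor is blocked, and
  facilitated detachment acts regardless of the activity state of either
  motor.

The default parameter set is the one extracted for kinesin-1 from the
concentration-series experiments: ν = 79 s⁻¹ (from V₀ = 0.66 µm/s),
ω_D = 0.53 s⁻¹ (from the 1.9 s dwell at low concentration),
λ₀ = 1.8×10⁻² µm⁻¹s⁻¹ (tracer landing normalisation at c₀ = 5 pM),
ω_a = 5.4×10⁻² nM⁻¹s⁻¹ and θ = 2.4 s⁻¹ (global fit), and for the pausing
variant r_inactivation = 0.004ν ≈ 0.32 s⁻¹, r_activation = 1/0.12 s ≈
8.3 s⁻¹. The fitted ω_a and θ are *inputs* here: they cannot be re-derived
without the original experimental tables, which were published only as
figures. Internal units are lattice sites and seconds; µm/nm appear only at
I/O boundaries.

## Mean-field theory

Factorising joint occupation probabilities with the dimer correlation
factor 1/(1−ρ) gives the stationary balance

    ω_A (1−2ρ)²/(1−ρ) = ω_D ρ + θ ρ²/(1−ρ),

with closed form ρ = 2ω_A / (4ω_A + ω_D + √(4ω_Aω_D + 4θω_A + ω_D²)), and
the observables

    j = νρ(1−2ρ)/(1−ρ),  τ = [ω_D + θρ/(1−ρ)]⁻¹,
    V = V₀(1−2ρ)/(1−ρ),  l = τV,  λ = λ₀(1−2ρ)²/(1−ρ).

The skewed current-density relation peaks at ρ* = (2−√2)/2 ≈ 0.29. Setting
ω_Dρ = θρ²/(1−ρ) and inverting the balance for ω_A gives the concentration
(≈7 nM at the default parameters) above which motor-induced detachment
dominates.

A one-site landing variant replaces the attachment term by ω_A(1−ρ); its
stationary density is found numerically (Brent, |Δρ| ≤ 1e−12) because the
balance may have no root below half filling when attachment overwhelms
detachment — the solver reports this instead of extrapolating. No
landing-rate expression is established for this variant; we use
λ = λ₀(1−ρ) by analogy with the attachment-term replacement, and flag this
as an inference in the docstring. The variant is mean-field only: the
microscopic attachment geometry (where the second head lands) is not
specified, so the simulator deliberately has no counterpart.

The spatial mean-field equation is relaxed by forward Euler with
dt = 0.2/(ν+ω_A+ω_D+θ) until max|∂ρ_i/∂t| < 1e−10 (the returned profile
therefore satisfies the plug-back residual check at that tolerance). Open
boundaries use zero injection at the minus end (a dimer cannot land with
its back head off-lattice) and unobstructed exit at the plus end, the
behaviour expected for kinesin-1, which shows no end-residence.

Accuracy: against the exact simulation the factorisation is good to ~1% at
small θ/ν and degrades with crowding interactions — at ω_A = 0.01ν,
ω_D = 0.001ν the density error is ≈3% at θ = 0.06ν and ≈7% at θ = 0.12ν; at
the kinesin-1 parameters (θ/ν = 0.03) the four observables deviate by 0–3%
(velocity +2–3%, landing rate −2–3%). Tests therefore compare simulation
and theory at the few-percent level, which is also the precision of the
plotted claims they reproduce.

## Stochastic simulation

The simulator is an exact Gillespie realisation of the continuous-time
Markov chain on a ring (default 2000 sites, periodic boundary conditions —
justified because the ~1 µm run length keeps boundary layers, ~100 sites,
small relative to real microtubules). Six channel classes (hop, attach,
spontaneous detach, facilitated detach, inactivate, activate) have their
member counts maintained incrementally: each event only changes flags in
its neighbourhood, and each flag refresh is idempotent, so a handful of
local updates per event suffice; a full recount validates the bookkeeping
at the end of every run (and the small-ring tests cross-validate against a
pure-Python channel enumeration). Members within a class are drawn by
rejection sampling from the dense bound-motor list, which is O(1) per draw
at the acceptance rates that occur in practice. The hot loop is compiled
with numba; seeding is explicit and a given (seed, config, parameters)
triple reproduces output bit for bit.

Recorded outputs: per-binding-event run records (attach/detach times,
steps, detachment cause), frame-sampled trajectories every 0.1 s (positions
stored as attach site + cumulative steps, i.e. unwrapped, so ring
wrap-around never corrupts displacements), and time-averaged counters.
Empirical observables: ρ and j are time averages over the post-burn-in
window; τ, l, V are means over completed runs that attached after burn-in
(the measurement window must exceed the dwell time several-fold, otherwise
censoring of long runs biases τ low — the defaults respect this); λ is λ₀
times the time-averaged pair-vacancy probability. Tracer landings are not
simulated as a species (bound kinetics are label-independent); where a
counting experiment is mirrored (see below), landings are drawn as the
exact Poisson thinning of the pair-vacancy trajectory.

Burn-in defaults to 20/ω_D. The exact master-equation oracle enumerates all
dimer configurations of rings up to 10 sites (47 configurations at L = 8;
with activity flags the count multiplies by 2^k per k-motor configuration),
builds the generator from the same event enumeration, and solves πQ = 0 by
a null-space computation.

## Detection of periods of no or slow motion

Trajectories sampled at Δ = 0.1 s are scanned per motor. A frame-to-frame
displacement d is SMALL when d < d_c (backward motion counts as small — the
1D collapse of the experimental off-axis angle criterion, which carries no
computation here) and TERMINATING when d > d_c. On integer lattice
positions d = d_c is deliberately neither: it cannot seed an onset, and it
neither counts toward nor continues a terminating pair. This literal
reading matters only for noiseless integer trajectories, but it is what
reproduces the published progression ladder (≈30 / ≈17 / ≈10 sites at
d_c = 5 / 3 / 2 with the terminating displacements included, the d_c = 2
value matching the experimental 10 sites); treating equality as large
yields ≈16 / 7 / 3 and cannot.

A period starts at the frame preceding the first of three consecutive small
displacements; isolated large displacements inside a period are tolerated;
two terminating displacements in a row end it. Each period carries two
displacement measures: `progression` (start to last slow frame) and
`progression_inclusive` (start to the frame at which termination is
confirmed, i.e. including the terminating pair — the quantity behind the
≈30-site figure). Durations always use the slow-motion anchors, so the
minimum detectable duration is exactly 3Δ = 0.3 s, the protocol's cutoff.
Periods cut off by the trajectory end are flagged truncated; they are
excluded from duration statistics but kept in progression statistics, since
a period ended by detachment still has a well-defined progression and the
~1 s dwell times would otherwise discard most of the sample. Localisation
noise is modelled as i.i.d. Gaussian offsets per frame (σ in nm, converted
through a).

Because only periods ≥ 0.3 s are detectable while pause durations average
0.12 s, counts are corrected by the exponential survival at the cutoff:
corrected = detected / exp(−0.3/τ̂). τ̂ is fitted to the tail (durations ≥
0.5 s) by maximum likelihood; for frame-quantised durations the excess
frame counts are geometric and the naive mean excess underestimates τ̂ by
~30%, so the geometric MLE is used and converted back to a time constant
(the continuous mean-excess estimator is used for non-quantised input).
Per-step probabilities divide the corrected count by the total steps taken
by the analysed motors in the window.

The ground-truth detector marks a motor as in a period when it is inactive
or chained — strict adjacency, front head exactly one site behind the back
head ahead — to an inactive motor; stochastically assembled jams with no
inactive member are excluded by construction. Chain contiguity is not
pinned down by the source material; strict adjacency is the conservative
choice. Jam-period durations use the same first-to-last-frame anchors as
the protocol, which is what brings the two detectors' corrected
frequencies within a factor ~2 of each other across 5–50 nM.

The analytic amplification estimate for the number of motors affected by
one pause of duration T is N = TV/(g − V/ν) with V in sites/s and mean gap
g = 1/ρ − 2 (jammed motors keep their two-site footprint) or 1/ρ − 1
(compact, single-site packing); the per-step probability of being caught in
a period is then p_inactivation(1 + N). N is finite for ρ < 1/2 and grows
like 1/(1−2ρ) toward full decoration.

## Fitting

ν, ω_D, λ₀ are anchored at low concentration; (ω_a, θ) are estimated by
minimising Σ((model − data)/SE)² over the present cells of a concentration
series of run length, dwell time, velocity, and landing rate. The optimiser
is bounded Nelder–Mead with 8 seeded log-uniform starts and a tight polish
(xatol 1e−11); bounds are ω_a ∈ [1e−5, 2] nM⁻¹s⁻¹, θ ∈ [1e−4, 50] s⁻¹. A
dataset whose concentrations cannot produce crowding (density below 0.02
even at the upper ω_a bound) is rejected as non-identifiable in θ. Missing
cells are skipped, never imputed. A full five-parameter fit is not exposed:
the fixed/fitted split is part of the method being implemented.

The synthetic generator evaluates the mean-field curves on a concentration
grid (default 1–100 nM, spanning the pre- and post-saturation regimes) and
adds independent Gaussian noise of s.d. rel_noise × value, with the SE
column set to that s.d. (default rel_noise = 5%, a typical experimental
error). What it emulates — and does not: curves follow the mean-field
model exactly, so recovery tests certify the estimator (noise-free
recovery to ≤1e−4 relative; at 5% noise the 100-replicate mean is within
~2 SE of truth) but cannot detect model misspecification against real
kymograph-derived data; noise is independent across cells, whereas real
observables share motors and are correlated; SEs are exact rather than
estimated. Reproducing the published (ω_a, θ) themselves requires the
original data, which users must supply as a digitised CSV.

## Problem sizes in tests and the acceptance script

Analytic checks run at full precision. Stochastic checks use rings of
120–2000 sites and windows of 12–8000 s (dimensionless runs use ν = 1)
chosen so Monte-Carlo errors sit at the few-percent level — the precision
at which the reproduced claims are stated. Observable comparisons against
the mean-field curves use experimental-like sample sizes (250 motor runs,
tracer-landing counts from a 128-filament assay equivalent) so that "within
3 SE" tests the agreement claim rather than the mean-field factorisation
error, which any sufficiently long exact simulation would resolve. The
pause-progression experiment uses the full 2000-site ring over 5–50 nM with
40 s windows, ~20k detected periods in total.

## Known limitations

- Strictly 1D: no side-stepping, no off-axis displacement component, and
  hence no angle criterion; multi-protofilament and open-boundary transport
  (boundary-induced phases) are out of scope.
- Mean-field accuracy degrades beyond θ ≈ 0.1ν (correlations between
  neighbouring dimers are only captured through the local factor).
- The pausing mechanism is phenomenological (two-state switching); the
  molecular origin is not modelled beyond the weak-state fraction
  f = ω_D/θ ≈ 0.22 derived from the fitted rates.
- The detection protocol's behaviour on real (continuous, noisy) data
  differs from integer-lattice trajectories exactly at the d = d_c
  boundary; both progression measures are reported so either convention
  can be consumed downstream.
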