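# Methods

## Models

The package implements three interpretable model families for the core
ADHD symptom domains, together with simulation, estimation and
validation machinery.

**Inattention facets.** Sustained attention, attention to detail and
mental effort are treated as one parameterized family: a level that
decays exponentially from `initial_level` with an effective rate
modulated by task context,

```
level(t) = initial_level · exp(−rate_eff · t)
rate_eff = base_rate · (1 + k_M·M) / (1 + k_R·R)
```

Monotony `M` accelerates the decay; perceived reward `R` protects
against it. The three facets share this functional form and differ only
in their parameter values, so they are a single `DecayParams` type with
a facet label rather than three code paths.

**Hyperactivity.** Motor activity oscillates around a baseline with an
amplitude suppressed by contextual constraints:

```
H(t) = baseline + A(context) · sin(ω·t + φ)
A    = max_amplitude / (1 + k_C·C + k_E·E + k_RC·R_C)
```

with cognitive demand `C`, environmental demand for stillness `E`, and
reinforcement of calm behaviour `R_C`. The sinusoid is an acknowledged
first-order idealization of rest–activity cycling; observed data add
stochastic noise on top (below). `H(t)` is a latent level and may go
negative when the amplitude exceeds the baseline; clamping, if wanted,
is an observation-layer option, never applied to the latent state.

**Impulsive choice.** A delayed reward's subjective value follows the
hyperbolic discount `V = A / (1 + k·D)`; the probability of taking the
smaller-sooner reward (SSR) over the larger-later one (LLR) is the
softmax/logistic

```
P(SSR) = 1 / (1 + exp(β · (V_LLR − V_SSR)))
```

`k` is the impulsivity readout (higher = steeper discounting), `β` the
choice consistency (0 = coin flip). One `k` is fitted per dataset; we do
not model task-specific discount rates.

Two presentational ambiguities in the source equations were resolved in
favour of internal consistency: the SSR value is always
`A_SSR/(1+k·D_SSR)` with `D_SSR = 0` in the standard battery (which
reduces it to the bare amount), and the oscillation's baseline and
effective amplitude are distinct quantities exactly as the displayed
`H(t)` equation has them.

## Units and scales

Task/hyperactivity time is in minutes, reward delay in days; these are
conventions recorded in file metadata, never converted implicitly.
Context covariates are dimensionless and nonnegative; `[0, 1]` is the
recommended working range and the one used by all shipped defaults. The
model is scale-covariant in the covariates (sensitivities absorb
rescaling), so only nonnegativity is enforced.

## Simulation

Context is piecewise-constant over a `ContextSchedule`. Decay dynamics
are state-continuous across segment boundaries: the level carries over
and only the rate switches, i.e. the trajectory solves
`dA/dt = −rate_eff(t)·A` with a piecewise-constant coefficient, reducing
exactly to the closed form on a single segment. A segment can be marked
`reset=True` to model a fresh task start (level snaps back to
`initial_level`); this is also how separate lab-style "sessions" are
represented. The oscillation's phase argument `ω·t + φ` is global in
time — context modulates amplitude only, so phase never resets at a
boundary.

Observation noise is additive i.i.d. Gaussian on the observations (the
latent state stays deterministic), with an optional clamp at zero for
observed activity. Noise is available on every stream; the default is
noise-free. Choices are Bernoulli draws from the softmax probability.
Every stochastic call takes an explicit seed and builds its own
`numpy.random.Generator`; nothing touches global RNG state.

## Estimation

**Decay (bounded NLS).** Free parameters `(initial_level, base_rate,
k_M, k_R)`, either sensitivity optionally fixed. Identifiability is
checked before fitting: with all four free, the data must span ≥ 3
distinct `(M, R)` conditions with variation in both covariates,
otherwise an `IdentifiabilityError` is raised rather than returning
unstable estimates. Initialization: per-condition log-linear regression
of `log(max(y, floor))` on `t` gives per-condition rates; the identity
`rate = b + b·k_M·M − k_R·R·rate` is linear in `(b, b·k_M, k_R)` and is
solved by ordinary least squares to seed the optimizer. The fitter
accepts either session-style data (each condition starts at the initial
level) or, given the schedule, the chained piecewise model.

**Hyperactivity (bounded NLS).** Baseline seeded by the sample mean;
angular frequency by the dominant Lomb–Scargle peak (parabolically
interpolated) scanned between one cycle per record and the Nyquist
limit of the grid; amplitude and phase by a sin/cos linear regression,
refined from eight equispaced phase starts. When contexts vary,
per-context amplitudes `A_j` are inverted through
`1/A_j = (1 + Σ k_x·x_j) / H_max` — linear in the scaled sensitivities —
to seed `H_max` and the `k`s; sensitivities of non-varying covariates
are fixed at zero, and with no variation at all the fit collapses to a
single free amplitude and says so in its result. Records shorter than
one full cycle set an `unreliable` flag instead of raising.

**Discounting (MLE).** Bernoulli log-likelihood of the softmax model,
maximized by L-BFGS-B with an analytic gradient from a fixed multi-start
grid (6 log-spaced discount rates × 3 consistency decades).
Probabilities are floored at 1e−12 inside logs. The response may be the
recorded binary choice (default) or the stored softmax probability; the
latter turns the objective into a cross-entropy whose optimum is exactly
the generating parameters, and is the package's "noise-free" recovery
route — binary choices are irreducibly stochastic, so exact recovery is
only defined against the probabilities. Degenerate all-one-option
datasets are flagged (`all_ssr`/`all_llr`) with boundary estimates,
never presented as interior optima.

Bounds: rates and `k` in `[1e−6, 1e3]`, sensitivities and `β` in
`[0, 1e3]`, `ω` between one cycle per record and `π/Δt_min`. Optimizer
tolerances are 1e−14 (NLS) and 1e−15/1e−12 (MLE ftol/gtol). All start
grids are fixed, so fits are deterministic given data.

**Parameter recovery.** `parameter_recovery` simulates with child
generators spawned from a master `SeedSequence`, fits each replicate,
and reports per-parameter bias, relative bias and RMSE; fit failures are
recorded per replicate, not raised. Phase is compared on the circle
(wrapped difference), so a true phase near 0 or 2π is not penalized.

## Synthetic cohort

`generate_ema_dataset` emulates an EMA wave: per-subject parameters
drawn from group priors, shared segment boundaries with per-subject
uniform `[0,1]` context draws, all four symptom streams plus a shared
deterministic choice battery, and MCAR row deletion at a configurable
rate. Child seeds are spawned deterministically per (group, subject,
stream), so any subject regenerates in isolation.

The shipped priors are synthetic conventions, not empirical estimates:
lognormal with medians chosen at plausible orders of magnitude
(control-like `base_rate` 0.02/min vs ADHD-like 0.06/min; discount rate
0.01/day vs 0.05/day; larger hyperactive amplitude in the ADHD-like
group), and a uniform phase. What the generator deliberately does not
emulate: informative (non-MCAR) missingness, within-subject parameter
drift, autocorrelated or heteroscedastic noise, cross-domain symptom
interactions, and any calibration to real patient data. Passing tests
therefore certify the estimation machinery under the models' own
assumptions — they are not evidence about real ADHD populations.

## Validation surfaces and problem sizes

The test suite checks closed-form identities over 1000 random draws at
1e−12; optimizer dominance over exhaustive bounded grids (11⁴ nodes for
decay, 51² for discounting) on fixed seeded datasets; exact (≤ 1e−6
relative) noiseless recovery for all three families on rank-sufficient
designs; stochastic recovery (decay: sd 0.05, 3 conditions × 20 points;
discounting: 500 battery trials; 200 replicates each) with headline
relative bias under 5%; simulator fidelity (binomial 3·SE bound at
n = 10 000, sinusoid RMS = amplitude/√2 within 1% over 12 periods, MCAR
retention within 3·SE); and byte-identical CLI reruns. The in-suite
group-separation check uses 15 subjects per group (40 in the acceptance
script) with probability-response fits, sizes chosen to keep the default
run fast; the fitted ADHD/control median discount-rate ratio sits around
4–6×, far from the decision boundary.

## Known limitations

- The sinusoid is a strong idealization; real actigraphy shows
  broadband, nonstationary rest–activity structure.
- Frequency estimation inherits Lomb–Scargle's resolution; designs with
  under ~2 observed cycles are flagged but will fit poorly.
- The decay fitter's log-linear initialization needs positive
  observations; heavy noise near zero degrades the seed (the bounded
  optimizer usually still converges).
- One discount rate per dataset; real/hypothetical task differences are
  not modelled.
- MCAR is the only missingness mechanism.
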