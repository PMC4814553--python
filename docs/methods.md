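# Methods

This note documents the models, estimators, and design choices behind
`perceptdcm`: a pipeline for studying age-dependent top-down control of
bistable perception with dynamic causal models (DCMs) for fMRI.  Because the
human cohort that motivates the pipeline is not publicly deposited, every
stage operates on synthetic data generated under known ground truth, and all
quantitative claims are recovery or calibration properties.

## Experimental design being modeled

A session is three concatenated blocks with no run breaks: Block 1 — six
60-s presentations of the ambiguous Rubin face–vase figure, each followed by
6 s fixation; Block 2 — sixteen 16-s presentations of a non-ambiguous,
face-biased version of the figure ("training"), each followed by 4 s
fixation; Block 3 — identical to Block 1.  Total 1112 s; BOLD is sampled at
TR = 2 s (556 samples).  During ambiguous trials subjects report their
current percept (faces or vase) by button press at every perceptual switch.
The 2000-ms window immediately preceding each press is the *pre-switch
event*; it serves as the modulatory input to the DCMs, truncated at the
trial onset when a press occurs less than 2 s into a trial.

## Neuronal and hemodynamic forward model

Four regions — lingual gyrus (LIN), precuneus (PRE), middle temporal gyrus
(MTG), inferior orbitofrontal cortex (IOF) — are reciprocally coupled except
between MTG and IOF.  Neuronal dynamics are bilinear:

    dz/dt = (A + Σ_j u_j B^(j)) z + C u_driving + w(t),

with A the intrinsic coupling (Hz), B^(j) the gating of connections by the
two pre-switch inputs (Block 1 and Block 3), C the driving effect of the two
ambiguous-block boxcars on every region, and w(t) endogenous neuronal
innovations (the "stochastic" part of the generative model).
Self-connections are parameterized as −0.5·exp(θ) Hz so negativity (local
stability) is structural.

Each region's activity drives a balloon–Windkessel cascade — vasodilatory
signal s, inflow f, venous volume v, deoxyhemoglobin q:

    ds/dt = z − κs − γ(f−1)         df/dt = s
    τ dv/dt = f − v^{1/α}           τ dq/dt = f·E(f,ρ)/ρ − v^{1/α} q/v,

with E(f,ρ) = 1 − (1−ρ)^{1/f}, and the nonlinear BOLD readout
y = V0 (k1(1−q) + k2(1−q/v) + k3(1−v)) with k1 = 7ρ, k2 = 2, k3 = 2ρ−0.2
(classical 1.5T-style coefficients).  Defaults: κ = 0.64 s⁻¹, γ = 0.32 s⁻¹,
τ = 2.0 s, α = 0.32, ρ = 0.32, V0 = 0.04; κ and τ carry per-region
log-scaling free parameters at inversion time.

**Integration.**  Euler–Maruyama on a microtime grid of TR/16 = 125 ms;
innovations enter the neuronal states only.  Deterministic simulation is the
innovation→0 limit of the same scheme, so the two are testably consistent.
The hemodynamic states f, v, q are integrated in log space (the drift of
log x is (dx/dt)/x).  This agrees with plain Euler to first order but makes
positivity structural, which matters twice: sustained deactivation can push
the plain-Euler inflow through zero, and the inversion routinely evaluates
candidate parameters far from the generating regime.  BOLD is read out at
the end of every TR window.

**Domain of validity.**  The balloon model has no steady state once
sustained neuronal activity drops below −γ (inflow would have to be
negative).  The synthetic-truth generator therefore rejects parameter draws
whose steady-state activity under any driving input — with or without the
pre-switch gating engaged — falls below −0.22 Hz.  This also bounds the
plausible magnitude of negative driving inputs: the generator uses −0.06 Hz
(with +0.2 Hz positive drive), not larger negative values, because 60-s
boxcar deactivation at stronger levels leaves the model's domain.

## Model space

Four candidate structures differ only in which connections the pre-switch
inputs may gate.  Bottom-up edges: LIN→MTG, LIN→IOF, PRE→MTG, PRE→IOF;
top-down edges: the four reverses.  Model 1: bottom-up gating pre-training,
top-down gating post-training.  Model 2: both directions in both blocks.
Model 3: bottom-up only.  Model 4: top-down only.  A and C structure is
shared, so models 1, 3, 4 have 38 free parameters and model 2 has 46 (plus
one shared observation log-precision).

## GLM and ROI extraction

The first-level GLM has nine task regressors (ambiguous Block 1/3 boxcars,
the non-ambiguous Block 2 boxcar, presses per block, and the pre-switch
windows of each block), convolved with a canonical double-gamma HRF
(response gamma shape 6, undershoot shape 16, ratio 6:1, 32-s support,
unit-sum normalization, 16 microtime bins per TR), plus six motion nuisance
columns and a constant.  F-contrasts use the extra-sum-of-squares form with
the reduced design obtained from the contrast's null space.

ROI series are the principal eigenvariate (first singular component, scaled
to the block's RMS amplitude, signed to correlate positively with the voxel
mean) of an 8-mm sphere's voxels after *effects-of-interest adjustment*:
the span of all no-interest columns (motion, presses, Block 2, constant) is
projected out orthogonally, keeping only the four ambiguous-block and
pre-switch regressor effects plus residuals.  The orthogonal-projection form
was chosen over subtracting fitted nuisance contributions because it
guarantees the adjusted data are exactly orthogonal to every removed
regressor; the cost is that task variance collinear with the removed columns
(e.g. pre-switch windows vs. the presses that end them) is removed too.

## Inversion: variational Laplace with AR(1) noise

The generative model is stochastic, but the estimator is deterministic
variational Laplace: endogenous fluctuations are absorbed by the
observation-noise model rather than estimated as states.  Innovations passed
through the hemodynamic low-pass are strongly autocorrelated — the lag-1
(TR = 2 s) autocorrelation of innovation-driven BOLD residuals is ≈ 0.8
under the generator's conditions — so the noise model is AR(1) with fixed
coefficient 0.8 and one shared log-precision hyperparameter with prior
N(4, 1/2).  Residual whitening is exact (first-sample scaling plus lag-1
differencing), and the AR log-determinant enters the free energy.

Priors: off-diagonal A ~ N(0, 1/16); B ~ N(0, 1/4); C ~ N(0, 1);
self-connection log-scaling ~ N(0, 1/16); log κ/τ scalings ~ N(0, 1/64);
masked-out entries are structural zeros (zero prior variance, excluded from
the free vector).

Optimization is Gauss–Newton ascent on the Laplace free energy with
Levenberg–Marquardt damping and monotone step rejection: a step is accepted
only if F increases; otherwise damping is increased eightfold (up to nine
attempts).  Model gradients are central finite differences (step 1e-4) of
the deterministic forward model, integrated as one batch of 2d+1
trajectories.  The log-precision is updated by a damped fixed-point
iteration of its stationarity condition (including the posterior-covariance
trace term) after every accepted step.  Convergence: |ΔF| < 1e-2 nats on
three successive accepted steps, or 64 iterations; if no damped step can
improve F the scheme is at a local maximum and stops.  Candidates whose
trajectories diverge are treated as rejected steps; if the curvature at an
accepted point cannot be evaluated the previous iterate is returned.

On a linear-Gaussian reduction (forward model replaced by a fixed linear
map, noise precision fixed) the scheme reproduces the conjugate closed-form
posterior, which is tested to 1e-3 relative accuracy.

**What the substitution preserves and what it does not.**  The original
stochastic-DCM estimators infer the innovation process jointly with the
parameters.  Absorbing innovations into AR(1) noise preserves the claims
this pipeline tests — model ranking by free energy and the sign/magnitude
structure of B and C at the group level (verified by the recovery studies)
— but per-subject estimates of weakly identified directions remain noisier
than a full stochastic treatment would give, and the innovation
spectrum itself is not estimated.

## Bayesian model selection and group statistics

Fixed-effects BMS sums log-evidences over subjects.  Random-effects BMS uses
the variational Dirichlet-multinomial scheme: responsibilities
u_nk ∝ exp(F_nk + ψ(α_k) − ψ(Σα)), α = α0 + Σ_n u_n, iterated to
|Δα| < 1e-6 with uniform prior concentration α0 = 1.  Exceedance
probabilities are Monte-Carlo estimates from 10⁶ seeded Dirichlet draws
(tolerance ≈ 0.01).  Per-subject winners are argmax responsibilities with
deterministic low-index tie-breaking.

Group tests follow the classical summary-statistic approach on posterior
means: one-sample two-sided t-tests against zero for connectivity
parameters (with Cohen's d = mean/sd), Welch two-sample tests between
cohorts for behavior and for the eight hemodynamic comparisons (decay and
transit-time log-scalings × four regions, uncorrected).

## Synthetic cohort: what it emulates and what it does not

**Behavior.**  Percept holding times are lognormal (heavy-tailed, as is
typical of bistable perception): base median 6 s for both percepts, sigma
0.6, with the first press following a lognormal latency (median 1.5 s).
Training scales the Block-3 face median by a cohort bias-ratio target —
1.5 for young (susceptible to the face bias), 0.85 for older (resisting it,
preferring the novel percept) — times a subject-level lognormal factor
(sigma 0.15).  Trials are resampled until every trial has ≥ 3 switches, so
generated cohorts pass the inclusion filter by construction.  These choices
put post-training mean face durations on the several-second scale with the
young/older ordering and a medium-to-large effect size; they do not claim to
reproduce any particular cohort's milliseconds.

**Connectivity ground truth (model-1 structure).**  Self-connections −0.5
Hz; bottom-up intrinsic coupling +0.15 Hz; top-down and LIN↔PRE coupling
+0.05 to +0.1 Hz.  Pre-switch gating: bottom-up +0.3 Hz in Block 1 for both
cohorts; in Block 3, top-down gating onto PRE (+0.3 young, +0.2 older) and —
only in the older cohort — the age-specific MTG→LIN modulation of +0.4 Hz.
The IOF→LIN gating is zero in both cohorts so that the LIN effect is
attributable to MTG; the young MTG→LIN entry is exactly zero (never
jittered), making "no modulation in the young" a true null.  The young
cohort must still carry *some* directional Block-1/Block-3 gating: a cohort
with all-zero B would make the four candidate models evidence-equivalent for
those subjects and model recovery undefined, so the young truth uses the
model-1 gating pattern with the MTG→LIN entry held at zero.  Driving
inputs: +0.2 Hz baseline; −0.06 Hz to LIN and PRE pre-training and to LIN
only post-training in the young cohort; −0.06 Hz to LIN and IOF
post-training in the older cohort.  Nonzero entries receive N(0, 0.05²)
between-subject jitter (structural zeros stay zero); κ and τ get ±10%
lognormal jitter; draws violating the steady-state plausibility bound are
rejected and redrawn.

**Noise.**  Neuronal innovations with diffusion scale 0.015 Hz^1/2 and
additive observation noise 0.0015 (BOLD units), giving effective SNR of a
few — enough endogenous fluctuation to exercise the stochastic machinery
while keeping the desk-scale studies informative.

**Not emulated:** volumetric images and spatial preprocessing, physiological
(cardiac/respiratory) noise, scanner drift, percept-duration dependence on
attention or eye position, and any within-session nonstationarity.  Passing
recovery tests therefore demonstrates the estimator and selection machinery
work under the model's own assumptions at realistic noise levels — not that
the original cohort's effect sizes are reproducible.

## Problem sizes and numerical choices

The recovery study uses 12 subjects (6 per cohort) at the full 556-sample
session and all four models; the behavioral study uses the full 14/16 cohort
sizes (press streams only).  These sizes keep the complete analysis in the
minutes range on one CPU while leaving all group tests well-powered for the
built-in effect sizes.  Other numerical choices: microtime grid TR/16
(shared by simulation, HRF convolution, and inversion); FD step 1e-4;
LM damping start 1e-4, ÷4 on acceptance, ×8 on rejection; divergence guards
at |z| > 1e6 and |log state| > 20; Dirichlet Monte-Carlo 10⁶ draws; all
randomness flows from named integer seeds (per-subject seeds derived from
the master seed via `SeedSequence` spawn keys).

## Known limitations

- The AR(1) absorption of innovations is an approximation; weakly identified
  modulatory directions show per-subject estimate spread of ~0.2 Hz under
  the default noise conditions (the group tests account for this).
- The effects-of-interest adjustment removes kept-task variance that is
  collinear with removed regressors (see above); eigenvariates should be
  compared against equally adjusted references.
- Finite-difference gradients make inversion cost scale linearly in the
  parameter count; analytic Jacobians would be the next optimization.
- The chi-square tests of initial-percept associations fall back to Fisher's
  exact test when expected cells drop below 1, with a flag.
- `R²` values on synthetic data (≈0.95+) are far higher than typical real
  ROI fits; the generator's noise floor is optimistic about scanner noise.
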