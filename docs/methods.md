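# Methods

`avci` implements a family of Bayesian observer models for an audiovisual
spatial task battery: unisensory visual (UV) and auditory (UA) localization,
bisensory causal judgment (BC, "same source or not"), and bisensory
localization of the visual (BV) or auditory (BA) stimulus.  This note records
the model, the numerical choices, and what the synthetic-data tests do and do
not establish.

## The observer model

On every trial the observer receives Gaussian-noisy measurements of the true
stimulus location(s) s (degrees of visual angle, response range [-45, 45]):

    x ~ N(s, sigma^2(s))

where sigma(s) is a symmetric, monotonically non-decreasing **sensory noise
function** per modality — homoskedastic `Const` (sigma(s) = sigma0),
saturating heteroskedastic `Exp` (sigma(s) = sigma0 + k1 (1 - exp(-k2 |s|))),
or a semiparametric pivot shape (free log-values at 12 fixed eccentricities
{0, 0.1, 0.3, 1, 2, 4, 6, 8, 10, 15, 20, 45} deg, cumulative-sum construction
for positivity and monotonicity, monotone cubic interpolation, mirror
symmetry).  Visual noise is scaled by alpha_med / alpha_low on medium/low
reliability trials and both modalities by beta_V / beta_A on bisensory trials.
Auditory measurements are multiplied by the range-recalibration gain rho_A
immediately after generation (full remapping of the [-15, 15] auditory onto
the [-20, 20] visual stimulus range corresponds to rho_A = 4/3); the observer
never corrects for this scaling downstream.

The observer holds a symmetric, centrally peaked **prior** p(s) over location
— `SingleGaussian`, `TwoGaussians`, `GaussianLaplace` (mixture of a Gaussian
and a central Laplace peak), or a semiparametric pivot shape (free
log-decrements, normalized over the response range).  The same supramodal
prior applies to both modalities.

Unisensory estimates are posterior means, s_hat(x) = E[s | x].  Reports add
Gaussian motor noise (SD sigma_motor) and lapse uniformly in [-45, 45] with
probability lambda.  Bisensory trials add the causal layer: with prior
probability p_same the cues share one source (C = 1).  The posterior
p(C=1 | xV, xA) combines the fused evidence integral against p(s) (C = 1) with
the product of single-cue evidences (C = 2).  The causal strategy maps the
posterior and the two conditional estimates (fused vs single-cue) to a
response: Model Selection takes the more probable hypothesis's estimate
(ties at exactly 0.5 count as C = 1, for determinism), Model Averaging takes
the posterior-weighted average, Probability Matching samples the hypothesis
with its posterior probability.  For BC, MS and MA coincide (report the more
probable hypothesis); PM reports "same" with probability p(C=1 | xV, xA).

Maximum-likelihood fits minimize the summed per-trial negative log likelihood;
models are compared by AIC = 2 NLL + 2k and BIC = 2 NLL + ln(N) k with N the
per-participant trial count of the fitted task scope.  Lifted semiparametric
fits freeze the 35 shape parameters estimated on unisensory data and refit the
9 context parameters (alpha_med, alpha_low, lambda, sigma_motor, rho_A,
p_same, beta_V, beta_A, and a prior exponent gamma) on all tasks; their
complexity can be counted excluding (9) or including (44) the frozen shapes.

## Numerics

All integrals use the trapezoidal rule.  Defaults (`GridSpec`):

- hypothesis grid: 721 points on [-45, 45] (0.125 deg) — fine enough to
  resolve fitted sigma0 well below 1 deg;
- per-trial measurement nodes: center +/- 5 sigma, 201 nodes (unisensory), 61
  per modality (bisensory localization), 161 for BC (the MS/MA indicator
  integrand converges only linearly in node spacing); node weights are
  renormalized so the truncated Gaussian sums to 1;
- shared measurement tables: s_hat(x) on a 0.25-deg grid over [-90, 90];
  bisensory tables (causal posterior, fused mean, single-cue means) on
  0.5-deg grids, the auditory axis pre-scaled by rho_A; per-trial values by
  linear/bilinear interpolation.

Halving every spacing changes reported probabilities by < 1e-3 (tested).
Priors are normalized on a fixed non-uniform grid (0.0000625-deg-scale steps
near the center) because the Laplace cusp and steep semiparametric shapes
defeat a uniform grid; unit mass holds to 1e-6 on an independently refined
grid.  Parametric priors are renormalized over the bounded response range so
every prior family shares one contract (truncation mass is negligible at
fitted scales).  Per-trial densities are floored at 1e-300 before the log.
The motor-noise Gaussian is untruncated; out-of-range responses are handled by
the load-time discard rule (they were 0.0404% of collected trials in the
experiment), not by the model.

Interpolation of semiparametric shapes uses a shape-preserving monotone cubic
(PCHIP) rather than an unconstrained cubic spline: the monotonicity of sigma
and p is an explicit model assumption and unconstrained splines can violate it
between knots.

## Fitting

Parameters are warped to unconstrained internal coordinates (sigmoid on a log
axis for scale parameters, logit for probabilities, linear otherwise) inside
generous bounds (e.g. sigma0, sigma_motor in [0.05, 30] deg; multipliers in
[0.2, 10]; rho_A in [0.5, 2]; gamma in [0, 5]).  The optimizer contract is a
bound-free derivative-free local search; the default is scipy's Powell with a
short second pass from the first optimum (resetting Powell's direction set
reliably un-sticks stalled line searches).  Start points are drawn from a
screened pool — a moment-based data-driven start (response-slope and
residual-SD heuristics), flat-function starts for semiparametric shapes, a
fixed heuristic, and Latin-hypercube draws within bounds — ranked by one NLL
evaluation each; the best ``n_starts`` are optimized.  The model-recovery
harness fits candidates in order of increasing complexity and adds the
embedded optima of already-fitted nested sub-models (Const in Exp via k1 at
its lower bound; SingleGaussian in the mixture priors via omega at its lower
bound) to the screening pool, which enforces the nesting inequality cheaply.
BADS/CMA-ES (used in the original study) are not available in this
environment; Powell is slower per basin but adequate at the scales exercised
here, and the optimizer is pluggable.

## Synthetic data and what the tests establish

The trial generator reproduces the experiment design: 15 participants, 500 UV
+ 500 UA + 1000 bisensory-localization (BV/BA split 50/50) + 1000 BC trials,
auditory locations uniform on the 7 speakers {0, +-5, +-10, +-15} deg, visual
locations uniform on [-20, 20], same-location probability 0.5, three
equiprobable visual reliability levels.  The response simulator is a
sampling-path implementation that shares only the posterior-mean quadrature
with the likelihood engine, so binned agreement between the two (chi-square,
alpha = 0.01, 1e5 responses per task x strategy condition) cross-validates
both.

Synthetic groups draw each parameter from evenly spaced values over ranges
chosen to mimic a plausible cohort (e.g. rho_A in [1.1, 1.5] around the 4/3
remapping value, beta_A > beta_V > 1, central visual noise well below
auditory); values are permuted across participants with a seeded RNG.  These
ranges are package choices: the human cohort's fitted values are not
deposited, so green recovery tests establish that the *pipeline* identifies
models and parameters in a world like this one — not that the published
cohort values are reproduced.  Weakly identified parameters (k2, the mixture
weight omega, gamma) are reported by the recovery harness but excluded from
pass/fail thresholds.

Known identifiability limits: at 1000 unisensory trials, the central visual
noise sigma0_V trades off against sigma_motor and the prior's central peak;
its maximum-likelihood estimate has participant-level error comparable to
plausible between-participant spread, so rank-correlation checks on sigma0_V
are the most fragile part of scaled-down recovery.  Similarly, with the
default generator ranges the Gaussian-Laplace mixture prior adds only a few
nats of log-likelihood per participant over a single Gaussian, so BIC — which
charges ln(N) per extra parameter — can prefer the nested Gaussian-prior
model on data generated by the mixture model at desk scale, even though all
noise-family distinctions recover decisively.  A cohort with a sharply
expressed central peak (small Laplace scale, high mixture weight) separates
the prior families far more strongly.  The recovery fits use coarser grids (0.25-deg hypothesis grid)
whose NLL differs from the default grids by ~1e-3 per 1000 trials — far below
recovery tolerances.

## Scaled-down test tiers

The full-scale recovery analyses (15 simulated participants, full restart
budgets) take many CPU-hours.  The shipped tests run reduced versions:
parameter recovery with 5 participants x 1000 unisensory trials and 2
restarts; model recovery over the 4-candidate unisensory subset
{Const-SingleGaussian_1, Const-GaussianLaplace, Exp-SingleGaussian,
Exp-GaussianLaplace} with 3 participants x 600 trials and 1 restart.  The
same harness functions run the full-scale analysis by passing the 15-
participant design and a larger `n_starts`/`budget`.

## Limitations

- Shapes are static, symmetric, and centered; no asymmetric or non-monotone
  noise, no dynamic priors, no circular statistics (the task range is narrow).
- Only posterior-mean estimators and the three standard causal strategies are
  implemented; no heuristic decision rules.
- The BC efficiency tables assume the causal posterior varies smoothly on a
  0.5-deg measurement grid; extremely small fitted noise (< ~0.3 deg) in a
  bisensory context would need finer `m_table_step`.
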