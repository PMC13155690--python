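# avci — Bayesian observer models for audiovisual causal inference

`avci` is a Python library for modeling how people localize audiovisual
stimuli and judge whether a flash and a beep came from the same place.  It is
aimed at computational psychophysicists who want to fit ideal-observer models
with realistic assumptions — eccentricity-dependent sensory noise and
non-Gaussian spatial priors — to trial-level data from a five-task battery:

- **UV / UA** — unisensory visual / auditory localization,
- **BC** — bisensory causal judgment ("same source or different?"),
- **BV / BA** — bisensory localization of the visual or auditory stimulus.

## The model

The observer receives noisy measurements `x ~ N(s, σ²(s))` of the true
location `s` (degrees of visual angle), with a per-modality noise function
σ(s) that may be constant (`Const`), saturating-exponential
(`Exp`: σ(s) = σ₀ + k₁(1 − e^{−k₂|s|})), or a 12-pivot semiparametric shape.
They combine measurements with a symmetric central prior p(s) — Gaussian,
two-Gaussian mixture, Gaussian–Laplace mixture, or an 11-parameter
semiparametric shape — and report posterior means corrupted by motor noise
(σ_motor) and lapses (λ).  On bisensory trials the observer infers whether
the cues share a common cause (prior p_same) and maps the causal posterior
`p(C=1 | x_V, x_A)` to a response with one of three strategies: **Model
Selection**, **Model Averaging**, or **Probability Matching**.  Context
effects include visual-reliability noise scalings (α_med, α_low),
unisensory-to-bisensory noise inflation (β_V, β_A), and an auditory range
recalibration gain ρ_A that stretches auditory measurements toward the wider
visual range (full remapping ⇒ ρ_A = 4/3).

Models are fitted by maximum likelihood (multi-start derivative-free
optimization over transformed parameters) and compared with AIC / BIC; the
package includes the full model registry (7–40 free parameters per model),
the "lifted" semiparametric workflow (freeze unisensory shape fits, refit 9
context parameters on all tasks), simulation-based model- and
parameter-recovery harnesses, and the binned behavioral summaries (bias, SD,
"same"-rate vs disparity curves) used to visualize fits.

## Worked example

```python
from avci import ExperimentDesign, make_simulated_group, fit_mle
from avci.recovery import RECOVERY_GRIDS
from avci.zoo import aic_bic

design = ExperimentDesign(n_participants=1,
                          trials_per_task={"UV": 500, "UA": 500})
group = make_simulated_group("Exp-GaussianLaplace", {}, design, seed=3)

fit = fit_mle("Exp-GaussianLaplace", group.trials, n_starts=2, seed=1,
              grids=RECOVERY_GRIDS)
aic, bic = aic_bic(fit.nll, fit.n_params, fit.n_trials)
print(f"NLL {fit.nll:.1f}  AIC {aic:.1f}  BIC {bic:.1f}")
print(f"rho_A true {group.params[0]['rho_A']:.2f} "
      f"fitted {fit.params['rho_A']:.2f}")
```

Output:

```
NLL 3014.7  AIC 6057.3  BIC 6126.0
rho_A true 1.30  fitted 1.31
```

The fitted NLL sits slightly below the NLL at the generating parameters
(3017.6), as it should at finite trial counts, and the auditory recalibration
gain is recovered within a few percent of its generating value.  The
`examples/` directory walks through each capability: simulating the
experiment, inspecting engine predictions, fitting and comparing models, and
running the recovery harnesses.

## Acceptance script

`scripts/acceptance.py` runs the pipeline end to end — it simulates a small
synthetic group from the Exp-GaussianLaplace-PM observer, evaluates the
likelihood engine on the simulated trials, fits the vanilla
(Const-SingleGaussian) observer to one participant's unisensory data, prints
the resulting NLL/AIC/BIC and behavioral summaries, and writes its JSON
output:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/avci/
  design.py     experiment design, stimulus sampling, trial-table CSV I/O
  shapes.py     prior and noise shape families (parametric + semiparametric)
  engine.py     trapezoid-quadrature likelihood engine for all five tasks
  simulate.py   sampling-path response simulator and synthetic groups
  fitting.py    NLL, parameter transforms, multi-start MLE, lifted fits
  zoo.py        model registry/naming, AIC/BIC, group comparison tables
  recovery.py   model- and parameter-recovery harnesses
  summaries.py  binned behavioral summaries (data and model, one code path)
  config.py     run configuration and reproducible seed derivation
docs/methods.md   model assumptions, numerics, and known limitations
```
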