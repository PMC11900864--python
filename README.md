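# thermolearn

Computational analysis of **probabilistic thermosensory learning**: how people
learn volatile cue–stimulus associations between auditory tones and thermal
stimuli, and how that learning shapes perception of the **thermal grill
illusion (TGI)** — the burning sensation evoked by interleaved innocuous warm
and cold stimulation.

The package is a self-contained, reproducible pipeline for researchers in
computational psychiatry / perceptual decision-making who want to

* simulate the probabilistic thermosensory reversal-learning task (306 trials;
  82 / 50 / 18 % cue–stimulus contingencies with unpredictable reversals;
  43 % cold, 43 % warm, 14 % TGI stimuli; VAS ratings on ~47 % of trials),
* simulate agents with known ground truth (choices, response times, ratings),
* fit trial-wise learning models to binary predictions — a **two-level
  Hierarchical Gaussian Filter (HGF)** and three competitors
  (Rescorla–Wagner, Sutton K1, Pearce–Hall),
* compare models across subjects with **random-effects Bayesian model
  selection** (Dirichlet variational scheme, exceedance probabilities),
* compute the behavioral and perceptual indices: post-prediction-error
  slowing, perceived TGI quality ratio, TGI responsiveness, and the
  uncertainty modulation of TGI index (UMTI), with a zero-one-inflated beta
  (ZOIB) likelihood for bounded VAS ratings.

## The model

Beliefs about the cue–stimulus mapping evolve on two levels. The contingency
input is u<sub>t</sub> ∈ {0, 1} on innocuous trials (which mapping held) and
u<sub>t</sub> = 0.5 on TGI trials (simultaneously cold and warm). With
ŝ<sub>t</sub> = S(μ₂<sup>t−1</sup>), S(x) = 1/(1+e<sup>−x</sup>), the
canonical two-level binary HGF updates per trial

    π̂₂ = 1 / (1/π₂^{t-1} + e^ω)          volatility inflation
    π₂^t = π̂₂ + ŝ_t (1 − ŝ_t)            precision update
    μ₂^t = μ₂^{t-1} + (u_t − ŝ_t) / π₂^t   precision-weighted prediction error

ω is the log-volatility step size (larger ω → faster updating).
**Prediction uncertainty** is the first-level Bernoulli variance
ŝ(1−ŝ) = 1/π₁; **estimation uncertainty** is 1/π₂. A stripped `paper`
variant without the volatility-inflation step is included for audit; its
precision is non-decreasing, so it cannot keep tracking reversals.

The response model converts beliefs to choice probabilities through the
inverse decision temperature ζ:

    p(choice = 1) = ŝ^ζ / (ŝ^ζ + (1−ŝ)^ζ)

Subject-level fitting is MAP in unconstrained space with weakly informative
Gaussian priors and a Laplace approximation to the log model evidence; group
comparison uses the classical random-effects Dirichlet scheme.

## Worked example

```bash
thermolearn run-all --subjects 6 --seed 11 --out demo
```

simulates six HGF agents on the counterbalanced task, fits the HGF and
Rescorla–Wagner models to each, runs group BMS, and computes all indices.
Output printed by the run:

```
thermolearn run report
======================

subjects: 6  models: hgf2, rw  seed: 11
  stage simulate  seed=2056454946  elapsed=0.06s
  stage filter    seed=624777416   elapsed=0.03s
  stage fit       seed=624089720   elapsed=1.17s
  stage compare   seed=1181105624  elapsed=0.07s
  stage metrics   seed=26578532    elapsed=0.05s

group BMS exceedance probabilities:
  hgf2   0.987
  rw     0.013
winning model: hgf2

group metrics (means):
  mean_error_rate_after_neutral     0.5154
  mean_error_rate_after_predicted   0.3658
  mean_error_rate_after_tgi         0.3861
  mean_error_rate_after_unpredicted  0.4472
  mean_missing_fraction             0.0169
  mean_rt_after_neutral             1.2431
  mean_rt_after_predicted           1.2567
  mean_rt_after_tgi                 1.2396
  mean_rt_after_unpredicted         1.3006
  mean_tgi_quality_ratio            0.4704
  mean_tgi_responsiveness           49.3107
  mean_umti                         1.2612

33 files written (SHA-256 in report.json)
```

Reading the numbers: BMS correctly prefers the generating model (HGF
exceedance 0.987). Predictions are more often wrong after an expectation
violation than after a confirmed prediction (0.447 vs 0.366), and responses
are slower after violations (1.30 s vs 1.26 s) — post-prediction-error
slowing. The TGI quality ratio near 0.5 means the grill felt about equally
cold and warm; TGI responsiveness of +49 VAS points marks strong illusory
burning; the positive group-mean UMTI reflects the simulated coupling
between estimation uncertainty and TGI burning ratings.

Every run is fully determined by the master seed: per-stage seeds are split
from it, and `report.json` records SHA-256 checksums of every output file
(re-running with the same seed reproduces them byte for byte).

## Layout

| module | contents |
| --- | --- |
| `thermolearn.synthetic_data` | task config, contingency schedules, trial realization, agent simulation, cohorts |
| `thermolearn.learning_models` | HGF (canonical + paper variants), RW, K1, PH filters; uncertainty extraction |
| `thermolearn.inversion` | response model, MAP fitting, Laplace evidence, parameter/model recovery |
| `thermolearn.model_comparison` | random-effects BMS, exceedance probabilities |
| `thermolearn.behavior_metrics` | trial labels, error rates, RT slowing, TGI indices, UMTI, ZOIB regression |
| `thermolearn.pipeline` / `thermolearn.cli` | orchestration, dataset IO, `thermolearn` command |

See `docs/methods.md` for the modeling assumptions, parameter conventions,
and known limitations.
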