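# Methods

This note documents the generative model of the synthetic task, the learning
models and their inversion, the group-level model comparison, the perceptual
indices, and the numerical and design choices behind them.

## Task generator

The probabilistic thermosensory learning task couples an auditory cue (low
400 Hz / high 1600 Hz tone) to a thermal outcome. The realized cue–stimulus
mapping on a trial is coded by the contingency input `u`: `u = 1` means
low-tone→warm / high-tone→cold, `u = 0` the opposite mapping, and `u = 0.5`
codes thermal-grill (TGI) trials, which are simultaneously cold and warm and
therefore carry no mapping information beyond ambiguity.

**Schedule.** Contiguous blocks alternate between predictive (82 % or 18 %)
and chance-level (50 %) contingency; successive predictive blocks flip
between 82 % and 18 %, which constitutes a reversal. The original block
layout is not public, so block lengths are drawn uniformly from configured
ranges — stable 20–40 trials, chance 10–20 trials by default — which
preserves the described statistical structure (unpredictable reversals
separated by chance blocks) without inventing a specific unpublished
sequence. Reversal positions are recorded in the output. The two
counterbalanced sequence variants share the block layout with predictive
probabilities mirrored (82↔18); cohorts alternate variants A, B, A, …

**Trial realization.** Trial counts follow the published composition
exactly: the TGI count is `round(0.14 · n)` (half-away-from-zero; 43 of 306),
and the remaining innocuous trials split as evenly as possible between cold
and warm, the odd trial going to cold (132/131 at defaults). TGI positions
are uniform at random. On innocuous trials the mapping is drawn
`u ~ Bernoulli(p_block)` and the cue is then derived from (stimulus,
mapping). Deriving the cue rather than the stimulus keeps both the exact
43/43/14 stimulus mix and the nominal block contingency; the cue remains
uniform in expectation (it is a deterministic function of two balanced
draws), which is the one place the generator trades literal cue-first
sampling for exact design composition. Rating flags cover all TGI trials
plus a random subset of innocuous trials so the overall rated fraction is
`round(0.47 · n)` = 144; the implied innocuous rated fraction is ≈ 38 %,
the only allocation consistent with rating all 14 % TGI trials and 47 %
of trials overall.

**Agents.** A simulated agent runs one of the perceptual filters over `u`
and emits:

* *choices* through the response model (below), omitted independently with
  probability `missing_rate` (default 0.02; the stimulus is delivered
  regardless, so missing trials still drive the filter);
* *response times* from Gamma(shape = 8) with log-link mean
  `exp(log 0.8 + 2.0 · prediction uncertainty)` seconds, capped at the 3 s
  deadline — slower when the upcoming outcome is uncertain;
* *VAS ratings* (0–100, only on rated trials) from a zero-one-inflated beta
  model on the 0–1 scale. Logit-scale means start from stimulus-specific
  intercepts chosen to reproduce TGI phenomenology (TGI rated both cold and
  warm, with elevated burning relative to innocuous stimuli). Two
  generative couplings carry the directional effects the analysis chain is
  meant to recover: the factual scale on innocuous trials (cold rating on
  cold trials, warm on warm) is shifted by
  `1.5 · (p̂(delivered) − 0.5)` — precise congruent expectations increase
  factual ratings — and burning on TGI trials is shifted by
  `4.0 · estimation uncertainty`. Precision φ = 12, inflation masses
  p₀ = 0.04, p₁ = 0.01.

These defaults define the synthetic study conditions used throughout the
tests. What they emulate is the *generative structure* the analyses assume;
they do not emulate sensitization/habituation over the session, temperature
calibration differences, rating drift, or non-independent missingness, so
passing tests demonstrate correctness of the machinery on well-specified
agents, not robustness to every real-data pathology.

## Learning models

All filters consume `u ∈ [0,1]` and expose the predictive probability
ŝ_t (before outcome t), the prediction error `u_t − ŝ_t`, and prediction
uncertainty ŝ(1−ŝ). Probabilities are clipped to [1e−8, 1−1e−8] to keep
likelihoods finite.

* **Two-level HGF** (`hgf2`). Canonical mode per trial:
  ŝ = S(μ₂), π̂₂ = 1/(1/π₂ + e^ω), π₂ ← π̂₂ + ŝ(1−ŝ),
  μ₂ ← μ₂ + (u − ŝ)/π₂, with μ₂⁰ = 0, σ₂⁰ = 1. ω (unbounded, default −3)
  inflates the predicted second-level variance each trial and is what makes
  volatility tracking possible; estimation uncertainty is 1/π₂. The
  `paper` mode omits the inflation step (π₂ ← π₂ + ŝ(1−ŝ)): ω then has no
  effect, π₂ is non-decreasing, and the filter progressively freezes — it
  is retained for auditing and as a regression contrast, not for fitting.
  In the printed form of the belief update the sigmoid's argument is the
  second-level mean; the filters apply S(μ₂) throughout.
* **Rescorla–Wagner** (`rw`): v ← v + α(u − v), α ∈ (0,1).
* **Sutton K1** (`k1`): gain k = e^β meta-learned at rate `mu_k1` from the
  correlation between the prediction error and a decaying update trace h
  (h⁰ = 0, β⁰ = ln 0.1); v is clipped into (ε, 1−ε).
* **Pearce–Hall** (`ph`): v ← v + κ·a·δ with associability
  a ← η|δ| + (1−η)a — surprising outcomes raise the effective learning
  rate.

The parameter domains are open intervals; the classical limit identities
(α→1 full update, α→0 no learning, η→0 fixed associability, `mu_k1`→0
reduction to RW) are exercised as limits at 1e−12 from the boundary.

## Inversion

The response model maps beliefs to choice probabilities,
`p = ŝ^ζ/(ŝ^ζ + (1−ŝ)^ζ)` (equivalently sigmoid(ζ·logit ŝ), the
numerically stable form used). ζ > 0 is the inverse decision temperature:
ζ→0 random, ζ = 1 probability matching, ζ→∞ argmax.

Per-subject estimation is MAP in transformed space (ω identity, ζ and
`mu_k1` log, α/η/κ logit) under weakly informative Gaussian priors:
ω ~ N(−3, 4²), log ζ ~ N(0, 2²), logit-scale rates ~ N(0, 1.5²),
log `mu_k1` ~ N(−2, 2²). These numbers are package defaults in the spirit
of weak informativeness, are overridable per call, and are recorded in
every fit result. Optimization is L-BFGS-B from the prior mean plus
jittered restarts (jitter SD 1 in transformed space; 8 restarts by default,
4 in the large recovery harnesses where the posterior is well behaved).
Choices on TGI trials are scored against the belief by default (the belief
update there sees `u = 0.5`); a switch excludes them. Subjects with more
than 10 % missing choices are rejected by default, mirroring the standard
exclusion rule.

Log model evidence uses the Laplace approximation
`log joint(MAP) + (d/2)·log 2π − ½·log det H` with a central-difference
Hessian (step 1e−4·max(1,|x|)). If H is singular, indefinite, or has
condition number above 1e10, the evidence falls back to a BIC-style
penalty `log joint − (d/2)·log n` and the result is flagged.

Recovery harnesses close the loop: `parameter_recovery` simulates and
refits over a grid (fit failures recorded per cell; sessions whose
recovered values collapse onto the prior are flagged non-identifiable
rather than crashing), and `model_recovery` cross-fits cohorts from every
model and tabulates per-subject winners, ties broken toward the model with
fewer free parameters.

## Group model comparison

Random-effects BMS treats model identity as a random effect: model
frequencies r ~ Dirichlet(α), fitted by the standard variational updates
(uniform prior α₀ = 1 per model)

    u_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα)),   α = α₀ + Σ_n u_nk

iterated to a 1e−6 change in α. Exceedance probabilities come from 10⁶
Dirichlet draws (seeded, chunked; sample counts below 1e5 are flagged).
Protected exceedance probabilities (adjusted by the Bayesian omnibus risk
computed from the variational free energies of the RFX model and the
equal-frequency null) are available but off by default. Results are
invariant to per-subject constants in the log evidences and equivariant
under model permutation; for two models the Monte-Carlo exceedance is
checked against the exact Beta tail probability.

## Behavioral metrics and perceptual indices

* **Trial labels.** An innocuous trial in a predictive (82/18 %) block is
  `predicted` when the delivered stimulus matches the subject's prediction,
  else `unpredicted`; 50 %-block innocuous trials are `neutral`; TGI trials
  are `tgi`.
* **Error rates** group each trial's correctness by the *preceding* trial's
  label (default). Grouping by a trial's own match-based label is
  degenerate — a `predicted` trial has zero error by construction — so the
  sequence grouping is the informative reading, consistent with how TGI
  trials enter the analyses (only as predecessors; they have no correct
  answer and are excluded from the error counts themselves). A block-level
  grouping (predictive vs neutral) is available via `by="block"`.
* **Post-prediction-error slowing**: response times grouped by the
  preceding label, plus a gamma GLM with log link (statsmodels) on the
  preceding-label dummies, reference level `predicted`.
* **TGI quality ratio**: per rated TGI trial, cold/(cold+warm), averaged
  per subject; trials with both ratings zero are skipped; 0.5 = thermal
  ambiguity.
* **TGI responsiveness**: mean TGI burning minus the larger of the mean
  innocuous cold and warm burning ratings; negative = non-responder.
* **UMTI** is computed as the per-subject OLS interaction coefficient of
  burning/100 on [1, tgi, estimation uncertainty, eu × tgi] over rated
  trials: the difference between the estimation-uncertainty slope on TGI
  burning and that slope on innocuous burning. Its exact published formula
  lives in a supplement that is not available, so this operational contrast
  — which isolates the TGI-specific uncertainty coupling and recovers the
  generative coefficient's sign — is this package's definition; results
  using it should cite the definition here. It requires at least 3 rated
  TGI and 3 rated innocuous trials, else the index is reported absent.
* **ZOIB regression**: point masses at 0 and 1 plus Beta(μφ, (1−μ)φ) on
  (0,1); logit links on μ, p₀, p₁ and log link on φ; maximum likelihood by
  L-BFGS-B, standard errors from the inverse numeric Hessian. VAS inputs
  are rescaled by /100; exact 0 and 100 map to the inflation masses. When
  no observation sits at a bound the corresponding inflation logit is
  capped at −15 and a separation flag is set. Mixed-effects (random
  intercept/slope) machinery is deliberately replaced by pooled
  fixed-effects fits and per-subject summaries: at desk scale this
  preserves the signs and approximate magnitudes of the tested effects
  while avoiding heavy random-effects dependencies; the per-subject →
  group-summary route plays the role of random intercepts.
* Binned uncertainty reports use nine equal-count bins.

All set-level indices are invariant to trial-order permutation; the
sequence analyses (error-by-preceding-label, RT slowing) are intentionally
not, and a test asserts that asymmetry.

## Reproducibility and problem sizes

Every source of randomness flows from an integer seed; stage seeds derive
from the master seed through `SeedSequence([master, crc32(label)])`, so
individual stages can be re-run independently and a fixed master seed makes
the full pipeline byte-identical (checked via SHA-256 manifests). The
recovery and selection studies shipped with the package use 306-trial
sessions with 20 repetitions per grid point (ω grid −6…−1, ζ grid 0.5…8,
α grid 0.05…0.6), a 30-subject cohort for group model selection, and a
16-subject cohort for the rating analyses — sizes chosen so the full suite
runs on a laptop-class single core in a few minutes while leaving the
measured correlations (≈ 0.96–0.99) comfortably away from their acceptance
floors.

## Known limitations

* MAP + Laplace, not full posterior sampling; evidence quality degrades for
  strongly non-Gaussian posteriors (the BIC fallback is flagged when the
  Hessian is unusable).
* No hierarchical (empirical-Bayes) group priors and no three-level or
  continuous-outcome HGF.
* The `paper` HGF variant is non-stationary by construction (freezing
  precision) and should not be used for fitting volatile sessions.
* The UMTI definition is operational (see above).
* The generator's ZOIB rating model shares one precision across stimulus
  types and scales; real rating data are likely more heteroscedastic.
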