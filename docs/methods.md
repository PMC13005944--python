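# Methods

## Model

The classifier is intentionally minimal: logits l = Θx with Θ ∈ ℝᵏˣᵈ,
softmax output, and no bias term. Features reaching the model are
z-scored, so the intercept is near-superfluous, and omitting it keeps the
Δweight interpretation exact (the decision between subtypes a and b
depends on sign((Θ(a)−Θ(b))·x) alone). Subtype indices are ordered by
prognosis: subtype 1 is, by convention, the best-surviving group, which
is what gives the reward its sign.

Per training episode (full batch, no minibatching):

1. Source pass with input dropout ρ_su → cross-entropy ℓ_CE against the
   one-hot labels.
2. Target pass with input dropout ρ_rl → probabilities p; one categorical
   sample ŷᵢ per patient; Kaplan–Meier RMST τₛ of each sampled group on
   [0, 60] months; scalar reward r = min pairwise gap. The reward is a
   single number per episode — patients share it, and the advantage
   qᵢ = r − bᵢ − b_c varies across patients only through the learned
   baseline bᵢ.
3. One Adam step (lr α_rl) on ω₁ℓ_CE + ω₂ℓ_RE + φ‖Θ‖₁, where
   ℓ_RE = −(1/N) Σ qᵢ log pᵢ(ŷᵢ) and q is treated as a constant — no
   gradient flows from the reward into Θ except through the log-policy
   term.
4. A separate Adam step (lr α_bl) on the baseline loss ‖r − b − b_c‖₂
   (the L2 norm of the residual vector, not its square), so baseline
   fitting errors never leak into the classifier.

If a sampled subtype group is empty its RMST is undefined; the episode
reward is then set to −t_restrict (−60). This strong penalty deters the
degenerate collapse onto a single subtype and is logged when triggered.
Probabilities are clipped at 1e-12 before logarithms. A non-finite loss
aborts training with a diagnostic rather than continuing silently.

With early stopping enabled, the model snapshot with the highest
validation ΔRMST — the same min-pairwise-gap statistic evaluated on
deterministic argmax predictions over a held-out target split — is
returned instead of the final weights.

### Ablations

* **No baseline:** q = r; the baseline network is never built or trained.
* **Soft relaxation:** the sampling step is replaced by a differentiable
  soft RMST gap. In the product-limit recursion, the death count d_t and
  risk count n_t of subtype s accumulate membership probabilities pᵢ(s)
  instead of hard counts; the resulting τₛ is differentiable in p, and
  −softΔRMST is added to ω₁ℓ_CE for end-to-end gradient descent. The
  gradient of the soft RMST with respect to the weights is computed
  analytically (chain rule through log S_t = Σ log(1 − d/n)) and is
  verified against central finite differences in the test suite; at
  one-hot memberships the soft gap equals the hard gap exactly.

### Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| ω₁ | 0.1 | weight of the supervised loss (grid {0.1, 0.01, 0.001}) |
| ω₂ | 1 | weight of the reinforcement loss |
| φ (l1_coeff) | 1e-5 | L1 penalty on Θ (grid {1e-5, 1e-4}) |
| ρ_su / ρ_rl | 0 / 0 | input dropout, supervised / RL pass |
| n_hidden | 10 | baseline-perceptron width (grid {10, 100}) |
| α_rl, α_bl | 0.01 | Adam learning rates (classifier, baseline) |
| episodes | 10,000 | full-batch iterations (reduced in the harness; below) |
| t_restrict | 60 months | RMST horizon |

The learning rates are not specified beyond "tunable"; 0.01 matches the
stated DNN/DANN rates and is used for both optimizers.

## Baselines

**DNN** — hidden layer (20 units, relu) → dropout 0.8 → prediction layer;
cross-entropy, Adam lr 0.01, 2000 epochs.

**DANN** — encoder (20 hidden units), task head and domain head (hidden
10 when the two-layer option is chosen), joined by a gradient-reversal
connection: forward identity, backward multiplies the domain-head
gradient entering the encoder by −λ. DANN here trains with momentum SGD
(0.9) and the standard ramp λ(t) = grl_weight·(2/(1+e^(−10t)) − 1) over
training progress. Adam was tried first and fails structurally: the tiny
domain head is scale-invariantly re-optimized every step, its
cross-entropy saturates at zero, and the reversal pressure on the encoder
vanishes before domain confusion can emerge. With momentum SGD the
adversarial game behaves as expected (held-out domain accuracy drifting
toward 0.5 on moderately shifted data). Adversarial dynamics remain
seed-sensitive — occasional collapses are visible across seeds — which is
inherent to the game, not a tuning failure.

## Synthetic data

### Toy grid (121 cells)

Two subtypes, 20 features on [0, 1]. Class means are block contrasts
(features 1–10 elevated for S-I, 11–20 for S-II, separation 0.4, per-
feature SD 0.15, clipped to [0, 1]); a contrast rather than a level
difference keeps the classes separable through the origin, which matters
because the classifier has no bias term. Source and target share the base
features; the target adds α·noise where the noise has per-dimension means
drawn once from U[0, 1] and SD 0.2. α runs over 0..4 in 11 steps (batch-
effect axis). Survival is uncensored and threshold-split: S-I uniform on
(30, 60], S-II uniform on (0, 30); a swap ratio s ∈ {0, 0.02, …, 0.2}
exchanges the survival times of ⌊s·n_subtype⌋ random cross-subtype pairs
(survival-correlation axis). Per-cell cohort size is 200 (the harness
holds out 20% of the target for testing).

Seeding is deliberately two-stream: labels, base features, and survival
derive from (seed, swap index) only, while the added noise derives from
(seed, α index, swap index). All cells in one swap row therefore share
identical survival data, making the survival-threshold reference map
*exactly* constant along the batch-effect axis rather than constant in
expectation.

Note the noise is drawn per sample (SD 0.2 scaled by α), so high-α cells
have an intrinsic Bayes ceiling (~0.86 at α = 4); accuracy maps should be
read against that ceiling, not against 1.0.

### Benchmark (1000 samples × 1000 features, 3 subtypes, 2 batches)

Simulated on a log2-intensity scale, mimicking label-free proteomics:
per-protein baseline levels N(3, 2); per-subtype differential expression
(probability 0.1 per protein, shift magnitude |N(0.5, 0.3)| with random
sign); per-protein batch factors applied to the second batch — lognormal
with location and scale equal to the batch-effect setting (0.01 ≈ none,
2 = large), half inverted; Gaussian measurement noise (SD 1); and a
detection limit at log2 intensity 0 below which values are missing.
Survival times are drawn by inverse-CDF from a Weibull proportional-
hazards model with baseline cumulative hazard H₀(t) = λt^γ (λ = 0.005,
γ = 0.5) and per-subtype log-hazards (0, 1, 2), administratively censored
at 60 months (~4/10/25% event rates). The log-hazard spacing matches the
prognostic separation of published HCC proteomic subtypes (roughly
90/70/50% five-year OS) and makes the subtypes clearly prognostic, so
that on batch-free data supervised and survival-guided training agree.
Batch 1 is the labelled source cohort, batch 2 the target; true target
labels are kept for evaluation only.

What the generators do *not* emulate: correlated protein blocks
(co-regulation), intensity-dependent missingness beyond a hard detection
limit, library-size artefacts, or competing-risk censoring. Passing
benchmarks here therefore demonstrate the mechanism — supervision
transferred across a per-feature distributional shift with survival
reinforcement — not performance on any particular real cohort.

## Preprocessing

The multi-cohort pipeline applies, per cohort and in order: quantile
normalization across samples (ties averaged; missing values stay
missing), removal of proteins detected in <30% of samples, zero
imputation, per-protein z-scoring (population SD; constant columns are
zeroed, not dropped, to keep signature alignment), then intersection to
the proteins shared by both cohorts (source order) and optionally to a
signature list. "Detected" means non-missing *before* imputation.

For the simulated benchmarks the z-scoring statistics are pooled over
both cohorts rather than computed per cohort (`zscore="pooled"`). The
reason is structural: the simulated batch effect is exactly a per-protein
multiplicative factor, and per-cohort standardization removes such a
factor *identically* — acting as an unrealistically perfect batch
correction that erases the very condition under study. Real batch effects
are not per-feature scalings and survive the per-cohort pipeline, which
remains the default for real data.

## Evaluation harness

Repeated k-fold cross-validation follows the rotate-one-fold protocol:
per repeat, an even 5-way split; three folds train, the fold after the
test fold validates, the test fold rotates. Survival metrics (log-rank
score, Harrell's C on the p(1) − p(k) probability contrast) are computed
on the *pooled* test-fold predictions of a repeat, so each repeat yields
one log-rank score on the full cohort; accuracies are recorded per fold.
Hyperparameter selection uses validation accuracy (target validation
labels when the data are simulated, source otherwise) or, for label-free
settings, the validation log-rank score gated by ssGSEA similarity ≥ 0.5
when gene sets are supplied (without gene sets the gate is skipped with a
prominent warning, or an error if the caller forbids the fallback).

Single-sample enrichment scores use the rank-weighted running-sum
statistic (weight 0.25, difference-of-ECDF form) on sets with ≥ 10
measured genes; cohort similarity is the mean over subtypes of the cosine
between subtype-average score vectors.

The accuracy-map experiment reserves 20% of each cell's target cohort for
testing, with the held-out split tied to the swap index so the
survival-threshold reference is exactly column-constant. The residual-map
t-test is a one-sample, one-sided test of residuals > 0, either over all
121 cells or over the upper-right 6×6 block (normalized batch scale ≥ 0.5
and survival correlation ≥ 0.5; the region is not delimited numerically
in the protocol, so the half-grid convention is adopted here).

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses one repeat of 5-fold CV and 1000 training
episodes (instead of five repeats and 10,000 episodes) and DANN's stated
2000 epochs; these sizes were chosen as the package's desk-scale protocol
and are also used in the test suite. The benchmark evaluation
configuration (ω₁ = 0.1, ρ_su = 0.3, φ = 1e-5, n_hidden = 10) was fixed
once by validation accuracy within the standard grid. The t3 denominator
(DANN's log-rank score) is floored at 0.01 because single-class
predictions yield a score of exactly 0; the floor only ever shrinks the
reported ratio.

## Numerical notes

* Kaplan–Meier curves are computed on the grid of distinct observed
  times; RMST is an exact rectangle sum (no quadrature), with the curve
  extended flat beyond the last observed time.
* C-index ties (times or scores) count 0.5, Harrell's convention; the
  log-rank P value comes from the (k−1)-df chi-square approximation, and
  is floored at 1e-300 before −log₁₀.
* Argmax ties in prediction resolve to the smaller subtype index.
* Seeded runs are bit-reproducible: every stochastic step draws from a
  generator derived from the run's seed.

## Known limitations

* The reward can overfit individual target patients when d ≳ n (the
  linear model can carve specific samples across the boundary while
  keeping the source fit intact); cross-validated evaluation measures
  what generalizes, and ρ_su dropout mitigates the companion source
  overfit, but training-cohort predictions should not be read as
  transfer accuracy.
* With k subtypes the reward is the *minimum* pairwise gap, so gradients
  vanish for pairs far from the minimum; orderings can be locally stable
  even when a non-adjacent pair is mis-ordered.
* DANN results on strongly shifted data are honest but unflattering: with
  per-feature shifts this large the domain classifier separates cohorts
  perfectly and adversarial alignment rarely recovers, across the stated
  tuning options.
* Real-cohort analyses (signature transfer between published HCC/LUAD
  cohorts) require user-supplied expression and clinical files; nothing
  in the package downloads them.
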