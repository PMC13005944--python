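# srps — survival-reinforced patient stratification

Molecular subtypes discovered in one cancer cohort rarely transfer cleanly
to another: proteomic profiles shift between centers for technical and
biological reasons, and a classifier trained on the discovery cohort loses
both accuracy and — more importantly for the clinic — the prognostic
separation that made the subtypes interesting. `srps` implements a
semi-supervised transfer algorithm for this *cohort adaptation* problem,
aimed at computational biologists working with multi-center proteomic (or
other omics) expression matrices plus survival follow-up.

## The method

A single linear softmax classifier serves both cohorts: for a z-scored
profile **x** ∈ ℝᵈ, subtype probabilities are **p** = softmax(Θ**x**) with
Θ ∈ ℝᵏˣᵈ and no bias. Training combines two signals per full-batch episode:

* **Source cohort (labelled):** cross-entropy
  ℓ_CE = −Σₛ y(s) log p(s) against the known subtype labels.
* **Target cohort (survival only):** an on-policy policy gradient
  (REINFORCE). Subtypes ŷᵢ are *sampled* from **p**ᵢ, each sampled group's
  restricted mean survival time τₛ (area under its Kaplan–Meier curve up
  to 60 months) is computed, and the scalar episode reward is the minimum
  pairwise gap r = min_{a<b} (τₐ − τ_b) — positive only when every
  better-indexed subtype outlives every worse-indexed one. A learned
  baseline (three-layer perceptron bᵢ = f_b(xᵢ) plus scalar b_c) gives the
  advantage q = r − bᵢ − b_c, and the surrogate loss
  ℓ_RE = −(1/N) Σᵢ q ᵢ log pᵢ(ŷᵢ) follows the policy gradient.

The total loss ω₁ℓ_CE + ω₂ℓ_RE + φ‖Θ‖₁ is minimized with Adam; the
baseline minimizes ‖r − b − b_c‖₂ with its own optimizer. Inference is a
plain argmax — no survival data needed. Because the classifier is one
linear layer, each protein's contribution to a subtype call is directly
interpretable through Δweight(a,i) = Θ(a,i) − mean_{b≠a} Θ(b,i).

The package also provides the comparison baselines (supervised DNN and a
gradient-reversal adversarial network, DANN), two ablations (no reward
baseline; a differentiable soft RMST-gap relaxation), synthetic-data
generators (a 121-cell toy grid and a two-batch, three-subtype benchmark
with Weibull survival), and a repeated cross-validation harness with
grid search, accuracy maps, ssGSEA subtype similarity, log-rank score and
concordance-index reporting.

## Worked example

Train on a toy pair with moderate batch noise (alpha = 2) and a small
survival swap, then predict the target cohort:

```python
from srps import ToyGridSpec, make_toy_pair, SrpsConfig, train, predict_subtype
from srps.harness import accuracy
from srps.survival_stats import logrank_score

spec = ToyGridSpec(seed=0)
source, target = make_toy_pair(spec, alpha=2.0, swap=0.04)

cfg = SrpsConfig(k=2, d=20, episodes=1000, omega1=0.1, seed=0)
model, log = train(source, target, cfg)

pred = predict_subtype(model, target.x)
times, events = target.survival("OS")
print(f"target accuracy:     {accuracy(pred, target.labels):.3f}")
print(f"final episode reward: {log.reward[-1]:.2f} months")
print(f"log-rank score:      {logrank_score(pred, times, events):.2f}")
```

prints

```
target accuracy:     0.975
final episode reward: 24.59 months
log-rank score:      30.06
```

The reward is in months of restricted mean survival time: the sampled
subtype groups differ by ~25 months of RMST at the end of training. The
log-rank score is −log₁₀ P of the between-subtype log-rank test (1.3
corresponds to P = 0.05), and 0.975 of target patients are assigned their
true subtype even though the target features are shifted relative to the
source.

The same workflow is scriptable from the shell:

```bash
srps simulate --preset benchmark-batch --seed 0 --out data/
srps map --strategy srps --seed 0 --out srps_map.tsv --heatmap srps_map.png
srps evaluate --preset benchmark-nobatch --out report.json
```

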