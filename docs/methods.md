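# Methods

## Model

A `K`-class classifier `f_θ(x) = softmax(g_{θ₂}(h_{θ₁}(x)))` is trained
against a consensus of noisy annotations rather than gold labels. For
instance `n` with observed annotator set `W_n` and one-hot labels
`o_n^(w)`, the predicted distribution `ŷ_n` serves as a dot-product
attention query over the labels:

    p_n(w)  = ŷ_nᵀ o_n^(w)                          (reliability score)
    ỹ_n     = Σ_w p_n(w) o_n^(w) / Σ_w p_n(w)       (pseudo-label)
    L(θ)    = −(1/N) Σ_n Σ_k ỹ_{n,k} log ŷ_{n,k}    (training loss)

`p_n(w)` is the predicted probability of the class annotator `w` chose, so
it already lies in [0, 1]; no softmax is applied across annotators and no
extra parameters are introduced — annotator reliability is represented
non-parametrically, as a function of the input through the classifier
itself. Scoring and aggregation cost `O(W·K)` per instance.

Assumptions worth making explicit:

* every instance has at least one annotation (`|W_n| ≥ 1`; enforced at
  dataset construction);
* annotators are conditionally independent given the input — the consensus
  has no term for correlated or colluding annotators;
* the bootstrap works because a symmetric random initialisation yields
  near-uniform predictions, making early pseudo-labels approximate soft
  majority votes; if the majority is wrong over a *large* region of feature
  space and no better-informed neighbouring region constrains the
  classifier, the model can lock onto the majority's error.

## Training procedure and defaults

| parameter | default | rationale |
|---|---|---|
| encoder | MLP, ReLU, hidden 512/256 | small tabular/1-D inputs; matches the benchmark backbone |
| optimiser | Adam, lr 0.005 | stable on full-batch gradients at this scale |
| batching | full batch | N ≤ a few thousand here; mini-batching available via `batch_size` |
| epochs | 500 | saturates the synthetic task in seconds; no early stopping |
| init | U(−1/√fan_in, +1/√fan_in) on weights and biases | symmetric, keeps initial predictions near uniform |
| `detach_pseudo_label` | `True` | see below |
| `epsilon` | 1e−8 | zero-mass fallback threshold in the pseudo-label |

**Gradient path through the pseudo-label.** As written, `ỹ_n` depends on θ
through the query. By default the pseudo-label is treated as a constant
target within each step (stop-gradient), the standard pseudo-labelling
convention: differentiating through the target rewards the model for
*reshaping the target toward its own prediction*, a self-confirmation
pressure that is strongest exactly where the model is wrong.
`detach_pseudo_label=False` implements the literal composite gradient
analytically (the extra term is `−(c_m/S)(log ŷ_m − Σ_k ỹ_k log ŷ_k)` per
instance, with `c` the per-class annotation counts and `S = Σ_j c_j ŷ_j`)
for comparison; on the synthetic benchmark both converge to the same
solution, with slightly different trajectories.

**Numerical choices.** Predicted probabilities are clamped at 1e−12 inside
logarithms. If an instance's total score mass `Σ_w p_n(w)` falls below
`epsilon`, weights fall back to uniform over `W_n` (soft majority vote) so
the pseudo-label stays defined; with one-hot keys this can only happen when
the query is numerically orthogonal to every observed label. Ties in argmax
predictions and in majority votes break toward the lowest class index.
Runs are bitwise-reproducible given (dataset, configs, seed): all
randomness flows through `numpy.random.default_rng(seed)` and training is
full-batch.

## Synthetic benchmark

The generator emulates a controlled crowdsourcing study. Inputs are scalar,
uniform on [0, 1], 300 train / 200 test; the true class is the argmax of
`sin(2πx)`, `−sin(2πx)` and `0.5 − sin(2π(x+0.25))`, giving three
interleaved class regions with nonlinear boundaries.

Five annotators are simulated with deterministic *reliable sets* — unions
of half-open subintervals of [0, 1] on which the annotator always reports
the true label. Outside its reliable set an annotator draws uniformly among
the `K−1` wrong classes, so expected accuracy equals the reliable-set
measure, and a small reliable set yields genuinely adversarial (sub-chance)
behaviour. The default profiles realise four archetypes with measures
calibrated exactly to the target accuracy vector
[84.66, 59.66, 66.33, 55.66, 27.66]%:

| annotator | shape | reliable set |
|---|---|---|
| a1 | sharp transitions | [0, 0.42) ∪ [0.5734, 1) |
| a2 | non-monotonic | three bumps of width 0.5966/3 at 0, 0.35, 0.70 |
| a3 | single plateau | [0.17, 0.8333) |
| a4 | non-monotonic | four bumps of width 0.5566/4 at 0.05, 0.28, 0.51, 0.74 |
| a5 | sparse signal | [0.3617, 0.6383) |

Because labels derive from known reliable sets, the generator also emits
per-(instance, annotator) correctness indicators — the ground truth for
reliability-recovery evaluation (estimated scores thresholded at 0.5,
per-annotator F1 with "correct" as the positive class, unweighted mean
over annotators, computed on the test inputs).

**What the simulator does not capture.** Real annotator errors are
correlated (shared training, shared ambiguous cases), biased toward
specific confusions, and stochastic rather than deterministic in their
competence regions; class imbalance and sparse annotation (most annotators
labelling few instances) are also absent by default. Passing tests on this
benchmark therefore demonstrate the mechanics of input-aware reliability
weighting, not robustness to structured real-world noise. Notably, with
independent errors the task is easy enough that the crowd-trained model
matches the gold-trained upper bound (~99% macro F1) on most seeds; under
correlated or stochastic annotator noise a gap of one to two points is the
expected picture.

## Baselines and evaluation

* **Majority vote** — plurality label, ties to the lowest index.
* **Dawid–Skene EM** — latent true class per instance, one row-stochastic
  `K×K` confusion matrix per annotator; EM from soft-majority-vote
  posteriors with additive smoothing 1e−6 on priors and confusion rows,
  stopping when the max posterior change drops below 1e−6 (observed-data
  log-likelihood is checked non-decreasing in the tests). The downstream
  network trains on the *soft* posteriors — strictly more information than
  their argmax.
* **Gold-trained upper bound** — same backbone on one-hot true labels.

All baselines share the attention model's architecture, optimiser and
seeds, so score differences isolate the labelling strategy.

The Friedman test uses the classical statistic
`χ² = 12/(Nk(k+1)) Σ_j R_j² − 3N(k+1)` with average ranks for ties and no
tie-correction factor, referred to χ² with `k−1` degrees of freedom. The
cumulative annotator sweep sorts annotators by descending label count (ties
by id), evaluates subset sizes 1, 1+step, 1+2·step, … (step 4 by default)
always ending at the full pool, and drops instances left without
annotations from each restricted run.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run the benchmark at its native
size (300/200, five annotators): ten attention trainings plus five
gold-trained runs of 500 full-batch epochs each complete in about a minute
on one CPU. Monte-Carlo calibration checks of the simulator use n = 10,000
draws, where the binomial standard error is ≈ 0.5 points (at n = 300 it is
≈ 2–3 points, which bounds how tightly realised accuracies can match their
targets on any single draw).

## Known limitations

* Reliability estimates fluctuate near decision boundaries, where the query
  itself is uncertain — an inherent property of using the prediction as the
  scoring signal.
* No explicit model of systematic annotator bias or class-dependent
  confusion; the score depends only on the predicted probability of the
  chosen class.
* The NumPy backbone is CPU-only and targets tabular/low-dimensional
  features; image or audio tasks need features extracted upstream (the CSV
  interfaces accept arbitrary feature width).
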