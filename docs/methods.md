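# Methods

`riskcast` forecasts whether a person in long-term residential care will have
a seizure or a high-risk behavioral event (aggression, self-injurious
behavior, elopement) on the next day, using only the previous one to two
weeks of daily presence/absence records of challenging behaviors.  This note
documents the model, the synthetic data that drives the test suite, the
statistical framework, and the numerical and design choices a maintainer
would want to know about.

## The prediction task

Raw records are long-format episodes: one row per (subject, date, shift,
behavior), collected across three daily staffing shifts (morning, afternoon,
overnight).  Preprocessing:

1. **Channel selection.** The 7 most prevalent behaviors across the whole
   population (episode-row counts, ties broken lexicographically) become
   channels 1–7; every other behavior folds into an 8th `Other` channel.
   The channel set is always computed from the data, never hard-coded.
2. **Daily OR-aggregation.** A day's value for a channel is 1 if any shift
   recorded that behavior.  Days with no records are all-zero (absence of a
   row means the event was absent).
3. **Seizure channel.** For the seizure task a 9th binary channel marks
   seizure days.  The seizure task is restricted to subjects present in both
   the behavior and seizure datasets; asking for the channel for anyone else
   is an error rather than a silent all-zero column.
4. **Cohorts.** A subject enters a target's cohort only with ≥ 1 occurrence
   of that target in their span.  The *severe* cohort additionally requires
   that at least 10% of the subject's target episodes carry the severe tag
   (subjects with zero target episodes are excluded, not a division error).
5. **Windows.** Stride-1 sliding windows: features are the W×C binary block
   of days t−W…t−1 (W ∈ {7, 14}; rows oldest→newest; the target's own
   history is included), the label is the target channel on day t.  A
   subject with T days yields exactly max(0, T−W) samples.
6. **Split.** Per subject, in time order: the first ⌊0.8·N⌋ samples train,
   the rest test.  Every training target day precedes every test target day.
   Subjects whose split would leave an empty train or test side are flagged
   and skipped.

One model is trained per subject × target × window length.

## The classifier

A small convolutional network over the W×C×1 window:

    conv 3×3, 32 filters, ReLU → batch norm → max-pool 2×2
    conv 2×2, 64 filters, ReLU → batch norm → max-pool 2×2
    flatten → dense 64, ReLU → dropout 0.5 → dense 1, sigmoid

trained with Adam (learning rate 1e-3) on binary cross-entropy for 50
epochs with batch size 32.  The network, including backpropagation, batch
normalization and Adam, is implemented in numpy (float64); training is
deterministic per platform given a seed.

Numerical conventions, chosen where the architecture description leaves
freedom:

- **Padding.** "Same" padding, stride-1 convolutions.  With valid padding
  the 7×8 input would collapse below the second pooling, so same padding is
  the only convention under which the stack is well-defined for both window
  sizes.  Even kernels pad the extra row/column at the bottom/right.
- **Pooling.** Floor division, stride 2, ties routed to the first maximal
  position.  Flattened widths are deterministic: 7×8 → 1×2×64 = 128,
  14×9 → 3×2×64 = 384.  Both spatial dims must be ≥ 4, hence the minimum
  window length of 4.
- **Batch norm.** After the ReLU of each conv, per the stated layer order;
  ε = 1e-3.  The running-statistics EMA momentum is 0.9: per-subject
  training runs contain only a few hundred updates, and a slower EMA (for
  example 0.99) leaves the inference statistics unconverged, producing a
  large train/inference mismatch with saturated constant predictions.
- **Dropout.** Inverted (scaled at train time), inactive at prediction.
- **Decision threshold.** 0.5, with score = threshold classified positive.
- **No early stopping, validation split, or class weighting** — the
  training recipe is fixed.
- A reduced "ci" profile (10 epochs, 500 permutations) exists for fast
  exploratory runs; paper-fidelity defaults are 50 epochs and 10⁴
  permutations.

The reference predictor is the **prevalence baseline**: i.i.d. Bernoulli
draws at the training-set label prevalence p̂ — prediction from historical
frequency with no use of the input.  Its expected accuracy against labels of
prevalence p is q·p + (1−q)·(1−p) with q = p̂.

## Significance: the label-permutation test and ΔAccuracy

Per subject, with test predictions ŷ held fixed, the test labels are
uniformly permuted m times (multiset preserved); the accuracy of ŷ against
each permutation forms the null distribution A — the accuracy achievable by
prevalence-aware guessing.  Then

    p = Pr(A > a) = |{b ∈ A : b > a}| / m      (strict inequality)
    ΔAccuracy = a − mean(A)

with rejection at p < α = 0.05.  Match counts are compared as integers, so
null ties are exact.  No add-one smoothing is applied (p = 0 is reportable);
a smoothed variant `(count+1)/(m+1)` is available behind a flag.

**Exact oracles.** Under a uniform permutation, the overlap between true and
predicted positives is hypergeometric, so the null distribution, its mean
(= q·p + (1−q)·(1−p) exactly), and the test's exact rejection probability
are all available in closed form; an exhaustive-enumeration mode over all
C(n, n₁) label arrangements covers small n.  These oracles are implemented
independently of the sampled path and used to cross-check it.

**Calibration caveat.** The strict ">" makes the test *anti-conservative*
wherever the null has tie mass: in the extreme, a constant classifier has a
degenerate null (A ≡ a), p = 0, and is always "significant".  Consequently
the test's Type-I rate is not α; it is the exactly computable quantity
`expected_rejection_rate(n, n₊, n̂₊, α)`.  Calibration checks therefore
compare the observed rejection count against the Poisson-binomial band of
these per-subject exact probabilities, not against nominal α.  ΔAccuracy
remains exactly zero-mean under the null either way.  A second, structural
caveat: with overlapping windows, a test label on day t is also a *feature*
of the windows targeting days t+1…t+W, so labels and the fixed prediction
vector are not perfectly independent under the null; empirically the effect
on calibration is within the oracle band at the sizes used here.

## Feature attribution

**First-layer Grad-CAM** (positive class, positive-labelled test samples by
default): with A^k the post-ReLU feature maps of the first convolution and Y
the pre-sigmoid score, the weights are global average-pooled gradients
α_k = (1/Z)·Σ_ij ∂Y/∂A^k_ij, and the map is ReLU(Σ_k α_k A^k).  With same
padding the first-layer maps share the input's day×channel grid, so no
upsampling is needed.  The gradient is taken on the pre-sigmoid score; the
sigmoid's positive slope scales all α_k equally and cancels under the
per-map sum normalization.  Aggregation: each map is normalized to unit sum
(all-zero maps dropped and counted), averaged within subject, then across
subjects; day rows are labelled as lags −1…−W.

**Known limitation, and the input-gradient mode.**  Grad-CAM condenses each
filter's gradient to a single scalar and re-introduces spatial structure
only through the activation maps.  On sparse binary windows the first
layer's activations largely echo where *any* event occurred, and its filters
remain nearly unselective at these data sizes, so the aggregated map does
not localize evidence at channel granularity: in a planted-single-channel
experiment where per-channel occlusion confirms the trained model relies on
the planted channel, Grad-CAM ranks that channel first in only ~20% of runs.
The package therefore also provides **input-gradient saliency**
|∂Y/∂x(day, channel)|, which keeps the gradient's spatial structure and
recovers the planted channel in 100% of the same runs.  Grad-CAM remains the
default (it is the method the pipeline is specified around); analyses that
need attribution tied to ground truth should use the input-gradient mode.

## The synthetic data generator

No public data exist for this task (the study data are proprietary
de-identified care records), so the generator is a first-class, tested
component that emulates their structure: ~10 behavior channels plus a
seizure channel per subject-day, three shifts per day, multi-year spans,
heterogeneous per-subject prevalence, cross-channel temporal coupling,
i.i.d. severity tags, and a categorical group label (sex, ~1:4
female:male).

Each channel follows an autoregressive logistic model

    logit P(x[t,c] = 1) = b_c + Σ_{c',ℓ} W[c', ℓ, c] · x[t−ℓ, c'] + cycle(t)

with subject baselines b_c ~ Normal(μ_c, σ); history before day 0 is
all-zeros.  Day-level events are thinned into shifts with probabilities
(0.5, 0.35, 0.15), forced into one uniform shift if all thinning draws fail.
One RNG stream per subject is derived from (seed, subject index), so output
is independent of iteration order and byte-identical under a fixed config.

Defaults (population means of baseline log-odds): disruptive behavior −1.2;
agitation −0.3; impulsive behavior and task refusal −0.6; aggression −0.9;
elopement −1.0; SIB −1.1; seizure −1.0; property destruction, pica and
inappropriate touch −1.3…−1.9; subject spread σ = 0.6; span 1200 days
(multi-year, as the records being emulated are).  The profile is
deliberately heterogeneous: it keeps the top-7 ranking stable and
meaningful, makes disruptive behavior a broad, common category, keeps the
coupled high-risk targets near the balanced-label regime that the published
accuracy/F1 pairs imply, and keeps the rarest behaviors in the `Other`
fold.  Span matters for the model, not just the statistics: at ~300
training windows the 20k-parameter network memorizes (training accuracy
1.0, test at chance), while at ~950 windows it generalizes at
logistic-regression-comparable accuracy.

Two presets define the study conditions for testing:

- **`null_preset`** — zero coupling, no cycle: labels carry nothing beyond
  prevalence.  Drives Type-I calibration.
- **`signal_preset(strength)`** — disruptive behavior on each of the
  previous three days adds `strength` to the log-odds of each high-risk
  target (aggression, SIB, elopement, seizure), and the trigger self-excites
  at lag 1 with `strength/2`, so disruptive episodes cluster into multi-day
  bouts as real challenging behaviors do.  `strength = 0` reduces to the
  null preset.  Equal lag weights (rather than decaying) were chosen
  because the pooled day axis of the classifier detects persistent
  multi-day elevation far better than a lag-1 impulse; a pure lag-1 signal
  is nearly invisible to this architecture even when a logistic regression
  on the same windows detects it easily.

**What the generator does not emulate:** medication, sleep and
environmental covariates; within-shift timing; seasonal/weekly structure
(the sinusoidal cycle is off by default); nonstationarity over years;
realistic demographics beyond one group label; and any dependence of
severity on context (severity tags are i.i.d.).  Passing tests therefore
show the pipeline's statistical machinery is correct and can detect
plausible planted structure — not that the model would reach any particular
accuracy on real care records.

## Calibration and recovery experiments (problem sizes)

The packaged experiments (also run by `scripts/acceptance.py`) use sizes
chosen to finish on a single CPU in minutes:

- **Permutation oracle** — 200 random prediction/label pairs at n ≤ 8;
  sampled p (m = 2000) vs exhaustive enumeration.
- **Null calibration** — 50 subjects × 400 days, 7-day window, reduced
  profile; observed rejections vs the exact Poisson-binomial oracle band
  (99%), and mean ΔAccuracy vs 0.
- **Signal recovery** — `signal_preset(2.0)`, 30 subjects at the default
  1200-day span, full 50-epoch budget, m = 2000; fraction of subjects where
  the model beats the prevalence baseline's expected accuracy and the test
  rejects (≥ 80% expected).
- **Planted-channel attribution** — 20 single-subject runs, single coupling
  edge, one busier-than-the-trigger noise channel as a control; top-1 rate
  reported for both saliency modes.

## Known limitations

- Significance is per subject with no multiple-testing correction across
  subjects, mirroring the procedure being reproduced.
- AUROC is undefined on single-class test sets and AUPRC without positives;
  both are excluded from macro means (with counts reported) rather than
  imputed.
- Macro F1 is the positive-class F1 averaged across subjects.
- Reproducibility is guaranteed per platform (fixed seeds, float64), not
  bit-for-bit across BLAS implementations.
- The strict-inequality p-value is kept exactly as defined, including its
  anti-conservative tie behavior; users wanting a valid nominal level
  should use the smoothed variant and/or the exact oracle utilities.
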