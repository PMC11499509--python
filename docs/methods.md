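# Methods

## The problem

In a multi-label dataset each instance carries a subset of `q` binary
labels. Between-label imbalance — some labels an order of magnitude rarer
than others — degrades every strategy that learns the labels jointly or
separately, and single-label resamplers cannot fix it: an instance that
carries both a rare and a frequent label is duplicated or deleted as a
whole, so boosting one label's count drags the other's along. The
motivating setting is a geriatric cohort with six adverse-outcome labels
(mortality, urgent hospitalization, disability, preventable
hospitalization, emergency admission, fracture) whose rarest outcomes
co-occur with the most frequent ones in most of their instances.

## Imbalance quantification

Per label, `IRLbl(λ)` is the count of the most frequent label divided by
the count of `λ` (so `min IRLbl = 1`). Summaries: `MeanIR` (mean),
`MaxIR` (max), `IRLblσ` (sample standard deviation, `q−1` denominator) and
`CVIR = IRLblσ / MeanIR`. A dataset is flagged imbalanced when
`MeanIR > 1.5` **and** `CVIR > 0.2`. Labels with `IRLbl > MeanIR` form
the minority set; ties go to the majority set (the conservative reading of
a strict-inequality rule: a label sitting exactly at the mean is not
oversampled). Zero-count labels make the ratio infinite; the
implementation raises instead of propagating infinities into `MeanIR`, and
the hybrid resampler refuses such datasets up front.

## The hybrid resampler

`ml_tlsmote` = iterated per-minority-label SMOTE, then one pass of
per-majority-label Tomek cleaning, then a final profile recomputation.

**Oversampling.** One SMOTE round (`ml_smote`) processes minority labels
in descending-ratio order (rarest first). The seed pool for label `λ` is,
under the default *strict* rule, the instances with `λ = 1` and every
other label 0 — the reading of "associated with the minority label but
non-associated with other label combinations" that guarantees majority
counts never grow; a relaxed *no-majority* rule (only majority labels must
be 0) is available for datasets where pure single-label minority instances
are rare. Synthetic rows interpolate uniformly between a pool member and
one of its k nearest pool neighbours (Euclidean; ties broken by lowest
index; `k = 5`, the canonical SMOTE default, clamped to pool−1), copy the
seed's full label vector, and are generated until the label's ratio —
with the numerator frozen at the round's maximum label count — reaches the
round's MeanIR, subject to a safety cap of 5× the pool size. Pools smaller
than 2 are skipped with a warning.

A single round cannot balance a dataset whose mid-frequency labels sit
between the final and the initial MeanIR: they are classed majority at
round 1 and would never be oversampled, leaving CVIR stuck well above 0.2.
The pipeline therefore reassesses the profile after each round and
repeats — each round's minority set, MeanIR target and seed pools track
the current data, and earlier rounds' synthetic singletons enlarge later
pools — until `MeanIR ≤ 1.5` and `CVIR ≤ 0.2`, a round adds nothing
(empty or capped pools), or a hard ceiling of 20 rounds. On the preset
below the fixed point of this iteration is `MeanIR ≈ 1.3`, `CVIR ≈ 0.15`
before cleaning, and convergence takes 3–4 rounds.

**Cleaning.** A Tomek link under a binary view is a cross-class pair of
mutual nearest neighbours — no third instance is strictly closer to either
member. For each majority label in ascending-ratio order (most frequent
first), links are recomputed on the currently surviving instances under
the view `target = y_λ` and **both** members are removed (the post-process
cleaning variant, which also sweeps up synthetic instances that invaded a
majority class's neighbourhood), except that an instance is never removed
if it is the last surviving positive of any label. Link recomputation is
sequential per label because a removal can create or destroy links for the
next view.

**Numerical conventions.** Euclidean distance on raw features everywhere;
features are *not* internally standardized (silent scaling would change
the link structure invisibly — callers pre-scale if their units are
incommensurate). Nearest-neighbour ties break toward the lowest instance
index. One RNG seed drives neighbour choice and interpolation draws and is
recorded in the report, making the pipeline bit-reproducible. Tomek
detection keeps all argmin candidates per instance (exact float equality),
so coincident points are handled identically to the quadratic
brute-force definition; distances are computed in blocks of 2048 rows to
bound memory at a few hundred MB for n ≈ 10⁴.

## Evaluation metrics

Five measures over true labels `Y` and score matrix `S` (ranks from
descending scores, ties by ascending label index):

- **Hamming loss** — fraction of disagreeing label cells.
- **Ranking loss** — mean fraction of (relevant, irrelevant) pairs ranked
  wrongly; instances with empty or full label sets are skipped.
- **Average precision** — mean precision of each relevant label at its
  rank; instances with no relevant label are skipped.
- **Micro F1** — `2·TP / (2·TP + FP + FN)` pooled over cells. The
  harmonic-mean form is used deliberately: the printed source formula for
  the micro-averaged F-measure omits the factor 2 and mixes prediction
  symbols, and is not a measure bounded at 1.
- **Macro AUROC** — per-label probability that a positive instance
  outscores a negative one, ties credited ½ (the standard Mann–Whitney
  estimator, computed by rank sums; a printed `≥` variant would credit
  ties fully). Labels without both classes are skipped with a warning.

## Classification strategies

All six strategies consume a base learner through a two-method contract
(fit on features + 1-D target; return per-class confidence) realized by
scikit-learn estimators: random forest, random tree (a single
`max_features="sqrt"` tree), decision tree, SVM (polynomial kernel,
degree 1, C = 0.1, gamma = 0.001 — margins squashed through a sigmoid
when no probabilities are available) and Gaussian naive Bayes. Degenerate
binary targets fall back to a constant scorer, logged.

- **BR** — one binary model per label.
- **CC** — chain in ascending label order by default (order is a recorded
  parameter); at inference each link consumes the chain's own thresholded
  predictions.
- **LP** — multi-class over observed labelsets; per-label score = summed
  confidence of classes containing the label; decision = argmax class, so
  unseen labelsets are never predicted and labels outside all training
  labelsets score 0.
- **RAkEL** — `n_models = 12` LP members on uniform `k = 3`-subsets
  (duplicates across members allowed), vote share thresholded at 0.5;
  uncovered labels fall back to prior frequency, logged.
- **CLR** — `q(q−1)/2` pairwise models trained on instances carrying
  exactly one label of the pair (empty pairs abstain, logged) plus `q`
  calibration models against a virtual boundary label; score = vote
  share; predicted = labels whose share beats the virtual label's.
- **MLkNN** — `k = 10`, Laplace smoothing `s = 1` (the canonical
  defaults): smoothed label priors, likelihoods of neighbour-count
  evidence from leave-one-out training statistics, posterior thresholded
  at ½.

`run_experiment` implements the resampled-train / untouched-test protocol:
split (or explicit test set), resample the training part only, k-fold CV
on the resampled training data, refit on all of it, evaluate on the
untouched test part; the report carries both routes plus the
across-strategy standard deviation per metric. `average_rank` ranks
models per dataset (average ranks on ties) and averages across datasets.

### A note on the two evaluation routes

On this generator the CV-on-resampled route shows the hybrid resampler
improving BR's average precision substantially, while the untouched-test
route shows a small *decrease*. Both are real effects, not bugs: the CV
route evaluates on balanced data, where minority labels carry more weight
per instance, whereas a near-calibrated learner's unresampled scores
already rank labels close to optimally on the original distribution, so
resampling mostly perturbs calibration there. Published gains of this
method family are computed under the CV-on-the-resampled-dataset protocol,
which is what the directional acceptance check reproduces; users who care
about deployment-distribution ranking should read the `test` block of the
report, not the `cv` block.

## Synthetic generator

`generate_mld` draws a labelset per instance from a finite distribution
and sets features to the sum of one Gaussian prototype per active label
plus isotropic `N(0, noise_sd²)` noise. The labelset distribution fixes
the analytic marginals (hence all ratios), the pairwise co-occurrence and
the supply of pure singletons; everything is a pure function of the spec's
seed.

The **frailty-like preset**: 6 labels with marginals `0.4 / IRLbl` for the
published ratio column (1.000, 1.075, 1.331, 2.193, 5.585, 5.905) — top
marginal 0.4 puts label cardinality at 1.39 — composed of one singleton
set per label plus five pairwise sets chosen so each of the two rarest
labels co-occurs with the most frequent label in ~70% of its occurrences
and each of the three rarest labels keeps 2% pure-singleton mass
(non-empty strict seed pools; the real cohort's 64 distinct label
combinations imply every singleton occurs). Analytically `MeanIR = 2.848`,
`CVIR = 0.803`. Features: `d = 20`, prototype entries `N(0, 0.3²)` under
unit noise — deliberately weak, heavily overlapping classes, as in
administrative health data where even strong models reach only modest
AUROC; this overlap is also what gives Tomek cleaning realistic work to
do.

What the preset does **not** emulate: mixed categorical/count covariates,
the full 64-set joint co-occurrence structure (only marginals and the
qualitative co-occurrence property are matched), calendar time, censoring,
and cohort scale (~10⁶ records). Tests passing on the preset show the
algorithmic contracts hold, not that clinical performance would transfer.

## Problem sizes

The test suite and the acceptance script run the balance check at
`n = 5000` across 20 seeds, the directional classification check at
`n = 2000` across 5 seeds with tenfold CV, and oracle comparisons at
`n ≤ 60` (Tomek) and `m ≤ 20, q ≤ 5` (metrics) — sizes at which the
quadratic brute-force oracles are exact and fast while the empirical
profile of the preset is stable.

## Known limitations

- The strict seed-pool rule needs pure single-label minority instances;
  datasets without them fall back to skipped labels (warned) unless the
  relaxed rule is chosen.
- The oversampling cap (5× pool per label per round) can stall
  convergence on extreme ratios with tiny pools; the pipeline logs the
  stall and returns the partially balanced data.
- Tomek cleaning is O(n²) per majority label in the worst case; fine to
  n ≈ 10⁴–10⁵, not engineered for millions of rows.
- ARFF support covers the MEKA dialect (numeric + nominal attributes,
  dense and sparse rows, labels first, `-C q` relation token); missing
  values are rejected by design because neither interpolation nor
  Euclidean links are defined for them.
- CC is a single chain; ensemble-of-chains variants are a possible
  extension.
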