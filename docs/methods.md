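# Methods

## Model

A drug universe of *m* drugs carries four attribute sources: a symmetric
binary pharmaceutical interaction network *T* (m×m, zero diagonal), a set
of first-level ATC codes per drug (subsets of the 14-letter alphabet
A B C D G H J L M N P R S V), and binary drug–target and side-effect
profiles over shared vocabularies. Approved combinative pairs form the
positive class; every other candidate pair in scope is a negative. The
default scope is all m(m−1)/2 unordered pairs; an explicit scope file can
restrict it when the negative class is curated rather than exhaustive.

Pair features are the elementwise sum Fᵢⱼ = fᵢ + fⱼ. The sum is symmetric
in the two drugs and, being linear, lets a linear classifier exploit only
drug-level (marginal) signal; this is a deliberate property of the
featurisation, and it shapes both the synthetic generator and the test
design (below).

### Feature channels

* **DDI.** The adjacency is factorised by SVD rather than
  eigendecomposition: for a symmetric indefinite adjacency the
  eigendecomposition can have negative eigenvalues, which would make √Σ
  undefined, while singular values are nonnegative by construction. The
  embedding is U√Σ with singular values < 10⁻⁶ discarded and the 25
  leading components kept (both configurable via `SVDEmbeddingConfig`).
  Isolated drugs get all-zero rows; an all-zero network degrades to a
  zero-column matrix with a warning.
* **ATC.** Tanimoto similarity of first-level code sets. A pair in which
  both sets are empty is defined as 0 (with a logged note); the diagonal
  is 1 only for drugs with a non-empty set. The similarity is used
  directly as a confidence score — any similarity in [0, 1] is the
  decision function of a trivial nearest-neighbour scorer.
* **DTI / SE.** Raw binary profiles compressed by PCA to 25 components
  (configurable). Profiles are mean-centered but not variance-scaled:
  the columns are 0/1 indicators on a common scale, and unit-variance
  scaling would blow up the rarest features.

Component signs in both SVD and PCA are fixed so that each component's
largest-magnitude loading is positive, making all outputs
bit-reproducible. Requesting more PCA components than the data rank
retains the rank with a warning. The implementation goes straight to the
25 leading components; an intermediate truncation (e.g. keeping every
above-threshold component first) changes nothing because components are
ordered by singular value / explained variance.

### Classifier

One logistic model per channel, fitted by penalised maximum likelihood
(scikit-learn, lbfgs, tol 10⁻⁸). A weak L2 penalty (λ = 0.01 by default)
stabilises collinear features; `l2=0` gives the unpenalised MLE, which the
tests check against closed forms and an independent numeric optimiser.
Training requires both classes and is deterministic given its inputs. The
scorer contract (features in, probability in (0, 1) out) is minimal so
other probabilistic classifiers could be slotted in.

### Fusion

Channel scores are combined by a normalised weighted mean
Σ w_c s_c / Σ w_c, so every rule keeps fused scores in [0, 1] and the
mean rule is exactly the uniform-weight case. The "direct" rule uses each
channel's training AUC as its weight. The "greedy" rule evaluates every
candidate on the grid {0, 0.1, …, 1}⁴ (11⁴ − 1 = 14 640 after dropping
the all-zero corner) — an exhaustive sweep is cheap and dominates any
greedy path through the same grid. Candidate AUCs are computed on a
stratified held-out half of the training scores, never on test instances;
ties break toward the lexicographically smallest weight vector (channel
order DDI, DTI, SE, ATC). Proportional weight vectors produce identical
rankings, hence identical AUCs, so tie-breaking picks the smallest
representative.

### Cross-validation

k = 10 by default. S1 partitions scope pairs; S2/S3 partition drugs and
derive train pairs (both members among training drugs) and test pairs
(exactly one / both members among test drugs). Per fold, the DTI/SE PCA
and all logistic models are refitted on training data only. The DDI
embedding and ATC similarity are computed once on the full network/codes:
they involve no combination labels, so a "new" drug's row is not leakage —
new status refers to having no known combination, not to missing
pharmaceutical data. Folds whose test set lacks one of the classes are
skipped with a warning and means taken over the remaining folds
(unavoidable in S3, where a drug fold may contain few or no positive
pairs); pooling all test scores into a single estimate is available via
`pool=True`.

AUC is the Mann–Whitney estimator (ties counted half), implemented via
midranks so it vectorises over the 14 640 weight candidates; tests pin it
to a brute-force pairwise oracle at 10⁻¹². AUPR is the non-interpolated
step (average-precision) estimator — stated explicitly because AUPR
values differ across interpolation conventions.

### Separability analysis

Per channel, a heuristic statistic in [0, 1] (0.5 = no separation):

* DDI: fractions of positive/negative pairs at shortest distance
  **exactly** 2 (Floyd–Warshall; unreachable = ∞), combined as
  p/(p+q). "Exactly 2" is the reading consistent with combinative drugs
  rarely interacting directly (distance 1); a flag switches to ≤ 2.
* ATC: mean of the positive sharing ratio and the negative non-sharing
  ratio.
* SE/DTI: a feature occurs in a pair if either member carries it (for
  binary profiles the union coincides with thresholding the summed pair
  vector). Occurrence frequencies are normalised by class size — absolute
  counts would trivially favour the much larger negative class — and
  features strictly more frequent in one class are counted as enriched
  there; exact nonzero ties belong to no enrichment class, and "neither"
  counts only features absent from both classes. Separability is
  n_neg / (n_neg + n_pos).

The elementary combination rules are exposed as `*_from_fractions` /
`*_from_counts` so they can be applied to externally reported class
summaries; `scripts/acceptance.py` uses them that way.

## Synthetic benchmark generator

The generator emulates a curated combination benchmark: ~120 drugs, a
sparse Erdős–Rényi DDI background (edge probability 0.04), 1–3 ATC codes
per drug, Bernoulli DTI/SE profiles (rates 0.02 / 0.03 over 300 / 800
items), and 100 positive pairs among 7140 candidates (≈1.4% positive —
the same order of imbalance as real benchmarks). Four signals are
planted:

1. positive pairs are moved to DDI distance 2 via a shared hub drug, with
   the direct edge removed;
2. positive pairs are given a shared first-level ATC code;
3. "combination-prone" drugs have elevated rates on a beneficial
   side-effect pattern set and depressed rates on an adverse set;
4. likewise for positive/negative target pattern sets.

Because Fᵢⱼ = fᵢ + fⱼ is linear, purely pair-level profile planting is
invisible to the classifier; profile signal must live at drug level. The
generator therefore concentrates positives on a prone subset (40 of 120
drugs by default) whose profiles carry the planted patterns. More
features are planted in the adverse/negative sets (160 SE, 60 DTI) than
the beneficial/positive sets (80 SE, 30 DTI), so the frequency
separabilities point in the direction observed in real benchmarks
(majority of informative features enriched among negatives).

All plantings — including the concentration itself — scale with
1 − 1/`effect_strength`, so `effect_strength = 1` yields uniformly random
positives and pure-background features: an exact null under which
cross-validated AUC sits at 0.5. The default strength is 4, which puts
fused S1 AUC near 0.8 — deliberately away from both chance and
saturation so that fusion gains and scenario differences remain visible.
Everything is driven by one integer seed (numpy `default_rng`);
regeneration is bit-identical.

What the generator does **not** emulate: real identifier schemes and
vocabularies, correlations between channels (signals are planted
independently so each channel can be ablated), degree heterogeneity of
real DDI networks, and the entanglement of combination approval with
drug age/popularity. Passing tests on this generator therefore show the
pipeline is correct and sensitive to the planted structure, not that the
method attains any particular performance on real data.

A consequence of drug-level signal plus drug-identity memorisation is
that the known-known protocol (S1) is optimistically biased relative to
the cold-start protocols, as expected; but S3 is not systematically
harder than S2 here — S3 test sets are small and their composition
(prone–prone positives against mostly background negatives) partly
offsets the colder start. The scenario-ordering check is accordingly made
at fold-noise resolution.

## Problem sizes and numerics

Default test/evaluation scale is m = 120 (m = 60–80 in unit tests), k = 10
folds, 5 generator seeds for Monte-Carlo properties — sizes chosen so the
whole suite runs in about a minute on one CPU while keeping fold-level
noise small enough for the qualitative assertions. Tolerances: SVD/PCA
oracle agreement at 10⁻⁸, AUC vs brute force at 10⁻¹², published
separability arithmetic at 4 decimal places, null AUC bands of ±0.05
(acceptance, 5-seed mean) and wider in single-seed unit tests.

## Known limitations

* The negative class is "unknown pairs", as in the underlying screening
  formulation; some negatives may be undiscovered positives.
* Only logistic scoring is implemented; the scorer interface is the
  extension point for SVMs or gradient boosting.
* The greedy rule's weights are selected on an internal split of the
  training fold; with few training positives the selection itself is
  noisy.
* `read_universe` intersects sources by default (drugs must have all four
  attribute kinds); `require_all=False` keeps the union for
  single-channel work, with zero profiles for missing sources.
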