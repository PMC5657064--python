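# combifuse

Predicting **combinative drug pairs** — two individual drugs co-administered
for a synergistic therapeutic effect — by integrating four heterogeneous
drug attribute sources and fusing their confidence scores. The package is
aimed at computational screening: ranking candidate pairs so that the small
set of genuinely combinable pairs concentrates at the top, including the
cold-start settings where one or both drugs have no approved combination yet.

## The method

Every drug *dᵢ* carries four attributes:

* a row in the symmetric binary **pharmaceutical drug–drug interaction
  (DDI)** network *T* (unwanted co-prescription interactions — a feature
  source, *not* the combination label);
* a set *Aᵢ* of **first-level ATC codes** (one of 14 anatomical main-group
  letters per code);
* a binary **drug–target interaction (DTI)** profile;
* a binary **side-effect (SE)** profile.

Per-drug features are built channel-wise: the DDI graph is factorised by
SVD, *T = U Σ Uᵀ*, and drug *i* is embedded as row *i* of *U √Σ* truncated
to the 25 leading components (singular values below 10⁻⁶ are discarded);
DTI and SE profiles are compressed to 25 principal components; ATC code
sets are compared directly by the Tanimoto coefficient
*s^ATC*ᵢⱼ = |Aᵢ ∩ Aⱼ| / |Aᵢ ∪ Aⱼ|.

A candidate pair *cᵢⱼ* is featurised symmetrically as **Fᵢⱼ = fᵢ + fⱼ** and
scored per channel by a logistic model
*p(C = 1 | F) = 1 / (1 + exp(−wᵀF − b))*. The three classifier posteriors
and the ATC similarity (already a score in [0, 1]) are combined by **late
fusion**: a plain mean, an AUC-weighted mean ("direct"), or weights chosen
by an exhaustive grid search over {0, 0.1, …, 1}⁴ on held-out training
scores ("greedy"). All weighted means are normalised by the weight sum.

Evaluation uses three scenario-aware cross-validation protocols:
**S1** (known–known) splits pairs at random, **S2** (known–new) holds out
drugs and tests pairs joining a new drug to a known one, **S3** (new–new)
tests pairs entirely among held-out drugs. In S2/S3 no pair touching a test
drug is ever trained on. A companion **separability analysis** quantifies,
per channel, how well positives stand apart from negatives (graph distance
2 for DDI, code sharing for ATC, per-feature occurrence frequencies for
SE/DTI).

Because curated benchmarks of approved combinations are licence-encumbered,
the package ships a **synthetic benchmark generator** that emulates their
structure and plants the four signals above with tunable strength
(`effect_strength = 1` is an exact null).

## Worked example

```python
from combifuse import generate, run_cv, separability_report

universe, network, labels = generate(seed=1)   # 120 drugs, 100 positives
for scenario in ("S1", "S2", "S3"):
    res = run_cv(universe, network, labels, scenario=scenario, k=10, seed=1)
    print(scenario, round(res.auc, 3), round(res.aupr, 3))
```

prints

```
S1 0.808 0.081
S2 0.781 0.056
S3 0.815 0.23
```

i.e. a random positive pair outranks a random negative one about 80% of
the time under all three protocols on this synthetic benchmark (AUPR is
low in absolute terms because positives are ~1.4% of the 7140 candidate
pairs). The separability analysis on the same data
(`separability_report(universe, network, labels)`) gives DDI 0.725,
ATC 0.711, SE 0.575, DTI 0.580 — each channel separates the classes
better than the 0.5 no-signal level, in the planted direction.

The `examples/` directory contains one short script per capability
(simulation, feature channels, CV scenarios, fusion rules, separability);
each prints the numbers it computes with a line on what they mean. A thin
CLI mirrors the same stages:

```bash
combifuse simulate --seed 1 --out scratch/bench
combifuse cv --data scratch/bench --scenario s2 --k 10 --seed 1 --rule mean
combifuse separability --data scratch/bench
```

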