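"""Scenario-aware cross-validation for drug-pair prediction.

Screening for new combinations happens in three distinct settings, and an
honest evaluation must split data accordingly:

* S1 (known-known): pairs are split at random; every drug may appear in
  both training and test pairs.
* S2 (known-new): *drugs* are split; test instances are pairs joining one
  held-out ("new") drug to one training drug.
* S3 (new-new): drugs are split as in S2 but test instances are pairs
  entirely inside the held-out drug set.

S2/S3 guarantee that no pair touching a test drug is ever trained on,
which is what makes them faithful cold-start protocols. Per fold, the
profile-channel PCA and all logistic models are refitted on training data
only. The DDI spectral embedding and the ATC similarity are computed once
from the full pharmaceutical network / code sets: they involve no
combination labels, so there is nothing to leak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import DDINetwork, DrugUniverse, Pair, PairLabelSet
from .features import (
    PCAConfig,
    PCAReducer,
    SVDEmbeddingConfig,
    atc_similarity,
    ddi_embedding,
)
from .fusion import (
    CHANNELS,
    WeightVector,
    direct_weights,
    fuse_average,
    fuse_weighted,
    greedy_weight_search,
    make_score_table,
)
from .metrics import auc, aupr
from .pairs import similarity_as_score, train_logistic, score_pairs

SCENARIOS = ("S1", "S2", "S3")


@dataclass(frozen=True)
class CVSplit:
    scenario: str
    fold_index: int  # 1-based
    train_pairs: tuple[Pair, ...]
    test_pairs: tuple[Pair, ...]
    train_drugs: frozenset[str]
    test_drugs: frozenset[str]  # empty for S1


@dataclass
class EvalResult:
    """Per-fold and mean AUC/AUPR, plus per-channel test AUCs."""

    scenario: str
    k: int
    fold_auc: list[float] = field(default_factory=list)
    fold_aupr: list[float] = field(default_factory=list)
    channel_auc: dict[str, list[float]] = field(default_factory=dict)
    n_folds_skipped: int = 0

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    @property
    def channel_auc_mean(self) -> dict[str, float]:
        return {ch: float(np.mean(v)) for ch, v in self.channel_auc.items()}


def _check_k(k: int, n: int, what: str) -> None:
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds out of {n} {what}")


def split_s1(labels: PairLabelSet, k: int, seed: int) -> list[CVSplit]:
    """Random k-fold partition of scope pairs (known-known scenario)."""
    scope = sorted(labels.scope)
    _check_k(k, len(scope), "pairs")
    if labels.n_positives < k:
        warnings.warn(
            f"only {labels.n_positives} positive pairs for {k} folds; some "
            f"test folds may lack positives (AUPR undefined there)"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scope))
    folds = np.array_split(order, k)
    drugs = frozenset(d for p in scope for d in p)
    splits = []
    for i, fold in enumerate(folds, start=1):
        test = tuple(scope[j] for j in sorted(fold))
        test_set = set(test)
        train = tuple(p for p in scope if p not in test_set)
        splits.append(
            CVSplit(
                scenario="S1",
                fold_index=i,
                train_pairs=train,
                test_pairs=test,
                train_drugs=drugs,
                test_drugs=frozenset(),
            )
        )
    return splits


def _drug_folds(universe: DrugUniverse, k: int, seed: int) -> list[frozenset[str]]:
    _check_k(k, universe.m, "drugs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(universe.m)
    return [
        frozenset(universe.drug_ids[j] for j in fold)
        for fold in np.array_split(order, k)
    ]


def _split_by_drugs(
    labels: PairLabelSet, universe: DrugUniverse, k: int, seed: int, scenario: str
) -> list[CVSplit]:
    scope = sorted(labels.scope)
    splits = []
    for i, test_drugs in enumerate(_drug_folds(universe, k, seed), start=1):
        train_drugs = frozenset(universe.drug_ids) - test_drugs
        train = tuple(
            p for p in scope if p[0] in train_drugs and p[1] in train_drugs
        )
        if scenario == "S2":
            test = tuple(
                p for p in scope if (p[0] in test_drugs) != (p[1] in test_drugs)
            )
        else:
            test = tuple(
                p for p in scope if p[0] in test_drugs and p[1] in test_drugs
            )
        if not test:
            warnings.warn(
                f"{scenario} fold {i}: no test instances (test-drug set too "
                f"small or outside scope); fold will be skipped in averaging"
            )
        splits.append(
            CVSplit(
                scenario=scenario,
                fold_index=i,
                train_pairs=train,
                test_pairs=test,
                train_drugs=train_drugs,
                test_drugs=test_drugs,
            )
        )
    return splits


def split_s2(labels: PairLabelSet, universe: DrugUniverse, k: int, seed: int) -> list[CVSplit]:
    """Drug-wise folds; test pairs join one new drug to one known drug."""
    return _split_by_drugs(labels, universe, k, seed, "S2")


def split_s3(labels: PairLabelSet, universe: DrugUniverse, k: int, seed: int) -> list[CVSplit]:
    """Drug-wise folds; test pairs lie entirely among new drugs."""
    return _split_by_drugs(labels, universe, k, seed, "S3")


def make_splits(
    labels: PairLabelSet, universe: DrugUniverse, scenario: str, k: int, seed: int
) -> list[CVSplit]:
    if scenario == "S1":
        return split_s1(labels, k, seed)
    if scenario == "S2":
        return split_s2(labels, universe, k, seed)
    if scenario == "S3":
        return split_s3(labels, universe, k, seed)
    raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")


def run_cv(
    universe: DrugUniverse,
    network: DDINetwork,
    labels: PairLabelSet,
    *,
    scenario: str = "S1",
    k: int = 10,
    seed: int = 0,
    rule: str = "mean",
    svd_config: SVDEmbeddingConfig | None = None,
    pca_config: PCAConfig | None = None,
    l2: float = 0.01,
    grid_step: float = 0.1,
    pool: bool = False,
) -> EvalResult:
    """Full scenario-aware cross-validated evaluation of the fused scorer.

    Per fold: compress DTI/SE profiles with PCA fitted on training drugs
    only, train one logistic model per channel on training pairs, score
    the test pairs, fuse with the requested rule (``mean``, ``direct`` or
    ``greedy``) and measure AUC/AUPR on the test fold. Folds whose test
    set lacks one of the classes are skipped with a warning. With
    ``pool=True`` a single AUC/AUPR is computed over all folds' pooled
    test scores instead of per-fold averaging.
    """
    if rule not in ("mean", "direct", "greedy"):
        raise ValueError(f"unknown fusion rule {rule!r}")
    pca_config = pca_config or PCAConfig()

    emb = ddi_embedding(network, svd_config)
    sim = atc_similarity(universe)
    raw = {
        "dti": universe.dti_profiles.astype(float),
        "se": universe.se_profiles.astype(float),
    }
    idx = universe.id_index

    def pair_rows(values: np.ndarray, pairs) -> np.ndarray:
        ai = np.fromiter((idx[a] for a, _ in pairs), dtype=int, count=len(pairs))
        bj = np.fromiter((idx[b] for _, b in pairs), dtype=int, count=len(pairs))
        return values[ai] + values[bj]

    result = EvalResult(scenario=scenario, k=k, channel_auc={ch: [] for ch in CHANNELS})
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []

    for split in make_splits(labels, universe, scenario, k, seed):
        if not split.test_pairs:
            result.n_folds_skipped += 1
            continue
        y_train = labels.labels_for(split.train_pairs)
        y_test = labels.labels_for(split.test_pairs)
        if y_test.min() == y_test.max():
            warnings.warn(
                f"{scenario} fold {split.fold_index}: single-class test set; "
                f"fold skipped in averaging"
            )
            result.n_folds_skipped += 1
            continue

        train_idx = sorted(idx[d] for d in split.train_drugs)
        channel_values: dict[str, np.ndarray] = {"ddi": emb.values}
        for ch in ("dti", "se"):
            reducer = PCAReducer(pca_config).fit(raw[ch][train_idx])
            channel_values[ch] = reducer.transform(raw[ch])

        train_scores: dict[str, np.ndarray] = {}
        test_scores: dict[str, np.ndarray] = {}
        for ch in ("ddi", "dti", "se"):
            model = train_logistic(
                pair_rows(channel_values[ch], split.train_pairs),
                y_train,
                channel=ch,
                l2=l2,
            )
            train_scores[ch] = score_pairs(
                model, pair_rows(channel_values[ch], split.train_pairs)
            )
            test_scores[ch] = score_pairs(
                model, pair_rows(channel_values[ch], split.test_pairs)
            )
        train_scores["atc"] = similarity_as_score(sim, split.train_pairs)
        test_scores["atc"] = similarity_as_score(sim, split.test_pairs)

        test_table = make_score_table(split.test_pairs, test_scores, y_test)
        if rule == "mean":
            fused = fuse_average(test_table)
        elif rule == "direct":
            w = direct_weights(
                {ch: auc(train_scores[ch], y_train) for ch in CHANNELS}
            )
            fused = fuse_weighted(test_table, w)
        else:  # greedy
            train_table = make_score_table(split.train_pairs, train_scores, y_train)
            w = greedy_weight_search(
                train_table, grid_step=grid_step, seed=seed + split.fold_index
            )
            fused = fuse_weighted(test_table, w)

        fused_scores = fused["fused"].to_numpy()
        result.fold_auc.append(auc(fused_scores, y_test))
        result.fold_aupr.append(aupr(fused_scores, y_test))
        for ch in CHANNELS:
            result.channel_auc[ch].append(auc(test_scores[ch], y_test))
        pooled_scores.append(fused_scores)
        pooled_labels.append(y_test)

    if not result.fold_auc:
        raise ValueError(
            f"{scenario}: every fold was skipped; cannot evaluate"
        )
    if pool:
        s = np.concatenate(pooled_scores)
        y = np.concatenate(pooled_labels)
        result.fold_auc = [auc(s, y)]
        result.fold_aupr = [aupr(s, y)]
    return result
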