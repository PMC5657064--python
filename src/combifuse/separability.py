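"""Channel-wise separability of positive and negative drug pairs.

For each feature channel a heuristic statistic in [0, 1] estimates how
well approved combinative pairs stand apart from the remaining pairs
(1 = perfectly separable, 0.5 = no separation):

* DDI: combinative drugs rarely interact directly but tend to sit two
  steps apart in the interaction graph. The statistic combines the
  class-wise fractions of pairs at shortest distance exactly 2 as
  ``p / (p + q)``.
* ATC: combinative drugs tend to act on the same anatomical main group.
  The statistic averages the fraction of positives sharing a first-level
  code with the fraction of negatives sharing none.
* SE / DTI: individual binary features occur with different relative
  frequencies in the two classes; features enriched in negatives vs
  positives are counted and combined as ``n_neg / (n_neg + n_pos)``.

The elementary combination rules are exposed separately (``*_from_*``) so
they can be applied to externally reported class fractions or counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from .datamodel import DDINetwork, DrugUniverse, FeatureMatrix, PairLabelSet


def all_pairs_shortest_paths(network: DDINetwork) -> np.ndarray:
    """Unweighted all-pairs shortest path lengths (Floyd–Warshall).

    Returns an m x m float matrix; unreachable pairs are ``inf`` and the
    diagonal is 0.
    """
    return floyd_warshall(
        network.adjacency.astype(float), directed=False, unweighted=True
    )


def separability_from_fractions(pos_frac: float, neg_frac: float) -> float:
    """Combine class-wise trait fractions as ``p / (p + q)``."""
    if pos_frac < 0 or neg_frac < 0:
        raise ValueError("fractions must be nonnegative")
    total = pos_frac + neg_frac
    if total == 0:
        raise ValueError("separability undefined: both fractions are zero")
    return pos_frac / total


def ddi_separability(
    distances: np.ndarray,
    labels: PairLabelSet,
    drug_ids: tuple[str, ...],
    *,
    step: int = 2,
    at_most: bool = False,
) -> tuple[float, float, float]:
    """Graph-distance separability of positives vs negatives.

    Computes the fraction of positive and of negative pairs whose members
    lie at shortest DDI distance exactly ``step`` (or ``<= step`` with
    ``at_most=True``) and combines them with
    :func:`separability_from_fractions`.
    """
    idx = {d: i for i, d in enumerate(drug_ids)}

    def frac(pairs) -> float:
        if not pairs:
            raise ValueError("empty pair class")
        d = np.array([distances[idx[a], idx[b]] for a, b in pairs])
        hit = (d <= step) if at_most else (d == step)
        return float(hit.mean())

    pos = frac(sorted(labels.positives))
    neg = frac(sorted(labels.negatives))
    return pos, neg, separability_from_fractions(pos, neg)


def atc_separability_from_fractions(
    pos_share_frac: float, neg_noshare_frac: float
) -> float:
    """Average the positive sharing ratio and negative non-sharing ratio."""
    for f in (pos_share_frac, neg_noshare_frac):
        if not 0 <= f <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    return (pos_share_frac + neg_noshare_frac) / 2.0


def atc_separability(
    universe: DrugUniverse, labels: PairLabelSet
) -> tuple[float, float, float]:
    """ATC-sharing separability of positives vs negatives."""
    if not labels.positives or not labels.negatives:
        raise ValueError("both pair classes must be non-empty")
    sets = universe.atc_sets

    def share(pair) -> bool:
        a, b = pair
        return bool(sets[a] & sets[b])

    pos_share = float(np.mean([share(p) for p in sorted(labels.positives)]))
    neg_noshare = float(np.mean([not share(p) for p in sorted(labels.negatives)]))
    return pos_share, neg_noshare, atc_separability_from_fractions(pos_share, neg_noshare)


def frequency_separability_from_counts(n_pos_enriched: int, n_neg_enriched: int) -> float:
    """Combine enriched-feature counts as ``n_neg / (n_neg + n_pos)``."""
    if n_pos_enriched < 0 or n_neg_enriched < 0:
        raise ValueError("counts must be nonnegative")
    total = n_pos_enriched + n_neg_enriched
    if total == 0:
        raise ValueError("no feature is enriched in either class")
    return n_neg_enriched / total


def frequency_separability(
    profiles: FeatureMatrix, labels: PairLabelSet
) -> tuple[int, int, int, float]:
    """Frequency-pattern separability of a binary profile channel.

    A feature "occurs" in a pair when either member drug carries it. Per
    feature, its occurrence frequency relative to class size is compared
    between positive and negative pairs; features are counted as
    pos-enriched (strictly more frequent among positives), neg-enriched,
    or absent from both classes (``n_neither``). Features tied at equal
    nonzero frequency belong to no enrichment class. Returns
    ``(n_neither, n_pos_enriched, n_neg_enriched, separability)``.
    """
    vals = profiles.values
    if not np.isin(np.unique(vals), (0, 1)).all():
        raise ValueError("frequency separability requires binary profiles")
    if not labels.positives or not labels.negatives:
        raise ValueError("both pair classes must be non-empty")
    idx = {d: i for i, d in enumerate(profiles.drug_ids)}

    def class_freq(pairs) -> np.ndarray:
        ai = np.array([idx[a] for a, _ in pairs])
        bj = np.array([idx[b] for _, b in pairs])
        occurrence = np.maximum(vals[ai], vals[bj])  # union of member profiles
        return occurrence.mean(axis=0)

    f_pos = class_freq(sorted(labels.positives))
    f_neg = class_freq(sorted(labels.negatives))
    n_neither = int(np.sum((f_pos == 0) & (f_neg == 0)))
    n_pos_enriched = int(np.sum(f_pos > f_neg))
    n_neg_enriched = int(np.sum(f_neg > f_pos))
    sep = frequency_separability_from_counts(n_pos_enriched, n_neg_enriched)
    return n_neither, n_pos_enriched, n_neg_enriched, sep


def shared_target_counts(
    universe: DrugUniverse, labels: PairLabelSet
) -> tuple[int, int, int]:
    """Count pairs whose DTI profiles intersect, split by label.

    Returns ``(n_pos_sharing, n_neg_sharing, n_total_sharing)``.
    """
    idx = universe.id_index
    prof = universe.dti_profiles

    def count(pairs) -> int:
        return sum(
            1 for a, b in pairs if np.any(prof[idx[a]] & prof[idx[b]])
        )

    n_pos = count(labels.positives)
    n_neg = count(labels.negatives)
    return n_pos, n_neg, n_pos + n_neg


@dataclass(frozen=True)
class SeparabilityReport:
    """Per-channel separability with the supporting fractions/counts."""

    ddi: float
    atc: float
    se: float
    dti: float
    ddi_pos_frac: float
    ddi_neg_frac: float
    atc_pos_share_frac: float
    atc_neg_noshare_frac: float
    se_counts: tuple[int, int, int]  # (neither, pos-enriched, neg-enriched)
    dti_counts: tuple[int, int, int]
    target_sharing: tuple[int, int, int]

    def as_dict(self) -> dict:
        return {
            "separability": {
                "ddi": self.ddi,
                "atc": self.atc,
                "se": self.se,
                "dti": self.dti,
            },
            "ddi_fractions": {
                "positives_at_distance_2": self.ddi_pos_frac,
                "negatives_at_distance_2": self.ddi_neg_frac,
            },
            "atc_fractions": {
                "positives_sharing_code": self.atc_pos_share_frac,
                "negatives_sharing_none": self.atc_neg_noshare_frac,
            },
            "se_feature_counts": dict(
                zip(("neither", "pos_enriched", "neg_enriched"), self.se_counts)
            ),
            "dti_feature_counts": dict(
                zip(("neither", "pos_enriched", "neg_enriched"), self.dti_counts)
            ),
            "target_sharing_pairs": dict(
                zip(("positives", "negatives", "total"), self.target_sharing)
            ),
        }


def separability_report(
    universe: DrugUniverse, network: DDINetwork, labels: PairLabelSet
) -> SeparabilityReport:
    """Run the full four-channel separability analysis."""
    from .features import binary_profiles

    dist = all_pairs_shortest_paths(network)
    d_pos, d_neg, d_sep = ddi_separability(dist, labels, universe.drug_ids)
    a_pos, a_neg, a_sep = atc_separability(universe, labels)
    se_stats = frequency_separability(binary_profiles(universe, "se"), labels)
    dti_stats = frequency_separability(binary_profiles(universe, "dti"), labels)
    return SeparabilityReport(
        ddi=d_sep,
        atc=a_sep,
        se=se_stats[3],
        dti=dti_stats[3],
        ddi_pos_frac=d_pos,
        ddi_neg_frac=d_neg,
        atc_pos_share_frac=a_pos,
        atc_neg_noshare_frac=a_neg,
        se_counts=se_stats[:3],
        dti_counts=dti_stats[:3],
        target_sharing=shared_target_counts(universe, labels),
    )
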