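"""Core domain types for drug-combination prediction.

The objects here are deliberately plain: ordered drug identifiers plus
per-drug attribute containers, all validated on construction so that
downstream numerical code can assume a consistent, lexicographically
ordered drug universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: WHO ATC first-level anatomical main groups (14 letters).
ATC_ALPHABET = frozenset("ABCDGHJLMNPRSV")

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical (sorted) id order."""
    if a == b:
        raise ValueError(f"a drug cannot be paired with itself: {a!r}")
    return (a, b) if a < b else (b, a)


def all_pairs(drug_ids: Iterable[str]) -> frozenset[Pair]:
    """All C(m, 2) unordered pairs over a drug universe."""
    ids = sorted(drug_ids)
    return frozenset(
        (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
    )


@dataclass(frozen=True)
class DrugUniverse:
    """Registry of drugs with their ATC code sets and binary DTI/SE profiles.

    Attributes
    ----------
    drug_ids : tuple of str
        Unique drug identifiers, lexicographically ordered. Every matrix in
        the package uses this row order.
    atc_sets : dict
        Per-drug set of single-character first-level ATC codes (may be empty).
    dti_items, se_items : tuple of str
        Lexicographically ordered target / side-effect vocabularies shared
        by all drugs (profile column order).
    dti_profiles, se_profiles : ndarray
        ``(m, p)`` and ``(m, n_se)`` binary {0, 1} matrices; row i is the
        profile of ``drug_ids[i]``.
    """

    drug_ids: tuple[str, ...]
    atc_sets: dict[str, frozenset[str]]
    dti_items: tuple[str, ...]
    dti_profiles: np.ndarray
    se_items: tuple[str, ...]
    se_profiles: np.ndarray

    def __post_init__(self) -> None:
        ids = self.drug_ids
        if len(set(ids)) != len(ids):
            raise ValueError("drug_ids are not unique")
        if tuple(sorted(ids)) != tuple(ids):
            raise ValueError("drug_ids must be lexicographically sorted")
        if set(self.atc_sets) != set(ids):
            raise ValueError("atc_sets keys do not match drug_ids")
        for did, codes in self.atc_sets.items():
            bad = set(codes) - ATC_ALPHABET
            if bad:
                raise ValueError(
                    f"drug {did!r} has ATC codes outside the 14-letter "
                    f"first-level alphabet: {sorted(bad)}"
                )
        for name, items, prof in (
            ("dti", self.dti_items, self.dti_profiles),
            ("se", self.se_items, self.se_profiles),
        ):
            if tuple(sorted(items)) != tuple(items) or len(set(items)) != len(items):
                raise ValueError(f"{name}_items must be sorted and unique")
            if prof.shape != (len(ids), len(items)):
                raise ValueError(
                    f"{name}_profiles shape {prof.shape} does not match "
                    f"({len(ids)}, {len(items)})"
                )
            vals = np.unique(prof)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name}_profiles must be strictly binary")

    @property
    def m(self) -> int:
        return len(self.drug_ids)

    def index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    @property
    def id_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.drug_ids)}


@dataclass(frozen=True)
class DDINetwork:
    """Symmetric binary adjacency of the pharmaceutical drug-drug
    interaction network (interactions, *not* combination labels)."""

    drug_ids: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.drug_ids)
        a = self.adjacency
        if a.shape != (m, m):
            raise ValueError(f"adjacency shape {a.shape} != ({m}, {m})")
        if not np.isin(np.unique(a), (0, 1)).all():
            raise ValueError("adjacency entries must be in {0, 1}")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")

    @property
    def m(self) -> int:
        return len(self.drug_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class PairLabelSet:
    """Positive (approved combinative) pairs plus the candidate-pair scope.

    ``scope`` is the full instance set considered by cross-validation:
    positives are labelled 1 and every other scope pair is labelled 0.
    """

    positives: frozenset[Pair]
    scope: frozenset[Pair]

    def __post_init__(self) -> None:
        for pair_set, name in ((self.positives, "positives"), (self.scope, "scope")):
            for a, b in pair_set:
                if a >= b:
                    raise ValueError(
                        f"{name} pair {(a, b)} is not in canonical order"
                    )
        if not self.positives <= self.scope:
            raise ValueError("positives must be a subset of scope")

    @classmethod
    def from_pairs(
        cls,
        positives: Iterable[tuple[str, str]],
        drug_ids: Iterable[str],
        scope: Iterable[tuple[str, str]] | None = None,
    ) -> "PairLabelSet":
        """Build a label set; scope defaults to all C(m, 2) pairs."""
        pos = frozenset(canonical_pair(a, b) for a, b in positives)
        if scope is None:
            sc = all_pairs(drug_ids)
        else:
            sc = frozenset(canonical_pair(a, b) for a, b in scope)
        return cls(positives=pos, scope=sc)

    @property
    def negatives(self) -> frozenset[Pair]:
        return self.scope - self.positives

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    def labels_for(self, pairs: Iterable[Pair]) -> np.ndarray:
        """Binary label vector (1 = positive) for an ordered pair list."""
        return np.array([1 if p in self.positives else 0 for p in pairs], dtype=int)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-drug real-valued feature vectors for one channel."""

    channel: str
    drug_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.drug_ids):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric m x m drug-drug similarity with entries in [0, 1]."""

    drug_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.drug_ids)
        v = self.values
        if v.shape != (m, m):
            raise ValueError(f"similarity shape {v.shape} != ({m}, {m})")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("similarity entries must lie in [0, 1]")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
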