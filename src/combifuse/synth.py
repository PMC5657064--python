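"""Synthetic drug universes with planted combination signal.

The generator emulates the structure of a curated drug-combination
benchmark: a sparse symmetric pharmaceutical interaction graph, small
first-level ATC code sets, sparse high-dimensional binary target and
side-effect profiles, and a small positive class of combinative pairs.
Four signals observed in real data are planted, each with an intensity
controlled by ``effect_strength``:

1. combinative drugs rarely interact directly but tend to sit two steps
   apart in the DDI graph (a shared interaction partner);
2. combinative drugs tend to share a first-level ATC code;
3. combinative drugs carry side effects from a "beneficial" pattern set
   and avoid an "adverse" set;
4. combinative drugs hit a planted positive-target pattern and avoid a
   negative-target pattern.

Because the pair feature ``F_ij = f_i + f_j`` is linear in per-drug
features, a linear classifier can only exploit drug-level signal; the
generator therefore concentrates positives on a "combination-prone" drug
subset whose profiles carry the planted patterns. The concentration and
all plantings scale with ``1 - 1/effect_strength``, so at
``effect_strength = 1`` positives are uniformly random pairs and every
profile is pure background — the exact null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .datamodel import (
    DDINetwork,
    DrugUniverse,
    PairLabelSet,
    canonical_pair,
)
from . import io as cfio

_ATC_LETTERS = sorted("ABCDGHJLMNPRSV")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic benchmark.

    Defaults keep a full three-scenario 10-fold CV run fast on one CPU
    while leaving each channel's signal clearly detectable.
    """

    m: int = 120
    n_targets: int = 300
    n_se: int = 800
    n_pos: int = 100
    n_prone: int = 40          # size of the combination-prone drug subset
    ddi_density: float = 0.04  # background edge probability
    p_atc_share: float = 0.8   # planted first-level-code sharing (positives)
    p_dist2: float = 0.8       # planted distance-2 placement (positives)
    n_beneficial_se: int = 80
    n_adverse_se: int = 160
    n_pos_targets: int = 30
    n_neg_targets: int = 60
    dti_rate: float = 0.02     # background Bernoulli rate per target
    se_rate: float = 0.03      # background Bernoulli rate per side effect
    effect_strength: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 4:
            raise ValueError("need at least 4 drugs")
        if not 2 <= self.n_prone <= self.m:
            raise ValueError("n_prone must lie in [2, m]")
        for name in ("ddi_density", "p_atc_share", "p_dist2", "dti_rate", "se_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_strength < 1:
            raise ValueError("effect_strength must be >= 1")
        if self.n_pos > math.comb(self.m, 2):
            raise ValueError("n_pos exceeds the number of possible pairs")
        if self.n_pos > math.comb(self.n_prone, 2):
            raise ValueError(
                "n_pos exceeds the pairs realizable within the prone subset"
            )
        if self.n_beneficial_se + self.n_adverse_se > self.n_se:
            raise ValueError("SE pattern sets exceed the SE dimension")
        if self.n_pos_targets + self.n_neg_targets > self.n_targets:
            raise ValueError("target pattern sets exceed the target dimension")


def _sample_pairs(rng, candidates: list, n: int, taken: set) -> set:
    free = [p for p in candidates if p not in taken]
    if n > len(free):
        raise ValueError("not enough free pairs to sample positives")
    chosen = rng.choice(len(free), size=n, replace=False)
    return {free[i] for i in chosen}


def generate(config: SyntheticConfig | None = None, seed: int | None = None):
    """Generate ``(DrugUniverse, DDINetwork, PairLabelSet)``.

    Deterministic for a given config (``seed`` overrides ``config.seed``).
    """
    cfg = config or SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m
    ids = tuple(f"D{i:04d}" for i in range(m))
    scale = 1.0 - 1.0 / cfg.effect_strength

    prone = set(rng.choice(m, size=cfg.n_prone, replace=False).tolist())
    non_prone = sorted(set(range(m)) - prone)
    hub_pool = [non_prone[i] for i in rng.choice(
        len(non_prone), size=min(max(8, m // 12), len(non_prone)), replace=False
    )]

    # --- positive pairs: concentrated on prone drugs with intensity `scale`
    prone_sorted = sorted(prone)
    prone_pairs = [
        (prone_sorted[i], prone_sorted[j])
        for i in range(len(prone_sorted))
        for j in range(i + 1, len(prone_sorted))
    ]
    all_pair_list = [(i, j) for i in range(m) for j in range(i + 1, m)]
    n_planted = int(rng.binomial(cfg.n_pos, scale))
    positives: set[tuple[int, int]] = set()
    positives |= _sample_pairs(rng, prone_pairs, n_planted, positives)
    positives |= _sample_pairs(rng, all_pair_list, cfg.n_pos - n_planted, positives)

    # --- ATC sets: background 1-3 codes; planted pairs share a code
    atc: dict[int, set[str]] = {}
    for i in range(m):
        size = int(rng.integers(1, 4))
        atc[i] = set(rng.choice(_ATC_LETTERS, size=size, replace=False).tolist())
    for a, b in sorted(positives):
        if rng.random() < cfg.p_atc_share * scale and not (atc[a] & atc[b]):
            atc[b].add(sorted(atc[a])[int(rng.integers(len(atc[a])))])

    # --- DDI graph: background Erdos-Renyi; planted pairs moved to
    #     distance 2 via a shared hub, direct edge removed
    adj = np.zeros((m, m), dtype=np.int8)
    iu, ju = np.triu_indices(m, k=1)
    edges = rng.random(len(iu)) < cfg.ddi_density
    adj[iu[edges], ju[edges]] = 1
    adj += adj.T
    for a, b in sorted(positives):
        if rng.random() < cfg.p_dist2 * scale:
            adj[a, b] = adj[b, a] = 0
            h = hub_pool[int(rng.integers(len(hub_pool)))]
            if h not in (a, b):
                adj[a, h] = adj[h, a] = 1
                adj[b, h] = adj[h, b] = 1

    # --- binary profiles with planted enrichment/depletion patterns
    def profiles(n_items: int, base: float, n_up: int, n_down: int) -> tuple[np.ndarray, np.ndarray]:
        cols = rng.choice(n_items, size=n_up + n_down, replace=False)
        up, down = cols[:n_up], cols[n_up:]
        rates = np.full((m, n_items), base)
        prone_rows = sorted(prone)
        rates[np.ix_(prone_rows, up)] = min(base * cfg.effect_strength, 0.9)
        rates[np.ix_(prone_rows, down)] = base / cfg.effect_strength
        mat = (rng.random((m, n_items)) < rates).astype(np.int8)
        # every drug has all four attribute kinds (mirrors benchmark
        # filtering) and every vocabulary item occurs in at least one drug
        # (an item nobody exhibits would not be in a curated vocabulary)
        for i in np.flatnonzero(mat.sum(axis=1) == 0):
            mat[i, int(rng.integers(n_items))] = 1
        for j in np.flatnonzero(mat.sum(axis=0) == 0):
            mat[int(rng.integers(m)), j] = 1
        return mat, cols

    dti, _ = profiles(cfg.n_targets, cfg.dti_rate, cfg.n_pos_targets, cfg.n_neg_targets)
    se, _ = profiles(cfg.n_se, cfg.se_rate, cfg.n_beneficial_se, cfg.n_adverse_se)

    universe = DrugUniverse(
        drug_ids=ids,
        atc_sets={ids[i]: frozenset(atc[i]) for i in range(m)},
        dti_items=tuple(f"T{j:04d}" for j in range(cfg.n_targets)),
        dti_profiles=dti,
        se_items=tuple(f"S{j:04d}" for j in range(cfg.n_se)),
        se_profiles=se,
    )
    network = DDINetwork(drug_ids=ids, adjacency=adj)
    labels = PairLabelSet.from_pairs(
        [canonical_pair(ids[a], ids[b]) for a, b in positives], ids
    )
    return universe, network, labels


def null_config(**overrides) -> SyntheticConfig:
    """A config whose labels are independent of every feature channel."""
    return SyntheticConfig(effect_strength=1.0, **overrides)


def write_fixture(
    universe: DrugUniverse,
    network: DDINetwork,
    labels: PairLabelSet,
    out_dir,
) -> dict[str, Path]:
    """Write the five standard TSVs; the result round-trips exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "atc": out / "atc.tsv",
        "dti": out / "dti.tsv",
        "se": out / "se.tsv",
        "ddi": out / "ddi_edges.tsv",
        "positives": out / "positive_pairs.tsv",
    }
    cfio.write_universe(universe, paths["atc"], paths["dti"], paths["se"])
    cfio.write_ddi(network, paths["ddi"])
    cfio.write_labels(labels, paths["positives"])
    return paths


def read_fixture(in_dir):
    """Read a directory written by :func:`write_fixture`."""
    d = Path(in_dir)
    universe = cfio.read_universe(d / "atc.tsv", d / "dti.tsv", d / "se.tsv")
    network = cfio.read_ddi(d / "ddi_edges.tsv", universe)
    labels = cfio.read_labels(d / "positive_pairs.tsv", universe)
    return universe, network, labels
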