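"""Readers and writers for the plain TSV dialects used by the package.

Formats
-------
ATC file     : ``drug_id<TAB>code1;code2;...`` — full or first-level ATC
               codes; only the first character of each code is retained.
DTI/SE files : long format, ``drug_id<TAB>item_id``, one interaction or
               side effect per line.
DDI file     : edge list, ``drug_a<TAB>drug_b``.
Labels file  : pair list, ``drug_a<TAB>drug_b``.

All writers emit the same dialects, so any object round-trips exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .datamodel import (
    ATC_ALPHABET,
    DDINetwork,
    DrugUniverse,
    PairLabelSet,
    canonical_pair,
)


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def _rows(path: Path, n_cols: int) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated "
                    f"columns, got {len(parts)}"
                )
            out.append((lineno, parts))
    return out


def _read_atc(path: Path) -> dict[str, frozenset[str]]:
    atc: dict[str, frozenset[str]] = {}
    for lineno, (drug, codes) in _rows(path, 2):
        if drug in atc:
            raise ParseError(f"{path}:{lineno}: duplicate drug id {drug!r}")
        first = frozenset(c.strip()[0].upper() for c in codes.split(";") if c.strip())
        bad = first - ATC_ALPHABET
        if bad:
            raise ParseError(
                f"{path}:{lineno}: first-level ATC code(s) {sorted(bad)} not in "
                f"the 14-letter alphabet"
            )
        atc[drug] = first
    return atc


def _read_long(path: Path) -> dict[str, set[str]]:
    prof: dict[str, set[str]] = {}
    for _, (drug, item) in _rows(path, 2):
        prof.setdefault(drug, set()).add(item)
    return prof


def read_universe(atc_path, dti_path, se_path, *, require_all: bool = True) -> DrugUniverse:
    """Assemble a drug universe from ATC, DTI and SE files.

    By default the universe is restricted to drugs present in all three
    sources; pass ``require_all=False`` to keep the union (drugs missing a
    source get an empty ATC set / zero profile), e.g. for single-channel
    runs. Drug order is lexicographic.
    """
    atc = _read_atc(Path(atc_path))
    dti = _read_long(Path(dti_path))
    se = _read_long(Path(se_path))

    if require_all:
        keep = set(atc) & set(dti) & set(se)
    else:
        keep = set(atc) | set(dti) | set(se)
    if not keep:
        raise ValueError(
            "empty drug universe: no drug appears in "
            + ("all three sources" if require_all else "any source")
        )
    drug_ids = tuple(sorted(keep))

    dti_items = tuple(sorted({t for d in drug_ids for t in dti.get(d, ())}))
    se_items = tuple(sorted({s for d in drug_ids for s in se.get(d, ())}))

    def profile(source: dict[str, set[str]], items: tuple[str, ...]) -> np.ndarray:
        col = {t: j for j, t in enumerate(items)}
        mat = np.zeros((len(drug_ids), len(items)), dtype=np.int8)
        for i, d in enumerate(drug_ids):
            for t in source.get(d, ()):
                mat[i, col[t]] = 1
        return mat

    return DrugUniverse(
        drug_ids=drug_ids,
        atc_sets={d: atc.get(d, frozenset()) for d in drug_ids},
        dti_items=dti_items,
        dti_profiles=profile(dti, dti_items),
        se_items=se_items,
        se_profiles=profile(se, se_items),
    )


def read_ddi(edge_path, universe: DrugUniverse) -> DDINetwork:
    """Read a two-column edge list into a symmetric binary adjacency.

    Edges touching drugs outside the universe are dropped (count reported
    in a warning); self-loops are rejected with a warning and not stored.
    """
    idx = universe.id_index
    adj = np.zeros((universe.m, universe.m), dtype=np.int8)
    dropped = 0
    for lineno, (a, b) in _rows(Path(edge_path), 2):
        if a == b:
            warnings.warn(
                f"{edge_path}:{lineno}: self-loop edge ({a}, {b}) ignored"
            )
            continue
        if a not in idx or b not in idx:
            dropped += 1
            continue
        adj[idx[a], idx[b]] = 1
        adj[idx[b], idx[a]] = 1
    if dropped:
        warnings.warn(
            f"{edge_path}: dropped {dropped} edge(s) referencing drugs outside "
            f"the universe"
        )
    return DDINetwork(drug_ids=universe.drug_ids, adjacency=adj)


def read_labels(pair_path, universe: DrugUniverse, scope_path=None) -> PairLabelSet:
    """Read positive pairs; scope defaults to all C(m, 2) pairs.

    An explicit scope file (same two-column dialect) restricts the
    candidate-instance set, e.g. when the negative class is curated rather
    than exhaustive.
    """
    known = set(universe.drug_ids)

    def read_pairs(path) -> set[tuple[str, str]]:
        pairs = set()
        dropped = 0
        for lineno, (a, b) in _rows(Path(path), 2):
            if a not in known or b not in known:
                dropped += 1
                continue
            if a == b:
                raise ParseError(f"{path}:{lineno}: self-pair ({a}, {b})")
            pairs.add(canonical_pair(a, b))
        if dropped:
            warnings.warn(
                f"{path}: dropped {dropped} pair(s) referencing unknown drugs"
            )
        return pairs

    positives = read_pairs(pair_path)
    scope = read_pairs(scope_path) if scope_path is not None else None
    if scope is not None:
        scope |= positives
    return PairLabelSet.from_pairs(positives, universe.drug_ids, scope=scope)


# ---------------------------------------------------------------------------
# writers

def write_universe(universe: DrugUniverse, atc_path, dti_path, se_path) -> None:
    with open(atc_path, "w") as fh:
        for d in universe.drug_ids:
            fh.write(f"{d}\t{';'.join(sorted(universe.atc_sets[d]))}\n")
    for path, items, prof in (
        (dti_path, universe.dti_items, universe.dti_profiles),
        (se_path, universe.se_items, universe.se_profiles),
    ):
        with open(path, "w") as fh:
            for i, d in enumerate(universe.drug_ids):
                for j in np.flatnonzero(prof[i]):
                    fh.write(f"{d}\t{items[j]}\n")


def write_ddi(network: DDINetwork, edge_path) -> None:
    ids = network.drug_ids
    with open(edge_path, "w") as fh:
        for i, j in zip(*np.triu_indices(network.m, k=1)):
            if network.adjacency[i, j]:
                fh.write(f"{ids[i]}\t{ids[j]}\n")


def write_pairs(pairs, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def write_labels(labels: PairLabelSet, pair_path, scope_path=None) -> None:
    write_pairs(labels.positives, pair_path)
    if scope_path is not None:
        write_pairs(labels.scope, scope_path)
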