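import numpy as np
import pytest

from combifuse import DDINetwork, DrugUniverse, PairLabelSet


def make_universe(atc: dict[str, set[str]], dti: dict[str, set[str]] | None = None,
                  se: dict[str, set[str]] | None = None) -> DrugUniverse:
    """Build a small universe from per-drug attribute dicts."""
    ids = tuple(sorted(atc))
    dti = dti or {d: {f"t{i}"} for i, d in enumerate(ids)}
    se = se or {d: {f"s{i}"} for i, d in enumerate(ids)}
    dti_items = tuple(sorted({t for s in dti.values() for t in s}))
    se_items = tuple(sorted({t for s in se.values() for t in s}))

    def prof(source, items):
        mat = np.zeros((len(ids), len(items)), dtype=np.int8)
        col = {t: j for j, t in enumerate(items)}
        for i, d in enumerate(ids):
            for t in source.get(d, ()):
                mat[i, col[t]] = 1
        return mat

    return DrugUniverse(
        drug_ids=ids,
        atc_sets={d: frozenset(atc[d]) for d in ids},
        dti_items=dti_items,
        dti_profiles=prof(dti, dti_items),
        se_items=se_items,
        se_profiles=prof(se, se_items),
    )


def make_network(drug_ids, edges) -> DDINetwork:
    ids = tuple(sorted(drug_ids))
    idx = {d: i for i, d in enumerate(ids)}
    adj = np.zeros((len(ids), len(ids)), dtype=np.int8)
    for a, b in edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
    return DDINetwork(drug_ids=ids, adjacency=adj)


@pytest.fixture
def four_drug_universe():
    return make_universe(
        {"a": {"A"}, "b": {"A", "C"}, "c": {"N"}, "d": {"C", "N"}},
    )


@pytest.fixture
def four_drug_labels(four_drug_universe):
    return PairLabelSet.from_pairs(
        [("a", "b"), ("c", "d")], four_drug_universe.drug_ids
    )
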