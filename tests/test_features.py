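"""DDI spectral embedding, ATC Tanimoto similarity, profiles and PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combifuse import (
    ATC_ALPHABET,
    DDINetwork,
    FeatureMatrix,
    PCAConfig,
    SVDEmbeddingConfig,
    atc_similarity,
    binary_profiles,
    ddi_embedding,
    read_universe,
    reduce_pca,
)
from conftest import make_network, make_universe


class TestDDIEmbedding:
    def test_two_drug_exchange_graph_has_unit_rows(self):
        # adjacency [[0,1],[1,0]] has both singular values equal to 1
        net = make_network(["a", "b"], [("a", "b")])
        emb = ddi_embedding(net, SVDEmbeddingConfig(n_keep=None))
        norms = (emb.values**2).sum(axis=1)
        assert np.allclose(norms, [1.0, 1.0])
        assert np.isclose((emb.values**2).sum(), 2.0)

    def test_path_graph_total_energy_equals_nuclear_norm(self):
        net = make_network("abcd", [("a", "b"), ("b", "c"), ("c", "d")])
        emb = ddi_embedding(net, SVDEmbeddingConfig(n_keep=None))
        nuclear = np.linalg.svd(net.adjacency.astype(float), compute_uv=False).sum()
        assert np.isclose((emb.values**2).sum(), nuclear)

    def test_psd_matrix_reconstruction(self):
        # For T = B B' (positive semidefinite), U sqrt(S) reconstructs T.
        rng = np.random.default_rng(0)
        b = rng.normal(size=(6, 3))
        t = b @ b.T
        u, s, _ = np.linalg.svd(t, hermitian=True)
        f = u * np.sqrt(s)
        assert np.allclose(f @ f.T, t, atol=1e-8)

    def test_zero_adjacency_warns_and_degenerates(self):
        net = DDINetwork(drug_ids=("a", "b", "c"), adjacency=np.zeros((3, 3), dtype=np.int8))
        with pytest.warns(UserWarning, match="below the threshold"):
            emb = ddi_embedding(net)
        assert emb.values.shape == (3, 0)

    def test_truncation_keeps_leading_components(self):
        net = make_network("abcde", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")])
        full = ddi_embedding(net, SVDEmbeddingConfig(n_keep=None))
        trunc = ddi_embedding(net, SVDEmbeddingConfig(n_keep=2))
        assert trunc.values.shape[1] == 2
        assert np.allclose(trunc.values, full.values[:, :2])

    def test_isolated_drug_gets_zero_row(self):
        net = make_network("abc", [("a", "b")])
        emb = ddi_embedding(net, SVDEmbeddingConfig(n_keep=None))
        assert np.allclose(emb.values[2], 0.0)

    def test_deterministic_across_runs(self):
        net = make_network("abcdef", [("a", "b"), ("c", "d"), ("b", "e"), ("a", "f")])
        e1 = ddi_embedding(net)
        e2 = ddi_embedding(net)
        assert np.array_equal(e1.values, e2.values)


class TestATCSimilarity:
    def test_worked_example_one_sixth(self):
        u = make_universe({"ond": {"A"}, "dex": {"A", "C", "D", "H", "R", "S"}})
        sim = atc_similarity(u)
        assert sim.values[0, 1] == pytest.approx(1 / 6)

    def test_identical_and_disjoint_sets(self):
        u = make_universe({"a": {"A", "C"}, "b": {"A", "C"}, "c": {"N"}})
        sim = atc_similarity(u)
        assert sim.values[0, 1] == 1.0
        assert sim.values[0, 2] == 0.0
        assert np.array_equal(np.diag(sim.values), [1.0, 1.0, 1.0])

    def test_empty_sets_give_zero_with_note(self):
        u = make_universe({"a": set(), "b": set(), "c": {"A"}})
        with pytest.warns(UserWarning, match="empty ATC"):
            sim = atc_similarity(u)
        assert sim.values[0, 1] == 0.0
        assert sim.values[0, 0] == 0.0  # empty diagonal is 0, not 1

    @settings(deadline=None, max_examples=25)
    @given(
        s1=st.sets(st.sampled_from(sorted(ATC_ALPHABET)), min_size=1, max_size=5),
        s2=st.sets(st.sampled_from(sorted(ATC_ALPHABET)), min_size=1, max_size=5),
    )
    def test_tanimoto_properties(self, s1, s2):
        u = make_universe({"a": s1, "b": s2})
        v = atc_similarity(u).values
        assert 0.0 <= v[0, 1] <= 1.0
        assert v[0, 1] == v[1, 0]
        assert (v[0, 1] == 1.0) == (s1 == s2)


class TestBinaryProfiles:
    def test_rows_follow_item_order(self):
        u = make_universe({"a": {"A"}, "b": {"A"}}, dti={"a": {"t1", "t3"}, "b": {"t2"}})
        fm = binary_profiles(u, "dti")
        assert fm.values.tolist() == [[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]

    def test_column_sums_conserve_long_format_counts(self, tmp_path):
        (tmp_path / "atc.tsv").write_text("a\tA\nb\tB\nc\tC\n")
        (tmp_path / "dti.tsv").write_text("a\tt1\nb\tt1\nc\tt2\na\tt2\n")
        (tmp_path / "se.tsv").write_text("a\ts1\nb\ts1\nc\ts1\n")
        u = read_universe(tmp_path / "atc.tsv", tmp_path / "dti.tsv", tmp_path / "se.tsv")
        fm = binary_profiles(u, "dti")
        assert fm.values.sum(axis=0).tolist() == [2.0, 2.0]  # t1, t2 counts

    def test_unknown_channel_rejected(self, four_drug_universe):
        with pytest.raises(ValueError, match="channel"):
            binary_profiles(four_drug_universe, "atc")


class TestReducePCA:
    def _toy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 4))
        return FeatureMatrix(channel="dti", drug_ids=tuple("abcde"), values=x)

    def test_matches_covariance_eigendecomposition_up_to_sign(self):
        fm = self._toy()
        out = reduce_pca(fm, PCAConfig(n_components=3)).values
        xc = fm.values - fm.values.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc, rowvar=False, ddof=1))
        order = np.argsort(evals)[::-1]
        oracle = xc @ evecs[:, order[:3]]
        for k in range(3):
            assert np.allclose(out[:, k], oracle[:, k], atol=1e-8) or np.allclose(
                out[:, k], -oracle[:, k], atol=1e-8
            )

    def test_scores_are_uncorrelated(self):
        rng = np.random.default_rng(5)
        fm = FeatureMatrix(channel="se", drug_ids=tuple(f"d{i}" for i in range(30)),
                           values=rng.random((30, 10)))
        out = reduce_pca(fm, PCAConfig(n_components=5)).values
        cov = np.cov(out, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() <= 1e-8

    def test_rank_one_data_fully_explained_by_one_component(self):
        v = np.array([1.0, 2.0, 3.0])
        coef = np.array([[1.0], [2.0], [-1.0], [0.5]])
        fm = FeatureMatrix(channel="dti", drug_ids=tuple("abcd"), values=coef * v + 7.0)
        out = reduce_pca(fm, PCAConfig(n_components=1)).values
        xc = fm.values - fm.values.mean(axis=0)
        assert np.isclose((out**2).sum(), (xc**2).sum())  # all variance captured

    def test_requesting_beyond_rank_clips_with_warning(self):
        fm = self._toy()  # rank <= 4 (5 rows, centered -> 4)
        with pytest.warns(UserWarning, match="retaining"):
            out = reduce_pca(fm, PCAConfig(n_components=10))
        assert out.values.shape[1] <= 4

    def test_deterministic_sign_convention(self):
        fm = self._toy()
        a = reduce_pca(fm, PCAConfig(n_components=2)).values
        b = reduce_pca(fm, PCAConfig(n_components=2)).values
        assert np.array_equal(a, b)
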