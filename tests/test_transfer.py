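"""Label transfer: normalization algebra, embedding, kNN mode vote, tie-break."""

import numpy as np
import pytest
from scipy import sparse

import scmultiome as sm
from scmultiome import transfer
from conftest import small_config


class TestLognormalize:
    def test_zero_count_maps_to_zero(self):
        out = transfer.lognormalize(np.array([[0.0, 2.0], [4.0, 2.0]]))
        assert out[0, 0] == 0.0

    def test_equal_libraries_give_unit_factors(self):
        counts = np.array([[2.0, 2.0], [3.0, 3.0]])
        out = transfer.lognormalize(counts)
        assert np.allclose(out, np.log1p(counts))

    def test_doubled_depth_cell_is_normalized_away(self):
        """Algebraic check: a cell whose counts are exactly double another's
        gets double the size factor, hence identical normalized values."""
        rng = np.random.default_rng(1)
        base = rng.poisson(5.0, size=20).astype(float) + 1
        counts = np.column_stack([base, 2 * base, rng.poisson(4.0, 20) + 1.0])
        out = transfer.lognormalize(counts)
        assert np.allclose(out[:, 0], out[:, 1])

    def test_sparse_matches_dense(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(1.0, size=(30, 6)).astype(float)
        counts[:, 0] += 1  # avoid empty cell
        counts[0] += 1
        dense = transfer.lognormalize(counts)
        sp = transfer.lognormalize(sparse.csr_matrix(counts))
        assert np.allclose(sp.toarray(), dense)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="zero library"):
            transfer.lognormalize(np.array([[0.0, 1.0]]))


class TestHVGs:
    def test_constant_gene_never_beats_varying(self):
        mat = np.vstack([np.ones(10), np.linspace(0, 1, 10)])
        got = transfer.select_hvgs(mat, ["const", "vary"], 1)
        assert list(got) == ["vary"]

    def test_all_genes_when_n_equals_total(self):
        mat = np.random.default_rng(0).normal(size=(5, 8))
        got = transfer.select_hvgs(mat, list("abcde"), 5)
        assert sorted(got) == list("abcde")

    def test_planted_high_variance_set_recovered(self):
        rng = np.random.default_rng(3)
        mat = np.zeros((20, 30))
        planted = [2, 5, 11]
        for g in planted:
            mat[g] = rng.normal(size=30)
        names = [f"g{i}" for i in range(20)]
        got = transfer.select_hvgs(mat, names, 3)
        assert sorted(got) == sorted(f"g{i}" for i in planted)

    def test_groupwise_variance_mode(self):
        # gene 0 varies within groups but has equal group means; gene 1 varies
        # across group means only
        groups = np.array(["a"] * 5 + ["b"] * 5)
        g0 = np.concatenate([[-1, 1, -1, 1, 0], [-1, 1, -1, 1, 0]])
        g1 = np.concatenate([np.zeros(5), np.ones(5)])
        got = transfer.select_hvgs(np.vstack([g0, g1]), ["within", "between"], 1,
                                   groups=groups)
        assert list(got) == ["between"]

    def test_too_many_requested_rejected(self):
        with pytest.raises(ValueError):
            transfer.select_hvgs(np.ones((3, 4)), list("abc"), 5)


class TestJointEmbed:
    def test_identical_query_gets_identical_coordinates(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(10, 20))
        names = [f"g{i}" for i in range(10)]
        emb = transfer.joint_embed(mat, mat, names, names, d=3)
        assert np.allclose(emb.reference_coords, emb.query_coords)

    def test_two_cluster_toy_separates_on_first_component(self):
        """Two well-separated clusters project to separated means at d=1."""
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 0.1, size=(5, 15))
        b = rng.normal(5.0, 0.1, size=(5, 15))
        mat = np.hstack([a, b])
        names = [f"g{i}" for i in range(5)]
        emb = transfer.joint_embed(mat, mat[:, :0], names, names, d=1)
        coords = emb.reference_coords.ravel()
        gap = abs(coords[:15].mean() - coords[15:].mean())
        spread = max(coords[:15].std(), coords[15:].std())
        assert gap > 10 * spread

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(8, 12))
        names = [f"g{i}" for i in range(8)]
        emb = transfer.joint_embed(mat, mat, names, names, d=2)
        perm = rng.permutation(12)
        emb_p = transfer.joint_embed(mat, mat[:, perm], names, names, d=2)
        assert np.allclose(np.abs(emb_p.query_coords), np.abs(emb.query_coords[perm]), atol=1e-8)

    def test_d_larger_than_hvgs_rejected(self):
        mat = np.ones((3, 4))
        with pytest.raises(ValueError, match="d="):
            transfer.joint_embed(mat, mat, list("abc"), list("abc"), d=5)


def _embedding(ref, query):
    coords = np.vstack([ref, query]).astype(float)
    role = np.array(["reference"] * len(ref) + ["query"] * len(query), dtype=object)
    return transfer.JointEmbedding(coords, role, np.array([]), np.empty((0, 0)), np.empty(0))


class TestKnnTransfer:
    def test_coincident_query_k1_takes_that_label(self):
        ref = np.array([[0.0, 0.0], [10.0, 0.0]])
        emb = _embedding(ref, ref[:1])
        res = transfer.knn_transfer(emb, ["A", "B"], k=1)
        assert res.labels[0] == "A"

    def test_unique_mode_wins(self):
        # 13 "A" slightly farther, 12 "B" nearer: mode still wins
        ref = np.vstack([
            np.linspace(2.0, 2.5, 13)[:, None] * [1, 0],
            np.linspace(1.0, 1.5, 12)[:, None] * [1, 0],
        ])
        labels = ["A"] * 13 + ["B"] * 12
        res = transfer.knn_transfer(_embedding(ref, np.array([[0.0, 0.0]])), labels, k=25)
        assert res.labels[0] == "A"
        assert not res.assignments["tie"][0]
        assert res.assignments["modal_count"][0] == 13

    def test_tie_resolved_by_nearest_reference_cell(self):
        # 10 "A", 10 "B", 5 "C"; the single nearest cell is a "B"
        ref = np.vstack([
            np.linspace(2.0, 2.9, 10)[:, None] * [1, 0],   # A
            np.vstack([[0.5, 0.0], *np.linspace(3.0, 3.8, 9)[:, None] * [1, 0]]),  # B, nearest first
            np.linspace(4.0, 4.4, 5)[:, None] * [1, 0],    # C
        ])
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 5
        res = transfer.knn_transfer(_embedding(ref, np.array([[0.0, 0.0]])), labels, k=25)
        assert res.labels[0] == "B"
        assert res.assignments["tie"][0]

    def test_k_validation(self):
        emb = _embedding(np.zeros((3, 2)), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            transfer.knn_transfer(emb, list("abc"), k=0)
        with pytest.raises(ValueError):
            transfer.knn_transfer(emb, list("abc"), k=4)


@pytest.fixture(scope="module")
def fitted():
    cfg = small_config(n_cells=800, seed=5)
    ds, truth = sm.simulate_multiome(cfg)
    atlas = sm.simulate_reference_atlas(cfg, 300)
    model = sm.LabelTransfer(atlas, ds.rna_counts, ds.gene_names,
                             exclusion=sm.GeneExclusionRules())
    return model.fit(k=25, d=20), truth


class TestEndToEnd:
    def test_transfer_accuracy_on_separated_clusters(self, fitted):
        res, truth = fitted
        assert res.accuracy(truth.celltype_per_cell) >= 0.95

    def test_confusion_matrix_row_stochastic(self, fitted):
        res, truth = fitted
        conf = res.confusion(truth.celltype_per_cell)
        assert np.allclose(conf.sum(axis=1), 1.0)

    def test_summary_mentions_k_and_counts(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "k: 25" in text and "query cells: 800" in text

    def test_self_transfer_k1_reproduces_labels(self):
        cfg = small_config(n_cells=300, seed=9)
        atlas = sm.simulate_reference_atlas(cfg, 200)
        emb = transfer.JointEmbedding(
            np.vstack([atlas.embedding, atlas.embedding]),
            np.array(["reference"] * 200 + ["query"] * 200, dtype=object),
            np.array([]), np.empty((0, 0)), np.empty(0),
        )
        res = transfer.knn_transfer(emb, atlas.labels, k=1)
        assert np.array_equal(res.labels, atlas.labels)

    def test_scale_invariance_of_assignments(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(50, 3))
        query = rng.normal(size=(20, 3))
        labels = rng.choice(list("xyz"), 50)
        r1 = transfer._knn_assign(ref, query, labels, k=5)
        r2 = transfer._knn_assign(ref * 3.7, query * 3.7, labels, k=5)
        assert np.array_equal(r1.labels, r2.labels)
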