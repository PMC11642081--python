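"""Hypergraph construction, co-occurrence adjacency and centrality."""

import numpy as np
import pandas as pd
import pytest

from comorbinet import (CooccurrenceAdjacency, HyperedgeCatalog, adjacency,
                        build_incidence, catalog_hyperedges, centrality,
                        export_hypergraph, filter_catalog)


def toy_incidence(columns, n_diseases=3, ids=("A", "B", "C")):
    """Incidence from a list of disease-index sets (one per patient)."""
    from comorbinet import IncidenceMatrix

    M = np.zeros((n_diseases, len(columns)), dtype=int)
    for j, members in enumerate(columns):
        M[list(members), j] = 1
    return IncidenceMatrix(M=M, disease_ids=tuple(ids[:n_diseases]),
                           patient_ids=tuple(f"p{j}" for j in range(len(columns))))


def brute_force_cooccurrence(M):
    n = M.shape[0]
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j:
                A[i, j] = int(sum(M[i, p] and M[j, p] for p in range(M.shape[1])))
    return A


class TestBuildIncidence:
    def test_multimorbid_columns_only(self, cohort_builder, codebook):
        flags = np.zeros((5, 26), int)
        flags[0, :2] = 1
        flags[1, :3] = 1
        flags[2, 0] = 1          # single disease: excluded
        inc = build_incidence(cohort_builder(flags), min_diseases=2)
        assert inc.n_patients == 2
        assert (inc.M.sum(axis=0) >= 2).all()
        assert inc.disease_ids == tuple(codebook.diseases)

    def test_no_multimorbid_patient_rejected(self, cohort_builder):
        flags = np.zeros((4, 26), int)
        flags[:, 0] = 1
        with pytest.raises(ValueError):
            build_incidence(cohort_builder(flags), min_diseases=2)

    def test_toy_column_sums(self):
        inc = toy_incidence([{0, 1}, {0, 1}, {0, 2}])
        assert list(inc.M.sum(axis=0)) == [2, 2, 2]


class TestCatalog:
    def test_grouping_and_counts(self):
        inc = toy_incidence([{0, 1}, {0, 1}, {0, 2}])
        cat = catalog_hyperedges(inc)
        assert cat.entries == {("A", "B"): 2, ("A", "C"): 1}

    def test_counts_conserve_patients(self):
        rng = np.random.default_rng(7)
        cols = [set(np.flatnonzero(rng.random(6) < 0.5)) for _ in range(40)]
        cols = [c if len(c) >= 2 else {0, 1} for c in cols]
        inc = toy_incidence(cols, n_diseases=6, ids="ABCDEF")
        cat = catalog_hyperedges(inc)
        assert cat.total_occurrences == 40

    def test_all_identical_columns(self):
        inc = toy_incidence([{0, 2}] * 7)
        cat = catalog_hyperedges(inc)
        assert cat.entries == {("A", "C"): 7}

    def test_filter_threshold(self):
        cat = HyperedgeCatalog({("A", "B"): 9, ("A", "C"): 7})
        assert filter_catalog(cat, 8).entries == {("A", "B"): 9}
        assert filter_catalog(cat, 1).entries == cat.entries
        assert filter_catalog(HyperedgeCatalog({("A", "B"): 2}), 5).entries == {}

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            HyperedgeCatalog({("A",): 3})
        with pytest.raises(ValueError):
            HyperedgeCatalog({("B", "A"): 3})


class TestAdjacency:
    def test_worked_example(self):
        inc = toy_incidence([{0, 1}, {0, 1}, {0, 2}, {1, 2}])
        adj = adjacency(inc)
        assert adj.A[0, 1] == 2 and adj.A[0, 2] == 1 and adj.A[1, 2] == 1
        assert (np.diag(adj.A) == 0).all()

    def test_repeated_pair_counts(self):
        inc = toy_incidence([{0, 1}] * 5)
        assert adjacency(inc).A[0, 1] == 5

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_p = rng.integers(2, 30)
            M = (rng.random((8, n_p)) < 0.35).astype(int)
            M[:2, M.sum(axis=0) < 2] = 1  # ensure every column is multimorbid
            inc = toy_incidence([set(np.flatnonzero(M[:, j])) for j in range(n_p)],
                                n_diseases=8, ids="ABCDEFGH")
            np.testing.assert_array_equal(adjacency(inc).A,
                                          brute_force_cooccurrence(inc.M))

    def test_handshake_identity(self):
        rng = np.random.default_rng(13)
        M = (rng.random((8, 40)) < 0.4).astype(int)
        M[:2, M.sum(axis=0) < 2] = 1
        inc = toy_incidence([set(np.flatnonzero(M[:, j])) for j in range(40)],
                            n_diseases=8, ids="ABCDEFGH")
        A = adjacency(inc).A
        d = inc.M.sum(axis=0)
        assert np.triu(A, 1).sum() == (d * (d - 1) // 2).sum()

    def test_symmetry(self):
        rng = np.random.default_rng(17)
        M = (rng.random((6, 25)) < 0.5).astype(int)
        M[:2, M.sum(axis=0) < 2] = 1
        inc = toy_incidence([set(np.flatnonzero(M[:, j])) for j in range(25)],
                            n_diseases=6, ids="ABCDEF")
        A = adjacency(inc).A
        np.testing.assert_array_equal(A, A.T)

    def test_proportions_diagonal_variant(self):
        inc = toy_incidence([{0, 1}, {0, 1}])
        adj = adjacency(inc, diagonal="proportions")
        assert adj.A[0, 0] == pytest.approx(2 - 1.0)  # count minus prevalence
        assert adj.A[0, 1] == 2


def make_adjacency(A, ids=None):
    A = np.asarray(A, dtype=float)
    ids = ids or tuple(chr(65 + i) for i in range(A.shape[0]))
    return CooccurrenceAdjacency(A=A, D_n=np.diag(np.diag(A)), disease_ids=ids)


class TestCentrality:
    def test_two_disease_symmetric_case(self):
        for c in (1, 3, 17):
            scores = centrality(make_adjacency([[0, c], [c, 0]]))
            np.testing.assert_allclose(scores.scores.to_numpy(),
                                       [1 / np.sqrt(2)] * 2, atol=1e-14)

    def test_star_hub_has_unique_maximum(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 2
        scores = centrality(make_adjacency(A)).scores
        assert scores.idxmax() == "A"
        assert scores["A"] > scores.drop("A").max() + 0.1

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            n = rng.integers(3, 12)
            A = rng.integers(0, 6, (n, n))
            A = np.triu(A, 1)
            A = A + A.T
            if not A.any():
                continue
            scores = centrality(make_adjacency(A)).scores.to_numpy()
            w, V = np.linalg.eigh(A)
            v = V[:, -1]
            v = v if v[np.argmax(np.abs(v))] > 0 else -v
            np.testing.assert_allclose(scores, v, atol=1e-8)

    def test_unit_norm_and_nonnegative(self):
        rng = np.random.default_rng(23)
        A = rng.integers(0, 4, (7, 7))
        A = np.triu(A, 1) + np.triu(A, 1).T
        scores = centrality(make_adjacency(A)).scores.to_numpy()
        assert np.linalg.norm(scores) == pytest.approx(1.0)
        assert (scores >= 0).all()

    def test_isolated_disease_scores_zero(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 4
        scores = centrality(make_adjacency(A)).scores
        assert scores["C"] == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(29)
        A = rng.integers(0, 5, (6, 6))
        A = np.triu(A, 1) + np.triu(A, 1).T
        perm = rng.permutation(6)
        base = centrality(make_adjacency(A)).scores.to_numpy()
        permed = centrality(make_adjacency(A[np.ix_(perm, perm)])).scores.to_numpy()
        np.testing.assert_allclose(permed, base[perm], atol=1e-10)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            centrality(make_adjacency(np.zeros((3, 3))))


class TestExport:
    def test_round_trip(self, tmp_path):
        inc = toy_incidence([{0, 1}] * 9 + [{0, 2}] * 3)
        cat = catalog_hyperedges(inc)
        scores = centrality(adjacency(inc))
        paths = export_hypergraph(filter_catalog(cat, 2), scores, tmp_path)
        edges = pd.read_csv(paths["hyperedges"], sep="\t")
        assert dict(zip(edges["diseases"], edges["count"])) == {"A|B": 9, "A|C": 3}
        nodes = pd.read_csv(paths["nodes"], sep="\t")
        assert set(nodes["disease"]) == {"A", "B", "C"}

    def test_empty_catalog_warns_nodes_only(self, tmp_path):
        inc = toy_incidence([{0, 1}] * 3)
        scores = centrality(adjacency(inc))
        with pytest.warns(UserWarning, match="empty"):
            paths = export_hypergraph(filter_catalog(catalog_hyperedges(inc), 99),
                                      scores, tmp_path)
        assert "hyperedges" not in paths
        assert paths["nodes"].exists()
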