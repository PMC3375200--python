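"""Functional distances: annotation projection, Mahalanobis, Resnik,
group matrices, dendrogram permutation test and profiles."""

import io
import itertools

import numpy as np
import obonet
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netphylo.funcspace import (are_siblings, build_annotation_matrix,
                                cluster_group_matrix, corr_funcdist_vs_agediff,
                                dendrogram_with_permutation,
                                funcdist_by_network_distance, mahalanobis_distance,
                                pairwise_mahalanobis, resnik_gene_distance,
                                sub_root_terms, term_ancestors,
                                term_information_content, tg_functional_matrix)
from netphylo.io import GroupMatrix


class TestAnnotationMatrix:
    def test_direct_subroot_annotation(self, toy_obo):
        am = build_annotation_matrix({"g": {"T:0001"}}, toy_obo)
        row = dict(zip(am.terms, am.X[0]))
        assert row == {"T:0001": 1, "T:0002": 0, "T:0003": 0}

    def test_grandchild_with_two_subroot_ancestors(self, toy_obo):
        am = build_annotation_matrix({"g": {"T:0012"}}, toy_obo)
        row = dict(zip(am.terms, am.X[0]))
        assert row == {"T:0001": 0, "T:0002": 1, "T:0003": 1}

    def test_matches_independent_dag_traversal(self, toy_obo):
        """Projection equals an oracle closure computed by BFS over is_a edges."""
        rng = np.random.default_rng(4)
        terms = [t for t in toy_obo.nodes
                 if toy_obo.nodes[t].get("namespace") == "biological_process"
                 and t != "T:0000"]
        ann = {f"g{i}": set(rng.choice(terms, size=rng.integers(1, 3), replace=False))
               for i in range(30)}
        am = build_annotation_matrix(ann, toy_obo)
        subroots = set(sub_root_terms(toy_obo, "biological_process"))
        idx = {t: j for j, t in enumerate(am.terms)}
        for i, g in enumerate(am.genes):
            # oracle: explicit frontier expansion, independent of term_ancestors
            closure = set()
            frontier = set(ann[g])
            while frontier:
                t = frontier.pop()
                closure.add(t)
                for _, parent, key in toy_obo.out_edges(t, keys=True):
                    if key == "is_a" and parent not in closure:
                        frontier.add(parent)
            expected = closure & subroots
            assert {t for t in am.terms if am.X[i, idx[t]]} == expected

    def test_zero_gene_flagged(self, toy_obo):
        am = build_annotation_matrix({"g": set(), "h": {"T:0001"}}, toy_obo)
        assert am.zero_genes == ["g"]

    def test_pseudoinverse_identity(self, default_funcspace):
        am = default_funcspace["am"]
        prod = am.cov @ am.cov_inverse @ am.cov
        assert np.allclose(prod, am.cov, atol=1e-8)


class TestMahalanobis:
    def test_zero_for_identical(self):
        assert mahalanobis_distance([1, 0, 1], [1, 0, 1], np.eye(3)) == 0.0

    def test_identity_cov_is_euclidean(self):
        assert mahalanobis_distance([1, 0], [0, 1], np.eye(2)) == pytest.approx(np.sqrt(2))

    def test_matches_linear_solve_oracle(self):
        cov = np.array([[2.0, 0.3, 0.1], [0.3, 1.5, 0.2], [0.1, 0.2, 1.0]])
        x = np.array([1.0, 0.0, 1.0])
        y = np.array([0.0, 1.0, 0.0])
        d = x - y
        expected = np.sqrt(d @ np.linalg.solve(cov, d))
        got = mahalanobis_distance(x, y, np.linalg.inv(cov))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mahalanobis_distance([1, 0], [1, 0, 0], np.eye(3))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_identity_cov_equals_euclidean_on_random_binary(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, size=20)
        y = rng.integers(0, 2, size=20)
        got = mahalanobis_distance(x, y, np.eye(20))
        assert abs(got - np.linalg.norm(x - y)) <= 1e-10

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(5, 5))
        vi = A @ A.T + 0.1 * np.eye(5)  # positive definite
        x, y = rng.normal(size=5), rng.normal(size=5)
        d1 = mahalanobis_distance(x, y, vi)
        assert d1 >= 0
        assert d1 == pytest.approx(mahalanobis_distance(y, x, vi), rel=1e-10)

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(12, 6)).astype(float)
        A = rng.normal(size=(6, 6))
        vi = A @ A.T + 0.2 * np.eye(6)
        D = pairwise_mahalanobis(X, vi, block=5)
        for i in range(12):
            for j in range(12):
                assert D[i, j] == pytest.approx(
                    mahalanobis_distance(X[i], X[j], vi), abs=1e-8)


class TestResnik:
    def test_root_only_overlap_gives_distance_one(self, toy_obo):
        ann = {"a": {"T:0001"}, "b": {"T:0002"}, "c": {"T:0001"}, "d": {"T:0002"}}
        ic = term_information_content(ann, toy_obo)
        d = resnik_gene_distance({"T:0001"}, {"T:0002"}, toy_obo, ic)
        assert d == pytest.approx(1.0)  # MICA is the root, IC 0

    def test_quarter_probability_term(self, toy_obo):
        # T:0011 hit by 1 of 4 genes -> p = 1/4, IC = 2 bits, distance 1/4
        ann = {"a": {"T:0011"}, "b": {"T:0002"}, "c": {"T:0002"}, "d": {"T:0003"}}
        ic = term_information_content(ann, toy_obo)
        d = resnik_gene_distance({"T:0011"}, {"T:0011"}, toy_obo, ic)
        assert d == pytest.approx(0.25)

    def test_empty_gene_missing(self, toy_obo):
        ic = {"T:0000": 0.0}
        assert resnik_gene_distance(set(), {"T:0001"}, toy_obo, ic) is None

    def test_matches_exhaustive_ancestor_oracle(self, toy_obo):
        """Distance equals brute force over all ancestor pairs of all term pairs."""
        rng = np.random.default_rng(6)
        terms = [t for t in toy_obo.nodes
                 if toy_obo.nodes[t].get("namespace") == "biological_process"]
        ann = {f"g{i}": set(rng.choice(terms, size=rng.integers(1, 4), replace=False))
               for i in range(10)}
        ic = term_information_content(ann, toy_obo)
        genes = sorted(ann)
        for a, b in itertools.combinations(genes, 2):
            best = 0.0
            for t1 in ann[a]:
                for t2 in ann[b]:
                    common = term_ancestors(toy_obo, t1) & term_ancestors(toy_obo, t2)
                    for c in common:
                        best = max(best, ic.get(c, 0.0))
            got = resnik_gene_distance(ann[a], ann[b], toy_obo, ic)
            assert got == pytest.approx(0.5 ** best)


class TestGroupFunctionalMatrix:
    def test_identical_annotations_give_zero(self):
        D = np.zeros((12, 12))
        genes = [f"g{i}" for i in range(12)]
        groups = {g: (i % 6) + 1 for i, g in enumerate(genes)}
        mat = tg_functional_matrix(D, genes, groups)
        assert np.allclose(mat.values, 0.0)

    def test_disjoint_single_terms_identity_cov(self):
        # TG1 genes carry term 0, TG2 genes carry term 1; identity covariance
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        D = pairwise_mahalanobis(X, np.eye(2))
        genes = ["a", "b", "c", "d"]
        groups = {"a": 1, "b": 1, "c": 2, "d": 2}
        mat = tg_functional_matrix(D, genes, groups)
        assert mat.values[0, 1] == pytest.approx(np.sqrt(2))
        assert mat.values[0, 0] == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(13)
        n = 50
        genes = [f"g{i}" for i in range(n)]
        groups = {g: int(rng.integers(1, 7)) for g in genes}
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        mat = tg_functional_matrix(D, genes, groups)
        sums = np.zeros((6, 6))
        counts = np.zeros((6, 6), dtype=int)
        for i, j in itertools.combinations(range(n), 2):
            m, k = sorted((groups[genes[i]] - 1, groups[genes[j]] - 1))
            sums[m, k] += D[i, j]
            counts[m, k] += 1
        for m in range(6):
            for k in range(m, 6):
                if counts[m, k]:
                    assert mat.values[m, k] == pytest.approx(sums[m, k] / counts[m, k])


class TestAgeCorrelation:
    def test_perfect_gradient_gives_rho_one(self):
        idx = np.arange(1, 7, dtype=float)
        values = np.abs(idx[:, None] - idx[None, :]) + 1.0
        mat = GroupMatrix(values, np.full((6, 6), 5), "functional_distance")
        rho, _ = corr_funcdist_vs_agediff(mat)
        assert rho == pytest.approx(1.0)

    def test_random_matrices_average_near_zero(self):
        rng = np.random.default_rng(21)
        rhos = []
        for _ in range(30):
            v = rng.random((6, 6))
            mat = GroupMatrix((v + v.T) / 2, np.full((6, 6), 5),
                              "functional_distance")
            rhos.append(corr_funcdist_vs_agediff(mat)[0])
        assert abs(np.mean(rhos)) < 0.2

    def test_age_scale_mya_requires_ages(self):
        mat = GroupMatrix(np.ones((6, 6)), np.full((6, 6), 5))
        with pytest.raises(ValueError):
            corr_funcdist_vs_agediff(mat, age_scale="mya")


class TestDendrogram:
    def test_planted_gradient_detected(self, default_ds, default_funcspace):
        """Age-graded annotations make the TG tree non-random."""
        fs = default_funcspace
        res = dendrogram_with_permutation(fs["D"], fs["am"].genes,
                                          default_ds.groups, reps=99, seed=5)
        assert res.p <= 0.05
        assert 0 < res.p <= 1

    def test_six_leaves_five_merges(self, default_ds, default_funcspace):
        fs = default_funcspace
        res = dendrogram_with_permutation(fs["D"], fs["am"].genes,
                                          default_ds.groups, reps=5, seed=1)
        assert res.Z.shape == (5, 4)
        assert res.newick.count(",") == 5
        heights = res.Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)  # nondecreasing merges

    def test_rho_positive_with_either_backend(self, default_ds, default_funcspace, toy_obo):
        """Mahalanobis and Resnik backends agree on the age-gradient direction."""
        ds = default_ds
        fs = default_funcspace
        mat = tg_functional_matrix(fs["D"], fs["am"].genes, ds.groups)
        assert corr_funcdist_vs_agediff(mat)[0] > 0
        # Resnik over the full gene set (vectorized path)
        obo = obonet.read_obo(io.StringIO(ds.obo_text))
        ic = term_information_content(ds.annotations, obo)
        from netphylo.funcspace import pairwise_resnik
        D, genes = pairwise_resnik(ds.annotations, obo, ic)
        mat2 = tg_functional_matrix(D, genes, ds.groups)
        assert corr_funcdist_vs_agediff(mat2)[0] > 0


class TestProfile:
    def test_constant_distance_flat_profile(self):
        genes = [f"g{i}" for i in range(10)]
        D = np.ones((10, 10))
        distances = {g: {h: 1 + (i + j) % 3 for j, h in enumerate(genes) if h != g}
                     for i, g in enumerate(genes)}
        prof = funcdist_by_network_distance(D, genes, distances)
        vals = prof["mean_functional_distance"]
        assert np.allclose(vals[~np.isnan(vals)], 1.0)

    def test_subsample_close_to_exhaustive(self, default_funcspace):
        fs = default_funcspace
        genes = fs["am"].genes[:200]
        full = funcdist_by_network_distance(fs["D"], genes, fs["distances"])
        sub = funcdist_by_network_distance(fs["D"], genes, fs["distances"],
                                           max_pairs=5000, seed=9)
        ok = ~np.isnan(full["mean_functional_distance"])
        diff = np.abs(full["mean_functional_distance"][ok]
                      - sub["mean_functional_distance"][ok])
        assert np.nanmax(diff) < 0.25  # Monte-Carlo error at 5k of ~20k pairs

    def test_neighbor_coherence_raises_profile(self):
        """With full hub coherence, close pairs are functionally tighter."""
        from netphylo.simulate import GeneratorConfig, generate_dataset
        from netphylo.topology import all_pairs_distances

        ds = generate_dataset(GeneratorConfig(n_final=800, hub_coherence=1.0, seed=3))
        obo = obonet.read_obo(io.StringIO(ds.obo_text))
        am = build_annotation_matrix(ds.annotations, obo,
                                     gene_order=sorted(ds.net.graph.nodes))
        D = pairwise_mahalanobis(am.X, am.cov_inverse)
        prof = funcdist_by_network_distance(D, am.genes,
                                            all_pairs_distances(ds.net))
        v = prof["mean_functional_distance"]
        assert v[0] < v[2] and v[1] < v[2]
        assert prof["rho"] > 0
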