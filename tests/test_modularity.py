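"""Hub coherence machinery: rewiring, group distances, nulls, enrichment."""

import itertools

import networkx as nx
import numpy as np
import pytest

from netphylo.io import PPINetwork
from netphylo.modularity import (controlled_correlation, distance2_baseline,
                                 edge_overlap, group_term_enrichment,
                                 hub_group_distance, hub_null_comparison,
                                 property_zscore_enrichment,
                                 rewire_degree_preserving)


def degree_seq(net):
    return sorted(d for _, d in net.graph.degree)


class TestRewiring:
    @pytest.mark.parametrize("maker", [
        lambda: nx.gnm_random_graph(40, 120, seed=1),
        lambda: nx.cycle_graph(4),
        lambda: nx.barbell_graph(6, 2),
    ])
    def test_degree_sequence_preserved(self, maker):
        net = PPINetwork(maker())
        rw = rewire_degree_preserving(net, 10, seed=0)
        assert degree_seq(rw) == degree_seq(net)
        assert rw.n_edges == net.n_edges

    def test_four_cycle_stays_two_regular(self):
        net = PPINetwork(nx.cycle_graph(4))
        rw = rewire_degree_preserving(net, 10, seed=3)
        assert degree_seq(rw) == [2, 2, 2, 2]

    def test_overlap_drops_on_dd_network(self):
        """10 swaps/edge randomizes most edges of a 500-node grown network."""
        from netphylo.simulate import GeneratorConfig, generate_dataset

        ds = generate_dataset(GeneratorConfig(n_final=500, seed=2))
        rw = rewire_degree_preserving(ds.net, 10, seed=4)
        assert edge_overlap(ds.net, rw) < 0.30

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            rewire_degree_preserving(PPINetwork(nx.cycle_graph(5)), 0)


class TestHubGroupDistance:
    def _toy(self):
        # hub h with partners a(TG1), b(TG2), c(TG2); b-c also interact
        net = PPINetwork.from_edges([("h", "a"), ("h", "b"), ("h", "c"), ("b", "c")])
        groups = {"h": 1, "a": 1, "b": 2, "c": 2}
        fd = lambda x, y: 1.0 if "a" in (x, y) else 5.0
        return net, groups, fd

    def test_cross_group_pairs_only(self):
        net, groups, fd = self._toy()
        res = hub_group_distance(net, groups, fd, hub_min_degree=3)
        # qualifying pairs: (a,b), (a,c); (b,c) same TG excluded
        assert res.hub_ids == ["h"]
        assert res.group_distances[0] == pytest.approx(1.0)

    def test_exclude_interacting_pairs(self):
        net = PPINetwork.from_edges([("h", "a"), ("h", "b"), ("a", "b"), ("h", "c")])
        groups = {"h": 1, "a": 1, "b": 2, "c": 3}
        seen = []
        fd = lambda x, y: seen.append((x, y)) or 2.0
        hub_group_distance(net, groups, fd, hub_min_degree=3,
                           exclude_interacting=True)
        assert all(set(p) != {"a", "b"} for p in seen)

    def test_single_group_hub_skipped(self):
        net = PPINetwork.from_edges([("h", "a"), ("h", "b")])
        groups = {"h": 1, "a": 2, "b": 2}
        res = hub_group_distance(net, groups, lambda x, y: 1.0, hub_min_degree=2)
        assert res.hub_ids == [] and res.n_hubs_skipped == 1

    def test_duplication_cluster_exclusion(self):
        import pandas as pd

        from netphylo.temporal import build_duplication_clusters

        net = PPINetwork.from_edges([("h", "a"), ("h", "b"), ("h", "c")])
        groups = {"h": 1, "a": 1, "b": 2, "c": 3}
        hits = pd.DataFrame([("b", "c", "human", 1e-40)],
                            columns=["query", "subject", "species", "evalue"])
        dup = build_duplication_clusters(hits, 1e-25, genes=set(groups))
        seen = []
        fd = lambda x, y: seen.append((x, y)) or 2.0
        res = hub_group_distance(net, groups, fd, hub_min_degree=2,
                                 dup_clusters=dup)
        # b and c are in a 2-gene cluster -> dropped; only partner a remains
        assert res.hub_ids == [] and seen == []

    def test_matches_naive_double_loop_oracle(self, small_ds, default_funcspace):
        """Per-hub values equal an independent plain-python enumeration."""
        from conftest import random_grouped_graph

        net, groups = random_grouped_graph(120, 0.08, seed=17)
        rng = np.random.default_rng(0)
        vals = {}
        def fd(a, b):
            key = (a, b) if a < b else (b, a)
            if key not in vals:
                vals[key] = float(rng.random())
            return vals[key]
        res = hub_group_distance(net, groups, fd, hub_min_degree=8)
        got = dict(zip(res.hub_ids, res.group_distances))
        for node in net.graph.nodes:
            if net.graph.degree[node] < 8:
                continue
            pair_vals = [fd(a, b)
                         for a, b in itertools.combinations(sorted(net.graph.neighbors(node)), 2)
                         if groups[a] != groups[b]]
            if pair_vals:
                assert got[node] == pytest.approx(np.mean(pair_vals))


class TestHubNull:
    def test_rewired_draw_is_calibrated(self):
        """Using one rewired network as 'empirical' gives unremarkable p."""
        from netphylo.simulate import GeneratorConfig, generate_dataset

        ds = generate_dataset(GeneratorConfig(n_final=300, seed=5))
        rng = np.random.default_rng(1)
        n = 40
        genes = sorted(ds.net.graph.nodes)
        gidx = {g: i for i, g in enumerate(genes)}
        D = rng.random((len(genes), len(genes)))
        D = (D + D.T) / 2
        fd = lambda a, b: float(D[gidx[a], gidx[b]])
        ps = []
        for seed in range(4):
            fake_emp = rewire_degree_preserving(ds.net, 5, seed=100 + seed)
            res = hub_null_comparison(fake_emp, ds.groups, fd, hub_min_degree=10,
                                      reps=3, seed=seed)
            ps.append(res["p"])
        assert np.median(ps) > 0.1


class TestDistance2:
    def test_same_distribution_small_z(self):
        rng = np.random.default_rng(2)
        zs = [distance2_baseline(rng.normal(size=200), rng.normal(size=500))["Z"]
              for _ in range(20)]
        assert abs(np.mean(zs)) < 0.5

    def test_shift_direction_and_growth(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=400)
        z1 = distance2_baseline(base - 0.2, rng.normal(size=400))["Z"]
        z2 = distance2_baseline(base - 0.8, rng.normal(size=400))["Z"]
        assert z2 < z1 < 0

    def test_hand_computation_n5(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        # mean diff = -1; se = sqrt(2.5/5 + 2.5/5) = 1
        res = distance2_baseline(a, b)
        assert res["Z"] == pytest.approx(-1.0)

    def test_jackknife_se_exceeds_naive_for_shared_genes(self):
        """Pairs sharing genes are correlated; the jackknife SE sees that."""
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        effect = {g: rng.normal() for g in genes}
        pairs_a = [(a, b) for a, b in itertools.combinations(genes[:15], 2)]
        pairs_b = [(a, b) for a, b in itertools.combinations(genes[15:], 2)]
        va = np.array([effect[a] + effect[b] + 0.1 * rng.normal() for a, b in pairs_a])
        vb = np.array([effect[a] + effect[b] + 0.1 * rng.normal() for a, b in pairs_b])
        naive = distance2_baseline(va, vb)
        jack = distance2_baseline(va, vb, pairs_a, pairs_b)
        assert jack["se"] > naive["se"]


class TestControlledCorrelation:
    def test_unconfounded_property_keeps_global(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(600)]
        groups = {g: (i % 6) + 1 for i, g in enumerate(genes)}
        prop = {g: -groups[g] + rng.normal(scale=1.0) for g in genes}
        cats = {f"c{j}": set(rng.choice(genes, size=80, replace=False))
                for j in range(10)}
        res = controlled_correlation(prop, groups, cats)
        assert res["df"] == len(res["per_category_rho"]) - 1
        assert abs(res["controlled_rho"] - res["global_rho"]) < 0.15

    def test_confounded_property_shrinks_toward_zero(self):
        """Category-driven property with age-confounded categories: the
        within-category correlation vanishes while the global stays negative."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(600)]
        groups = {g: (i % 6) + 1 for i, g in enumerate(genes)}
        # categories span two adjacent groups; property is a category constant
        cats = {f"c{j}": {g for g in genes if groups[g] in (j + 1, j + 2)}
                for j in range(5)}
        prop = {g: -(groups[g] // 2) * 1.0 + rng.normal(scale=0.1) for g in genes}
        res = controlled_correlation(prop, groups, cats)
        assert res["global_rho"] < -0.9
        # within categories the property barely tracks age: strong shrinkage
        assert abs(res["controlled_rho"]) < 0.6 * abs(res["global_rho"])
        assert res["t"] > 0  # controlled coefficient sits above the global one

    def test_too_few_categories_errors(self):
        with pytest.raises(ValueError):
            controlled_correlation({"a": 1.0}, {"a": 1}, {})


class TestEnrichment:
    def test_toy_hypergeometric_matches_tail_sum(self):
        """Background 20 genes, 5 with the term; group of 5 with 4 carriers."""
        from math import comb

        genes = {f"g{i}": ({"t"} if i < 5 else set()) for i in range(20)}
        groups = {f"g{i}": (1 if i in (0, 1, 2, 3, 5) else 2) for i in range(20)}
        res = group_term_enrichment(groups, genes)
        row = [r for r in res["rows"] if r[0] == 1 and r[1] == "t"][0]
        expected = sum(comb(5, k) * comb(15, 5 - k) for k in (4, 5)) / comb(20, 5)
        assert row[4] == pytest.approx(expected, rel=1e-12)

    def test_all_share_all_terms_no_enrichment(self):
        genes = {f"g{i}": {"t1", "t2"} for i in range(20)}
        groups = {f"g{i}": (i % 2) + 1 for i in range(20)}
        res = group_term_enrichment(groups, genes)
        assert all(r[4] == pytest.approx(1.0) for r in res["rows"])
        assert not any(res["significant"].values())

    def test_random_subset_mostly_unenriched(self):
        rng = np.random.default_rng(6)
        genes = {f"g{i}": {t for t in "abcde" if rng.random() < 0.3}
                 for i in range(200)}
        groups = {g: int(rng.integers(1, 3)) for g in genes}
        res = group_term_enrichment(groups, genes)
        assert sum(len(s) for s in res["significant"].values()) <= 1

    def test_bh_q_monotone_and_above_p(self):
        rng = np.random.default_rng(7)
        genes = {f"g{i}": {t for t in "abcdefgh" if rng.random() < 0.3}
                 for i in range(100)}
        groups = {g: int(rng.integers(1, 4)) for g in genes}
        res = group_term_enrichment(groups, genes)
        for gi in set(groups.values()):
            fam = sorted((r for r in res["rows"] if r[0] == gi), key=lambda r: r[4])
            assert all(r[5] >= r[4] - 1e-12 for r in fam)  # q >= p
            qs = [r[5] for r in fam]
            assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))  # q monotone in p


class TestZscoreEnrichment:
    def test_whole_population_category_zero(self):
        prop = {f"g{i}": float(i) for i in range(50)}
        rows = property_zscore_enrichment(prop, {"all": set(prop)})
        assert rows[0]["z"] == pytest.approx(0.0, abs=1e-12)

    def test_shifted_category_z_near_two(self):
        rng = np.random.default_rng(9)
        prop = {f"g{i}": rng.normal() for i in range(2000)}
        cat = set(list(prop)[:100])
        sd = np.std(list(prop.values()), ddof=1)
        shift = 2 * sd / np.sqrt(100)
        for g in cat:
            prop[g] += shift
        rows = property_zscore_enrichment(prop, {"c": cat})
        assert rows[0]["z"] == pytest.approx(2.0, abs=0.7)
        assert rows[0]["z"] > 0

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            property_zscore_enrichment({"a": 1.0, "b": 1.0}, {"c": {"a"}})
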