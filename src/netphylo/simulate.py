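"""Synthetic study-input generator with planted, tunable structure.

Grows an interaction network by duplication-divergence (duplicate a random
node, keep each parent edge with probability ``p_edge_retain``, gain a few
random edges), which yields heavy-tailed degrees and an age-degree
correlation.  Birth times cut into six temporal groups define the planted
gene ages; annotations drift with group age at rate ``age_gradient``; hub
neighborhoods share terms with probability ``hub_coherence``; omega rises
linearly with group index.  Setting ``age_gradient = hub_coherence =
omega_slope = 0`` ablates all structure, giving an exact null for
calibration.  Every emitted file parses back through the package readers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (N_GROUPS, PPINetwork, TemporalGroupScheme, default_scheme,
                 write_edge_list, write_hit_table, write_omega_table)


@dataclass
class GeneratorConfig:
    n_final: int = 1000
    p_edge_retain: float = 0.45
    p_new_edge: float = 0.1
    p_parent_link: float = 0.25
    triangle_rate: float = 2.0
    group_boundaries: tuple = (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6)
    ages_mya: tuple = (990.0, 450.0, 360.0, 310.0, 90.0, 50.0)
    n_terms: int = 30
    n_shared_terms: int = 2
    age_gradient: float = 0.5
    hub_coherence: float = 0.8
    hub_tilt: float = 0.45
    hub_fraction: float = 0.02
    omega_slope: float = 0.03
    omega_base: float = 0.03
    p_dup_detect: float = 0.15
    evalue_threshold: float = 1e-20
    dup_threshold: float = 1e-25
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_edge_retain, self.p_parent_link, self.hub_coherence,
                  self.hub_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_final < 20:
            raise ValueError("n_final must be >= 20")
        if any(a <= b for a, b in zip(self.ages_mya, self.ages_mya[1:])):
            raise ValueError("ages must strictly decrease")
        if self.age_gradient > 0 and self.n_terms < N_GROUPS:
            raise ValueError("need n_terms >= 6 when age_gradient > 0")


@dataclass
class SyntheticTruth:
    birth_time: dict[str, int]
    parent: dict[str, str | None]
    dup_edges: list[tuple[str, str]]
    planted_hubs: list[str] = field(default_factory=list)
    term_home_group: dict[str, int] = field(default_factory=dict)


def _derived_rng(seed: int, label: str) -> np.random.Generator:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big"))


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def simulate_network(config: GeneratorConfig) -> tuple[PPINetwork, SyntheticTruth]:
    """Duplication-divergence growth from a small seed clique.

    Records birth order and parentage; keeps the largest connected
    component (dropped-node count is small at the defaults).
    """
    rng = _derived_rng(config.seed, "network")
    g = nx.Graph()
    seed_n = 4
    for i in range(seed_n):
        g.add_node(_gene_name(i))
    for i in range(seed_n):
        for j in range(i + 1, seed_n):
            g.add_edge(_gene_name(i), _gene_name(j))
    birth = {_gene_name(i): i for i in range(seed_n)}
    parent: dict[str, str | None] = {_gene_name(i): None for i in range(seed_n)}
    dup_edges: list[tuple[str, str]] = []
    for i in range(seed_n, config.n_final):
        child = _gene_name(i)
        template = list(g.nodes)[rng.integers(g.number_of_nodes())]
        g.add_node(child)
        birth[child] = i
        parent[child] = template
        for nb in list(g.neighbors(template)):
            if rng.random() < config.p_edge_retain:
                g.add_edge(child, nb)
        if rng.random() < config.p_parent_link:
            g.add_edge(child, template)  # closes triangles over retained edges
        mean_deg = 2.0 * g.number_of_edges() / g.number_of_nodes()
        extra = rng.poisson(config.p_new_edge * mean_deg)
        if g.degree[child] == 0:
            g.add_edge(child, template)  # keep duplicates attached
        others = [n for n in g.nodes if n != child]
        for _ in range(extra):
            tgt = others[rng.integers(len(others))]
            g.add_edge(child, tgt)
        if rng.random() < config.p_dup_detect:
            dup_edges.append((template, child))
        # age-weighted triadic closure: older proteins consolidate modules
        if config.triangle_rate > 0:
            names = list(g.nodes)
            w = np.array([(i + 1) - birth[v] for v in names], dtype=float)
            w /= w.sum()
            for _ in range(rng.poisson(config.triangle_rate)):
                u = names[rng.choice(len(names), p=w)]
                nbrs = list(g.neighbors(u))
                if len(nbrs) < 2:
                    continue
                a, b = rng.choice(len(nbrs), size=2, replace=False)
                g.add_edge(nbrs[a], nbrs[b])
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise ValueError("generator parameters yielded an empty graph")
    giant = max(nx.connected_components(g), key=len)
    dropped = g.number_of_nodes() - len(giant)
    g = g.subgraph(giant).copy()
    birth = {n: birth[n] for n in g.nodes}
    parent = {n: parent[n] for n in g.nodes}
    dup_edges = [(a, b) for a, b in dup_edges if a in birth and b in birth]
    truth = SyntheticTruth(birth, parent, dup_edges)
    net = PPINetwork(g, {"self_loops": 0, "duplicates": 0, "dropped_nodes": dropped})
    return net, truth


def assign_groups_and_ages(truth: SyntheticTruth,
                           config: GeneratorConfig) -> tuple[dict[str, int], np.ndarray]:
    """Quantile-cut birth times into six groups; oldest births = TG1."""
    genes = sorted(truth.birth_time, key=truth.birth_time.get)
    n = len(genes)
    if len(set(truth.birth_time.values())) < N_GROUPS:
        raise ValueError("fewer distinct birth times than groups")
    cuts = [int(round(q * n)) for q in config.group_boundaries]
    groups: dict[str, int] = {}
    prev = 0
    for gi, c in enumerate(list(cuts) + [n], start=1):
        for g in genes[prev:c]:
            groups[g] = gi
        prev = c
    return groups, np.asarray(config.ages_mya)


def _term_name(j: int) -> str:
    return f"TOY:{j + 1:07d}"


def simulate_annotations(net: PPINetwork, groups: dict[str, int],
                         truth: SyntheticTruth, config: GeneratorConfig
                         ) -> tuple[dict[str, set[str]], str, list[str]]:
    """Plant age-graded and hub-coherent annotations over a toy ontology.

    Returns (gene -> term set, OBO text, planted hub list).  Group terms
    are carried with probability decaying exponentially in the group-to-
    home-group separation at rate ``age_gradient``.  Each planted hub (top
    ``hub_fraction`` by degree) imposes functional coherence on its
    neighborhood through a shared annotation tilt: the hub draws a random
    +/-``hub_tilt`` offset per term, and each partner re-draws its profile
    from its OWN group probabilities shifted by that common offset with
    probability ``hub_coherence``.  Partners of one hub therefore correlate
    (smaller pairwise distance) while group-mean profiles stay unbiased, so
    the age gradient survives.  Rewiring destroys the co-location of
    same-tilt genes, which is the signal the group-distance test detects.
    """
    rng = _derived_rng(config.seed, "annotations")
    group_terms = [_term_name(j) for j in range(config.n_terms)]
    shared_terms = [_term_name(config.n_terms + j) for j in range(config.n_shared_terms)]
    # terms anchor at the oldest or newest group so the six group profiles
    # form a low-rank monotone gradient that survives covariance whitening
    home = {t: (1 if j % 2 == 0 else N_GROUPS) for j, t in enumerate(group_terms)}
    truth.term_home_group = dict(home)

    base_p = 0.6
    floor_p = 0.05

    def profile(gi: int) -> dict[str, float]:
        if config.age_gradient > 0:
            return {t: floor_p + (base_p - floor_p)
                    * np.exp(-config.age_gradient * abs(gi - home[t]))
                    for t in group_terms}
        return {t: 0.3 for t in group_terms}  # flat: no group signal (pure null)

    profiles = {gi: profile(gi) for gi in range(1, N_GROUPS + 1)}

    def draw(gi: int) -> set[str]:
        p = profiles[gi]
        return {t for t in group_terms if rng.random() < p[t]}

    ann: dict[str, set[str]] = {}
    for g in sorted(net.graph.nodes):
        ann[g] = set(shared_terms) | draw(groups[g])

    hubs: list[str] = []
    if config.hub_fraction > 0:
        by_deg = sorted(net.graph.nodes, key=lambda n: (-net.graph.degree[n], n))
        n_hubs = max(1, int(round(config.hub_fraction * net.n_nodes)))
        hubs = by_deg[:n_hubs]
    if config.hub_coherence > 0 and config.hub_tilt > 0:
        tilts = {h: np.where(rng.random(len(group_terms)) < 0.5, 1.0, -1.0)
                 * config.hub_tilt for h in hubs}
        member: dict[str, list] = {}
        for h in hubs:
            member.setdefault(h, []).append(tilts[h])  # hub shares its unit's function
            for p_ in net.graph.neighbors(h):
                if rng.random() < config.hub_coherence:
                    member.setdefault(p_, []).append(tilts[h])
        for p_, tl in member.items():
            shift = np.mean(tl, axis=0)
            prof = profiles[groups[p_]]
            ann[p_] = set(shared_terms) | {
                t for j, t in enumerate(group_terms)
                if rng.random() < min(0.98, max(0.02, prof[t] + shift[j]))}
    truth.planted_hubs = hubs

    obo = _toy_obo(group_terms + shared_terms)
    return ann, obo, hubs


def _toy_obo(terms: list[str]) -> str:
    """Two-level ontology: one biological_process root, all terms direct children."""
    lines = ["format-version: 1.2", "ontology: toy", "",
             "[Term]", "id: TOY:0000000", "name: biological_process",
             "namespace: biological_process", ""]
    for t in terms:
        lines += ["[Term]", f"id: {t}", f"name: term {t.split(':')[1]}",
                  "namespace: biological_process", "is_a: TOY:0000000 ! root", ""]
    return "\n".join(lines)


def annotations_to_gaf(ann: dict[str, set[str]]) -> str:
    """Serialize gene -> term assignments as GAF 2.2 rows."""
    lines = ["!gaf-version: 2.2"]
    for g in sorted(ann):
        for t in sorted(ann[g]):
            lines.append("\t".join([
                "TOY", g, g, "", t, "TOY:ref", "IEA", "", "P",
                g, "", "protein", "taxon:9606", "20120424", "TOY", "", ""]))
    return "\n".join(lines) + "\n"


def simulate_hit_tables(truth: SyntheticTruth, groups: dict[str, int],
                        scheme: TemporalGroupScheme, config: GeneratorConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit homology hit tables consistent with the planted groups.

    Each gene in TG g < 6 gets one qualifying hit in a species of clade g
    (and a non-qualifying decoy in an older clade); TG6 genes get only
    non-qualifying hits.  The self-hit table holds the detectable
    parent-child duplication pairs below the duplication threshold.
    """
    rng = _derived_rng(config.seed, "hits")
    clade_species = {gi: sorted(sp) for gi, sp in scheme.clades}
    rows = []
    weak = config.evalue_threshold * 1e4  # decoy e-value above threshold
    strong_max = config.evalue_threshold
    for g in sorted(groups):
        gi = groups[g]
        if gi < N_GROUPS:
            sp = clade_species[gi][int(rng.integers(len(clade_species[gi])))]
            ev = strong_max * 10 ** (-float(rng.uniform(1, 10)))
            rows.append((g, f"{sp}|{g}h", sp, ev))
        if gi > 1:
            older = clade_species[int(rng.integers(1, gi)) if gi <= 5 else int(rng.integers(1, 6))]
            sp = older[int(rng.integers(len(older)))]
            rows.append((g, f"{sp}|{g}w", sp, weak * 10 ** float(rng.uniform(0, 3))))
    species_hits = pd.DataFrame(rows, columns=["query", "subject", "species", "evalue"])
    self_rows = [(a, b, "human", config.dup_threshold * 10 ** (-float(rng.uniform(1, 10))))
                 for a, b in truth.dup_edges]
    self_hits = pd.DataFrame(self_rows, columns=["query", "subject", "species", "evalue"])
    return species_hits, self_hits


def simulate_omega(groups: dict[str, int], config: GeneratorConfig) -> dict[str, float]:
    """Gamma-distributed omega with mean rising linearly in group index."""
    if config.omega_slope < 0:
        raise ValueError("omega_slope must be >= 0")
    rng = _derived_rng(config.seed, "omega")
    out = {}
    shape = 2.0
    for g in sorted(groups):
        mean = config.omega_base + config.omega_slope * (groups[g] - 1)
        out[g] = float(rng.gamma(shape, mean / shape))
    return out


@dataclass
class SyntheticDataset:
    """One complete in-memory synthetic study."""

    config: GeneratorConfig
    net: PPINetwork
    truth: SyntheticTruth
    groups: dict[str, int]
    ages_mya: np.ndarray
    annotations: dict[str, set[str]]
    obo_text: str
    scheme: TemporalGroupScheme
    species_hits: pd.DataFrame
    self_hits: pd.DataFrame
    omega: dict[str, float]


def generate_dataset(config: GeneratorConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate the full bundle of synthetic study inputs."""
    if config is None:
        config = GeneratorConfig()
    if seed is not None:
        config = GeneratorConfig(**{**asdict(config), "seed": seed})
    net, truth = simulate_network(config)
    groups, ages = assign_groups_and_ages(truth, config)
    ann, obo_text, _ = simulate_annotations(net, groups, truth, config)
    scheme = default_scheme(config.evalue_threshold)
    scheme = TemporalGroupScheme(scheme.clades,
                                 {i + 1: a for i, a in enumerate(config.ages_mya)},
                                 config.evalue_threshold)
    sp_hits, self_hits = simulate_hit_tables(truth, groups, scheme, config)
    omega = simulate_omega(groups, config)
    return SyntheticDataset(config, net, truth, groups, ages, ann, obo_text,
                            scheme, sp_hits, self_hits, omega)


def emit(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the dataset as the plain-text files the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: str(outdir / v) for k, v in {
        "net": "net.tsv", "hits_species": "hits_species.tsv",
        "hits_self": "hits_self.tsv", "gaf": "ann.gaf", "obo": "toy.obo",
        "omega": "omega.tsv", "truth": "truth.json", "groups": "groups.tsv"}.items()}
    write_edge_list(ds.net, paths["net"])
    write_hit_table(ds.species_hits, paths["hits_species"])
    write_hit_table(ds.self_hits, paths["hits_self"])
    Path(paths["gaf"]).write_text(annotations_to_gaf(ds.annotations))
    Path(paths["obo"]).write_text(ds.obo_text)
    write_omega_table(ds.omega, paths["omega"])
    with open(paths["groups"], "w") as fh:
        for g in sorted(ds.groups):
            fh.write(f"{g}\t{ds.groups[g]}\n")
    truth = {"birth_time": ds.truth.birth_time,
             "parent": ds.truth.parent,
             "dup_edges": ds.truth.dup_edges,
             "planted_hubs": ds.truth.planted_hubs,
             "term_home_group": ds.truth.term_home_group,
             "config": asdict(ds.config)}
    Path(paths["truth"]).write_text(json.dumps(truth, indent=1))
    return paths
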