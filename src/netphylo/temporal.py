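"""Temporal-group (gene age) assignment and duplication clustering.

Phylostratigraphy by oldest-clade homology: a gene belongs to the oldest
temporal group whose clade contains at least one homology hit at or below
the e-value threshold; genes without any qualifying hit fall in the newest
group (lineage-specific).  Duplication clusters are single-linkage closures
of above-threshold human-vs-human similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import N_GROUPS, TemporalGroupScheme

logger = logging.getLogger("netphylo")


def assign_temporal_groups(hits: pd.DataFrame, scheme: TemporalGroupScheme,
                           genes: set[str] | None = None) -> dict[str, int]:
    """Assign each gene the OLDEST clade with a qualifying hit.

    ``hits`` needs columns query/species/evalue.  ``genes`` extends the
    universe beyond the queries present in the table; any gene with no hit
    at ``evalue <= scheme.evalue_threshold`` in any clade gets group 6.
    Hits in species absent from the scheme are ignored (logged).
    """
    sp2g = scheme.species_to_group()
    universe: set[str] = set(genes) if genes is not None else set()
    universe.update(hits["query"])
    assigned = {g: N_GROUPS for g in universe}
    unknown_species: set[str] = set()
    qual = hits[hits["evalue"] <= scheme.evalue_threshold]
    for q, sp in zip(qual["query"], qual["species"]):
        gi = sp2g.get(sp)
        if gi is None:
            unknown_species.add(sp)
            continue
        if gi < assigned[q]:
            assigned[q] = gi
    if unknown_species:
        logger.info("ignored hits in %d species absent from scheme: %s",
                    len(unknown_species), sorted(unknown_species)[:5])
    return assigned


@dataclass
class DuplicationClusters:
    """Single-linkage partition of genes by sequence similarity."""

    clusters: list[frozenset]
    threshold: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters are not disjoint")
            seen |= c
        self._membership = {g: i for i, c in enumerate(self.clusters) for g in c}

    def cluster_of(self, gene: str) -> frozenset | None:
        i = self._membership.get(gene)
        return None if i is None else self.clusters[i]

    def duplicated_genes(self) -> set[str]:
        """Genes in clusters of size >= 2 (evidence of detectable duplication)."""
        return {g for c in self.clusters if len(c) >= 2 for g in c}

    def same_cluster(self, a: str, b: str) -> bool:
        ia, ib = self._membership.get(a), self._membership.get(b)
        return ia is not None and ia == ib


def build_duplication_clusters(self_hits: pd.DataFrame, threshold: float,
                               genes: set[str] | None = None) -> DuplicationClusters:
    """Connected components of the above-threshold similarity graph.

    A-A self hits are ignored; similarity is symmetrized.  Genes passed in
    ``genes`` but hit-less become singleton clusters.
    """
    g = nx.Graph()
    if genes:
        g.add_nodes_from(genes)
    g.add_nodes_from(self_hits["query"])
    g.add_nodes_from(self_hits["subject"])
    qual = self_hits[self_hits["evalue"] <= threshold]
    for a, b in zip(qual["query"], qual["subject"]):
        if a != b:
            g.add_edge(a, b)
    clusters = [frozenset(c) for c in nx.connected_components(g)]
    return DuplicationClusters(sorted(clusters, key=lambda c: sorted(c)[0]), threshold)


def omega_by_group(groups: dict[str, int], omega: dict[str, float]) -> dict:
    """Per-group mean omega plus a Kruskal-Wallis test across groups.

    Lower omega in older groups indicates stronger purifying selection.
    Returns per-group means/counts and the H statistic with its chi-square
    p-value.
    """
    samples: dict[int, list[float]] = {}
    for g, w in omega.items():
        gi = groups.get(g)
        if gi is not None:
            samples.setdefault(gi, []).append(w)
    if not samples:
        raise ValueError("no gene has both a group and an omega value")
    populated = {gi: v for gi, v in samples.items() if v}
    if len(populated) < 2:
        raise ValueError("need omega values in >= 2 groups")
    means = {gi: float(np.mean(v)) for gi, v in populated.items()}
    counts = {gi: len(v) for gi, v in populated.items()}
    arrays = [populated[gi] for gi in sorted(populated)]
    try:
        H, p = stats.kruskal(*arrays)
    except ValueError:  # all values identical
        H, p = 0.0, 1.0
    return {"means": means, "counts": counts, "H": float(H), "p": float(p),
            "df": len(populated) - 1}
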