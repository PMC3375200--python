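"""Domain types and file readers/writers.

Everything downstream (temporal groups, topology, function space, hub
analysis) consumes the types defined here: a cleaned simple interaction
graph, homology hit tables, annotation dictionaries, symmetric group-pair
summary matrices and Newick trees.  All readers reject malformed input with
the offending line number rather than silently coercing it, and every
cleaning step (self-loop removal, duplicate collapse) is counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger("netphylo")

N_GROUPS = 6
GROUP_LABELS = tuple(f"TG{i}" for i in range(1, N_GROUPS + 1))


@dataclass
class GeneRecord:
    """One gene: identifier, temporal group, selective constraint, membership."""

    gene_id: str
    temporal_group: int | None = None
    omega: float | None = None
    in_network: bool = False

    def __post_init__(self) -> None:
        if self.temporal_group is not None and not 1 <= self.temporal_group <= N_GROUPS:
            raise ValueError(f"temporal_group must be 1..{N_GROUPS}, got {self.temporal_group}")
        if self.omega is not None and self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")


class PPINetwork:
    """Undirected simple graph over gene identifiers.

    Wraps a :class:`networkx.Graph` and keeps the counts of self-loops and
    duplicate (including reversed-duplicate) edges removed at load time.
    """

    def __init__(self, graph: nx.Graph | None = None,
                 cleaning_log: dict[str, int] | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()
        self.cleaning_log = cleaning_log or {"self_loops": 0, "duplicates": 0}

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]],
                   nodes: Iterable[str] | None = None) -> "PPINetwork":
        g = nx.Graph()
        log = {"self_loops": 0, "duplicates": 0}
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v in pairs:
            if u == v:
                log["self_loops"] += 1
                continue
            if g.has_edge(u, v):
                log["duplicates"] += 1
                continue
            g.add_edge(u, v)
        return cls(g, log)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def copy(self) -> "PPINetwork":
        return PPINetwork(self.graph.copy(), dict(self.cleaning_log))


@dataclass
class TemporalGroupScheme:
    """Mapping from clades (species sets) to temporal group indices plus ages.

    ``clades`` lists (group index, species set) ordered oldest (1) to newest;
    the last group holds genes with no qualifying homolog in any listed clade.
    """

    clades: Sequence[tuple[int, frozenset]]
    ages_mya: Mapping[int, float]
    evalue_threshold: float = 1e-20

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.clades]
        if not idx:
            raise ValueError("scheme has no clades")
        if idx != sorted(idx) or any(i < 1 or i > N_GROUPS for i in idx):
            raise ValueError("clade group indices must be increasing and in 1..6")
        ages = [self.ages_mya[i] for i in sorted(self.ages_mya)]
        if not all(x > y for x, y in zip(ages, ages[1:])):
            raise ValueError("group ages must strictly decrease with group index")

    def species_to_group(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for gi, species in self.clades:
            for s in species:
                out[s] = gi
        return out


def default_scheme(evalue_threshold: float = 1e-20) -> TemporalGroupScheme:
    """Six-group phylostratigraphy scheme for the human gene complement."""
    clades = [
        (1, frozenset({"african_malaria_mosquito", "fruitfly", "nematode",
                       "schistosoma", "yellow_fever_mosquito"})),
        (2, frozenset({"medaka", "pufferfish", "trout", "zebrafish"})),
        (3, frozenset({"clawed_frog", "tropical_frog"})),
        (4, frozenset({"chicken"})),
        (5, frozenset({"cattle", "dog", "pig", "sheep"})),
    ]
    ages = {1: 990.0, 2: 450.0, 3: 360.0, 4: 310.0, 5: 90.0, 6: 50.0}
    return TemporalGroupScheme(clades, ages, evalue_threshold)


@dataclass
class GroupMatrix:
    """Symmetric 6x6 matrix of group-pair averages with pair counts.

    Cells with ``pair_counts == 0`` hold NaN (missing), never zero.
    """

    values: np.ndarray
    pair_counts: np.ndarray
    kind: str = "functional_distance"

    KINDS = ("functional_distance", "network_distance", "interaction_density")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts)
        if self.values.shape != (N_GROUPS, N_GROUPS):
            raise ValueError("GroupMatrix must be 6x6")
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("values must be symmetric")
        if not np.array_equal(self.pair_counts, self.pair_counts.T):
            raise ValueError("pair_counts must be symmetric")
        self.values = np.where(self.pair_counts == 0, np.nan, self.values)

    def upper_triangle(self, include_diagonal: bool = True):
        k = 0 if include_diagonal else 1
        iu = np.triu_indices(N_GROUPS, k=k)
        return self.values[iu], iu

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=GROUP_LABELS, columns=GROUP_LABELS)


# ---------------------------------------------------------------------------
# readers


def read_edge_list(path: str | Path, format: str = "tsv") -> PPINetwork:
    """Read an interaction edge list (2-column TSV or PSI-MI TAB 2.5).

    PSI-MI TAB rows use columns 1-2 (the interactor identifiers).  The
    returned graph is simple: self-loops and duplicate/reversed-duplicate
    edges are removed and counted in ``cleaning_log``.
    """
    path = Path(path)
    if format not in ("tsv", "psimitab"):
        raise ValueError(f"unknown edge list format {format!r}")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{ln}: expected >=2 non-empty columns")
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ValueError(f"{path}: no interaction rows")
    net = PPINetwork.from_edges(pairs)
    if any(net.cleaning_log.values()):
        logger.info("edge list cleaning: %s", net.cleaning_log)
    return net


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_obo(path: str | Path) -> nx.MultiDiGraph:
    """Parse an OBO ontology into a graph with edges child -> parent."""
    return obonet.read_obo(str(path))


GAF_COLS = {"db_object_id": 1, "qualifier": 3, "go_id": 4, "aspect": 8}
_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}


def read_annotations(gaf_path: str | Path, obo: nx.MultiDiGraph,
                     namespace: str = "biological_process") -> dict[str, set[str]]:
    """Read per-gene ontology term sets from a GAF 2.x file.

    NOT-qualified rows are excluded; rows citing terms absent from the
    ontology (or in the wrong namespace) are skipped with a logged count.
    Evidence codes are not filtered.
    """
    if namespace not in _ASPECT:
        raise ValueError(f"unknown namespace {namespace!r}")
    aspect = _ASPECT[namespace]
    out: dict[str, set[str]] = {}
    skipped_unknown = skipped_not = 0
    with open(gaf_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gaf_path}:{ln}: GAF row has {len(fields)} columns, need >=9")
            gene = fields[GAF_COLS["db_object_id"]]
            qual = fields[GAF_COLS["qualifier"]]
            term = fields[GAF_COLS["go_id"]]
            row_aspect = fields[GAF_COLS["aspect"]]
            if "NOT" in qual.split("|"):
                skipped_not += 1
                continue
            out.setdefault(gene, set())
            if row_aspect != aspect:
                continue
            if term not in obo.nodes:
                skipped_unknown += 1  # unknown or obsolete term
                continue
            if obo.nodes[term].get("namespace", namespace) != namespace:
                out.setdefault(gene, set())
                continue
            out.setdefault(gene, set()).add(term)
    if skipped_unknown or skipped_not:
        logger.info("GAF: skipped %d unknown/obsolete-term rows, %d NOT rows",
                    skipped_unknown, skipped_not)
    if not any(out.values()):
        raise ValueError(f"{gaf_path}: no usable annotations in namespace {namespace}")
    return out


def read_omega_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of gene -> omega (Ka/Ks); omega must be >= 0."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            if fields[1].lower() in ("na", "nan", ""):
                continue
            try:
                w = float(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric omega {fields[1]!r}") from None
            if w < 0:
                raise ValueError(f"{path}:{ln}: negative omega {w}")
            out[fields[0]] = w
    return out


def write_omega_table(omega: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(omega):
            fh.write(f"{g}\t{omega[g]:.6g}\n")


def read_hit_table(path: str | Path, query_col: int = 0, subject_col: int = 1,
                   evalue_col: int = 10, species_col: int | None = None) -> pd.DataFrame:
    """Read a BLAST-tabular-style homology hit table.

    Default column indices follow outfmt 6 (qseqid, sseqid, ..., evalue at
    index 10).  When ``species_col`` is None the subject species is taken
    as the prefix of the subject id before the first ``|``.  Returns a
    DataFrame with columns ``query, subject, species, evalue``.
    """
    rows = []
    max_col = max(query_col, subject_col, evalue_col,
                  species_col if species_col is not None else 0)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= max_col:
                raise ValueError(f"{path}:{ln}: expected >{max_col} columns, got {len(fields)}")
            try:
                ev = float(fields[evalue_col])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric e-value {fields[evalue_col]!r}") from None
            if ev < 0:
                raise ValueError(f"{path}:{ln}: negative e-value {ev}")
            subject = fields[subject_col]
            species = (fields[species_col] if species_col is not None
                       else subject.split("|", 1)[0])
            rows.append((fields[query_col], subject, species, ev))
    return pd.DataFrame(rows, columns=["query", "subject", "species", "evalue"])


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write hits as 4-column TSV (query, subject, species, evalue)."""
    hits.to_csv(path, sep="\t", header=False, index=False,
                columns=["query", "subject", "species", "evalue"])


def write_group_matrix(mat: GroupMatrix, path: str | Path) -> None:
    """Write a GroupMatrix as labelled TSV; pair counts in a sibling block."""
    with open(path, "w") as fh:
        fh.write(f"# kind={mat.kind}\n")
        fh.write("\t" + "\t".join(GROUP_LABELS) + "\n")
        for i, lab in enumerate(GROUP_LABELS):
            vals = "\t".join("NA" if math.isnan(mat.values[i, j]) else f"{mat.values[i, j]:.12g}"
                             for j in range(N_GROUPS))
            fh.write(f"{lab}\t{vals}\n")
        fh.write("# pair_counts\n")
        for i, lab in enumerate(GROUP_LABELS):
            fh.write(lab + "\t" + "\t".join(str(int(c)) for c in mat.pair_counts[i]) + "\n")


def read_group_matrix(path: str | Path) -> GroupMatrix:
    values = np.full((N_GROUPS, N_GROUPS), np.nan)
    counts = np.zeros((N_GROUPS, N_GROUPS), dtype=int)
    kind = "functional_distance"
    section = "values"
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# kind="):
                kind = line.split("=", 1)[1]
                continue
            if line.startswith("# pair_counts"):
                section = "counts"
                continue
            fields = line.split("\t")
            if fields[0] == "":
                continue  # header row
            if fields[0] not in GROUP_LABELS:
                raise ValueError(f"{path}:{ln}: unexpected row label {fields[0]!r}")
            i = GROUP_LABELS.index(fields[0])
            for j, tok in enumerate(fields[1:N_GROUPS + 1]):
                if section == "values":
                    values[i, j] = np.nan if tok == "NA" else float(tok)
                else:
                    counts[i, j] = int(tok)
    return GroupMatrix(values, counts, kind)


# ---------------------------------------------------------------------------
# Newick


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick string with branch lengths.

    Branch lengths are differences of merge heights (leaf height 0), so the
    root-to-leaf path length equals the final merge height.
    """
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    body = rec(tree, tree.dist)
    # root has no branch length
    return body.rsplit(":", 1)[0] + ";"


def write_newick(Z: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    Path(path).write_text(linkage_to_newick(Z, labels) + "\n")
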