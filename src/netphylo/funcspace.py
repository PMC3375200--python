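"""Functional distances between genes and temporal groups.

Genes are embedded as binary vectors over the sub-root ontology terms (the
direct children of the biological_process / molecular_function root), with
annotations propagated up the is_a graph.  The primary metric is the
Mahalanobis distance under the term covariance estimated over the
annotation universe; a Resnik information-content distance is the
alternative backend.  Group-level summaries: the 6x6 mean-distance matrix,
its dendrogram with a gene-label permutation test, the distance-vs-age
correlation and the functional-distance-by-network-distance profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import N_GROUPS, GROUP_LABELS, GroupMatrix, linkage_to_newick


def namespace_root(obo: nx.MultiDiGraph, namespace: str) -> str:
    """The root term of a namespace: its name equals the namespace string."""
    for t, data in obo.nodes(data=True):
        if data.get("name") == namespace:
            return t
    raise ValueError(f"no root named {namespace!r} in ontology")


def sub_root_terms(obo: nx.MultiDiGraph, namespace: str) -> list[str]:
    """Direct is_a children of the namespace root, sorted for stable order."""
    root = namespace_root(obo, namespace)
    kids = {u for u, v, k in obo.in_edges(root, keys=True) if k == "is_a"}
    if not kids:
        raise ValueError(f"namespace {namespace!r} has no sub-root terms")
    return sorted(kids)


def term_ancestors(obo: nx.MultiDiGraph, term: str) -> set[str]:
    """Ancestors-or-self of a term along is_a edges (child -> parent)."""
    seen = {term}
    stack = [term]
    while stack:
        t = stack.pop()
        for _, parent, key in obo.out_edges(t, keys=True):
            if key == "is_a" and parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen


@dataclass
class AnnotationMatrix:
    """Genes x sub-root-terms binary matrix with its regularized covariance."""

    genes: list[str]
    terms: list[str]
    X: np.ndarray
    cov: np.ndarray
    cov_inverse: np.ndarray
    regularization: float
    zero_genes: list[str] = field(default_factory=list)

    def row(self, gene: str) -> np.ndarray:
        return self.X[self.genes.index(gene)]

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def build_annotation_matrix(annotations: dict[str, set[str]], obo: nx.MultiDiGraph,
                            namespace: str = "biological_process",
                            gene_order: list[str] | None = None,
                            ridge: float = 1e-6) -> AnnotationMatrix:
    """Project gene annotations onto the sub-root term basis.

    X[g, t] = 1 iff sub-root term t is an ancestor-or-self of any annotation
    of g.  The covariance is estimated over all genes supplied (the
    annotation universe); when singular it is ridge-regularized before
    (pseudo)inversion.  Genes whose annotations reach no sub-root term get
    an all-zero row and are listed in ``zero_genes``.
    """
    terms = sub_root_terms(obo, namespace)
    t_index = {t: j for j, t in enumerate(terms)}
    genes = list(gene_order) if gene_order is not None else sorted(annotations)
    X = np.zeros((len(genes), len(terms)), dtype=np.int8)

    @lru_cache(maxsize=None)
    def subroots_of(term: str) -> frozenset:
        return frozenset(t for t in term_ancestors(obo, term) if t in t_index)

    zero = []
    for i, g in enumerate(genes):
        hit = False
        for t in annotations.get(g, ()):
            if t not in obo.nodes:
                continue
            for sr in subroots_of(t):
                X[i, t_index[sr]] = 1
                hit = True
        if not hit:
            zero.append(g)
    Xf = X.astype(float)
    cov = np.cov(Xf, rowvar=False) if len(genes) > 1 else np.eye(len(terms))
    cov = np.atleast_2d(cov)
    eps = 0.0
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        eps = ridge
        cov = cov + eps * np.eye(cov.shape[0])
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = np.linalg.pinv(cov)
    return AnnotationMatrix(genes, terms, X, cov, cov_inv, eps, zero)


def mahalanobis_distance(x: np.ndarray, y: np.ndarray, cov_inverse: np.ndarray) -> float:
    """sqrt((x-y)^T V^-1 (x-y)); the covariance-whitened vector distance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dimension mismatch")
    d = x - y
    q = float(d @ cov_inverse @ d)
    return float(np.sqrt(max(q, 0.0)))


def pairwise_mahalanobis(X: np.ndarray, cov_inverse: np.ndarray,
                         block: int = 512) -> np.ndarray:
    """Full n x n Mahalanobis distance matrix, computed blockwise.

    Uses the Cholesky/whitening identity: distances are Euclidean in the
    space y = L^T x where V^-1 = L L^T (symmetric square root via eigh for
    the PSD-regularized inverse).
    """
    Xf = np.asarray(X, dtype=float)
    w, V = np.linalg.eigh((cov_inverse + cov_inverse.T) / 2.0)
    w = np.clip(w, 0.0, None)
    Y = Xf @ (V * np.sqrt(w))
    n = Y.shape[0]
    D = np.zeros((n, n))
    sq = np.einsum("ij,ij->i", Y, Y)
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        G = Y[i0:i1] @ Y.T
        d2 = sq[i0:i1, None] + sq[None, :] - 2.0 * G
        D[i0:i1] = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# Resnik information-content distance


def term_information_content(annotations: dict[str, set[str]], obo: nx.MultiDiGraph,
                             namespace: str = "biological_process") -> dict[str, float]:
    """IC(t) = -log2 p(t), p = fraction of annotated genes hitting t or a descendant."""
    root = namespace_root(obo, namespace)
    counts: dict[str, int] = {}
    n_genes = 0
    for g, terms in annotations.items():
        closure: set[str] = set()
        for t in terms:
            if t in obo.nodes:
                closure |= term_ancestors(obo, t)
        if not closure:
            continue
        n_genes += 1
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
    if n_genes == 0:
        raise ValueError("no annotated genes")
    ic = {}
    for t, c in counts.items():
        ic[t] = -np.log2(c / n_genes)
    ic[root] = 0.0
    return ic


def resnik_gene_distance(terms_a: set[str], terms_b: set[str], obo: nx.MultiDiGraph,
                         ic: dict[str, float]) -> float | None:
    """(1/2)^sim with sim the best Resnik term-pair similarity.

    sim(t1, t2) = IC of the most informative common is_a ancestor; the gene
    similarity takes the max over annotation term pairs, so the distance is
    in (0, 1] and 1 means the genes share only the root.
    """
    if not terms_a or not terms_b:
        return None
    best = 0.0
    anc_b = {t: term_ancestors(obo, t) for t in terms_b}
    for t1 in terms_a:
        a1 = term_ancestors(obo, t1)
        for t2 in terms_b:
            common = a1 & anc_b[t2]
            if common:
                mica = max(ic.get(t, 0.0) for t in common)
                best = max(best, mica)
    return float(0.5 ** best)


def pairwise_resnik(annotations: dict[str, set[str]], obo: nx.MultiDiGraph,
                    ic: dict[str, float],
                    gene_order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Full gene-gene Resnik distance matrix.

    Precomputes the MICA information content for every term pair, then
    resolves gene pairs in descending-IC order so each pair is touched once.
    Genes without terms get NaN rows.
    """
    genes = list(gene_order) if gene_order is not None else sorted(annotations)
    terms = sorted({t for g in genes for t in annotations.get(g, ()) if t in obo.nodes})
    t_idx = {t: j for j, t in enumerate(terms)}
    anc = {t: term_ancestors(obo, t) for t in terms}
    nt = len(terms)
    mica = np.zeros((nt, nt))
    for i in range(nt):
        for j in range(i, nt):
            common = anc[terms[i]] & anc[terms[j]]
            v = max((ic.get(c, 0.0) for c in common), default=0.0)
            mica[i, j] = mica[j, i] = v
    X = np.zeros((len(genes), nt), dtype=bool)
    for gi, g in enumerate(genes):
        for t in annotations.get(g, ()):
            if t in t_idx:
                X[gi, t_idx[t]] = True
    n = len(genes)
    sim = np.zeros((n, n))  # unresolved pairs share only the root (IC 0)
    unset = np.ones((n, n), dtype=bool)
    iu = np.triu_indices(nt)
    order = np.argsort(-mica[iu])
    for k in order:
        i, j = iu[0][k], iu[1][k]
        if mica[i, j] <= 0.0:
            break
        both = np.outer(X[:, i], X[:, j])
        if i != j:
            both |= both.T
        mask = unset & both
        sim[mask] = mica[i, j]
        unset &= ~mask
    D = 0.5 ** sim
    bad = ~X.any(axis=1)
    D[bad, :] = np.nan
    D[:, bad] = np.nan
    np.fill_diagonal(D, 0.0)
    return D, genes


# ---------------------------------------------------------------------------
# group-level summaries


def tg_functional_matrix(D: np.ndarray, genes: list[str],
                         groups: dict[str, int]) -> GroupMatrix:
    """Mean pairwise functional distance for every temporal-group pair.

    ``D`` is the full symmetric gene-gene distance matrix aligned with
    ``genes``.  Unordered pairs counted once; self-pairs excluded.
    """
    gidx = np.array([groups.get(g, 0) for g in genes])
    return _aggregate_group_matrix(D, gidx, "functional_distance")


def _aggregate_group_matrix(D: np.ndarray, gidx: np.ndarray, kind: str) -> GroupMatrix:
    S = np.zeros((N_GROUPS, N_GROUPS))
    C = np.zeros((N_GROUPS, N_GROUPS), dtype=np.int64)
    n = len(gidx)
    mask = gidx > 0
    for m in range(1, N_GROUPS + 1):
        im = mask & (gidx == m)
        if not im.any():
            continue
        for g in range(m, N_GROUPS + 1):
            ig = mask & (gidx == g)
            if not ig.any():
                continue
            sub = D[np.ix_(im, ig)]
            if m == g:
                iu = np.triu_indices(sub.shape[0], k=1)
                vals = sub[iu]
            else:
                vals = sub.ravel()
            if vals.size:
                S[m - 1, g - 1] = S[g - 1, m - 1] = vals.sum()
                C[m - 1, g - 1] = C[g - 1, m - 1] = vals.size
    with np.errstate(invalid="ignore", divide="ignore"):
        V = np.where(C > 0, S / np.maximum(C, 1), np.nan)
    return GroupMatrix(V, C, kind)


def cluster_group_matrix(mat: GroupMatrix, method: str = "average") -> dict:
    """Agglomerative clustering of the 6x6 group matrix.

    The off-diagonal cells are the between-group dissimilarities.  The tree
    statistic is the summed cophenetic (along-tree) distance over all leaf
    pairs; the summed merge heights are reported too.
    """
    from scipy.cluster.hierarchy import cophenet

    M = mat.values.copy()
    off = M[np.triu_indices(N_GROUPS, k=1)]
    if np.any(np.isnan(off)):
        raise ValueError("group matrix has missing off-diagonal cells")
    Z = linkage(squareform(M - np.diag(np.diag(M)), checks=False), method=method)
    return {"Z": Z, "statistic": float(cophenet(Z).sum()),
            "merge_height_sum": float(Z[:, 2].sum()),
            "newick": linkage_to_newick(Z, GROUP_LABELS)}


def _leaf_sets(Z: np.ndarray) -> list[set[int]]:
    """Leaf sets of each internal merge of a 6-leaf linkage."""
    n = Z.shape[0] + 1
    sets: dict[int, set[int]] = {i: {i} for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + i] = s
        out.append(s)
    return out


def are_siblings(Z: np.ndarray, leaf_a: int, leaf_b: int) -> bool:
    """True if two leaves are merged directly with each other."""
    for a, b, _, _ in Z:
        if {int(a), int(b)} == {leaf_a, leaf_b}:
            return True
    return False


@dataclass
class DendrogramResult:
    Z: np.ndarray
    newick: str
    statistic: float
    null_statistics: np.ndarray
    p: float
    reps: int


def dendrogram_with_permutation(D: np.ndarray, genes: list[str],
                                groups: dict[str, int], method: str = "average",
                                reps: int = 1000, seed: int | None = None) -> DendrogramResult:
    """Cluster the observed TG matrix and test it against label permutations.

    The null permutes the gene -> temporal-group labels (preserving group
    sizes), rebuilds the 6x6 matrix and reclusters.  Label permutation
    homogenizes the matrix toward the grand mean distance, so real group
    structure shows up as an extreme summed along-tree distance on either
    side; p is the two-sided add-one permutation probability.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    gidx = np.array([groups.get(g, 0) for g in genes])
    obs_mat = _aggregate_group_matrix(D, gidx, "functional_distance")
    obs = cluster_group_matrix(obs_mat, method)
    null_stats = np.empty(reps)
    labels = gidx[gidx > 0]
    where = np.where(gidx > 0)[0]
    for r in range(reps):
        perm = gidx.copy()
        perm[where] = rng.permutation(labels)
        m = _aggregate_group_matrix(D, perm, "functional_distance")
        null_stats[r] = cluster_group_matrix(m, method)["statistic"]
    lo = (1 + int(np.sum(null_stats <= obs["statistic"]))) / (reps + 1)
    hi = (1 + int(np.sum(null_stats >= obs["statistic"]))) / (reps + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    return DendrogramResult(obs["Z"], obs["newick"], obs["statistic"], null_stats, float(p), reps)


def corr_funcdist_vs_agediff(mat: GroupMatrix, ages_mya: np.ndarray | None = None,
                             cells: str = "full", age_scale: str = "rank") -> tuple[float, float]:
    """Spearman correlation between group functional distance and age separation.

    Defaults correlate every cell of the symmetric 6x6 matrix against the
    difference in group age rank (group index), which treats the six ages
    as an ordinal scale.  ``cells='upper'`` restricts to the 21
    upper-triangle cells, ``cells='offdiag'`` drops the diagonal;
    ``age_scale='mya'`` uses absolute age differences in Myr instead of
    ranks (the two differ only through tie structure).
    """
    if age_scale == "rank":
        a = np.arange(1, N_GROUPS + 1, dtype=float)
    elif age_scale == "mya":
        if ages_mya is None:
            raise ValueError("age_scale='mya' requires ages_mya")
        a = np.asarray(ages_mya, dtype=float)
    else:
        raise ValueError(f"unknown age_scale {age_scale!r}")
    A = np.abs(a[:, None] - a[None, :])
    if cells == "full":
        x, y = mat.values.ravel(), A.ravel()
    elif cells == "upper":
        iu = np.triu_indices(N_GROUPS)
        x, y = mat.values[iu], A[iu]
    elif cells == "offdiag":
        iu = np.triu_indices(N_GROUPS, k=1)
        x, y = mat.values[iu], A[iu]
    else:
        raise ValueError(f"unknown cells {cells!r}")
    ok = ~np.isnan(x)
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def funcdist_by_network_distance(D: np.ndarray, genes: list[str],
                                 distances: dict, cap: int = 8,
                                 max_pairs: int | None = None,
                                 seed: int | None = None) -> dict:
    """Mean functional distance profiled by network distance.

    Network distances >= cap are pooled into the last bin.  Also reports
    the global Spearman correlation between the two distances over the
    pairs used.  ``max_pairs`` subsamples pairs (seeded) for large inputs.
    """
    idx = {g: i for i, g in enumerate(genes)}
    fd_vals: list[float] = []
    nd_vals: list[int] = []
    for u, du in distances.items():
        iu = idx.get(u)
        if iu is None:
            continue
        for v, d in du.items():
            if v <= u:
                continue
            iv = idx.get(v)
            if iv is None or d < 1:
                continue
            fd_vals.append(D[iu, iv])
            nd_vals.append(min(d, cap))
    fd = np.array(fd_vals)
    nd = np.array(nd_vals)
    if max_pairs is not None and fd.size > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(fd.size, size=max_pairs, replace=False)
        fd, nd = fd[pick], nd[pick]
    prof_d = np.arange(1, cap + 1)
    prof = np.array([fd[nd == d].mean() if (nd == d).any() else np.nan for d in prof_d])
    if fd.size >= 2 and len(np.unique(nd)) > 1 and not np.all(fd == fd[0]):
        rho, p = stats.spearmanr(fd, nd)
    else:
        rho, p = np.nan, np.nan
    return {"network_distance": prof_d, "mean_functional_distance": prof,
            "rho": float(rho), "p": float(p), "n_pairs": int(fd.size)}
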