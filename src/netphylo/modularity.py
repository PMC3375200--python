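"""Hub-neighborhood functional coherence and enrichment statistics.

A topological unit is a hub (degree >= 50 by default) together with its
interaction partners.  Its functional coherence is measured by the group
distance: the mean functional distance over partner pairs drawn from
different temporal groups (restricting to cross-group pairs removes the
within-group similarity signal).  The empirical per-hub group distances are
compared with those from degree-preserving rewired networks; bias controls
drop partner pairs that themselves interact and genes from multi-gene
duplication clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PPINetwork
from .temporal import DuplicationClusters

logger = logging.getLogger("netphylo")


def rewire_degree_preserving(net: PPINetwork, n_swaps_per_edge: float = 10.0,
                             seed: int | None = None) -> PPINetwork:
    """Randomize edges by repeated double-edge swaps, keeping every degree.

    Swaps producing self-loops or multi-edges are rejected.  On graphs too
    constrained to swap, returns the best effort with a warning; the degree
    sequence is preserved in every case.
    """
    if n_swaps_per_edge <= 0:
        raise ValueError("n_swaps_per_edge must be > 0")
    g = net.graph.copy()
    m = g.number_of_edges()
    nswap = max(1, int(round(n_swaps_per_edge * m)))
    try:
        seed_int = int(np.random.default_rng(seed).integers(2**31))
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=seed_int)
    except nx.NetworkXError as e:
        logger.warning("rewiring stopped early: %s", e)
    except nx.NetworkXAlgorithmError as e:
        logger.warning("rewiring exhausted tries: %s", e)
    return PPINetwork(g, dict(net.cleaning_log))


def edge_overlap(a: PPINetwork, b: PPINetwork) -> float:
    """Fraction of a's edges also present in b."""
    ea, eb = a.edges, b.edges
    return len(ea & eb) / len(ea) if ea else float("nan")


@dataclass
class HubAnalysisResult:
    hub_min_degree: int
    hub_ids: list[str]
    group_distances: np.ndarray
    n_hubs_skipped: int
    n_pairs_skipped_missing: int
    exclusions: dict = field(default_factory=dict)


def hub_group_distance(net: PPINetwork, groups: dict[str, int],
                       funcdist, hub_min_degree: int = 50,
                       exclude_interacting: bool = False,
                       dup_clusters: DuplicationClusters | None = None) -> HubAnalysisResult:
    """Per-hub mean functional distance over cross-group partner pairs.

    ``funcdist(a, b)`` returns the functional distance or None when either
    gene lacks annotations.  Partner pairs sharing a temporal group never
    count; optional exclusions drop pairs that are themselves edges and
    genes from multi-gene duplication clusters.  Hubs with no qualifying
    pair are skipped and counted.
    """
    if hub_min_degree < 2:
        raise ValueError("hub_min_degree must be >= 2")
    dup_genes = dup_clusters.duplicated_genes() if dup_clusters is not None else set()
    hub_ids, values = [], []
    skipped_hubs = skipped_pairs = 0
    for node in net.graph.nodes:
        if net.graph.degree[node] < hub_min_degree:
            continue
        partners = [p for p in net.graph.neighbors(node) if p in groups
                    and p not in dup_genes]
        pair_vals = []
        for a, b in combinations(partners, 2):
            if groups[a] == groups[b]:
                continue
            if exclude_interacting and net.graph.has_edge(a, b):
                continue
            d = funcdist(a, b)
            if d is None or (isinstance(d, float) and np.isnan(d)):
                skipped_pairs += 1
                continue
            pair_vals.append(d)
        if pair_vals:
            hub_ids.append(node)
            values.append(float(np.mean(pair_vals)))
        else:
            skipped_hubs += 1
    return HubAnalysisResult(
        hub_min_degree, hub_ids, np.array(values), skipped_hubs, skipped_pairs,
        {"interacting_pairs": exclude_interacting,
         "duplication_clusters": dup_clusters is not None})


def hub_null_comparison(net: PPINetwork, groups: dict[str, int], funcdist,
                        hub_min_degree: int = 50, reps: int = 20,
                        n_swaps_per_edge: float = 10.0, seed: int | None = None,
                        exclude_interacting: bool = False,
                        dup_clusters: DuplicationClusters | None = None,
                        pool: str = "per_hub") -> dict:
    """Empirical hub group distances vs degree-preserving rewired networks.

    Per-hub values from all rewired replicates are pooled (``pool='per_rep'``
    compares per-replicate means instead) and compared with the empirical
    distribution by the two-sample Kruskal-Wallis test (equivalent to
    Mann-Whitney, df = 1).  A negative direction means hubs in the real
    network have tighter (smaller) group distances than in the nulls.
    """
    rng = np.random.default_rng(seed)
    emp = hub_group_distance(net, groups, funcdist, hub_min_degree,
                             exclude_interacting, dup_clusters)
    if len(emp.group_distances) < 5:
        logger.warning("only %d hubs with qualifying pairs", len(emp.group_distances))
    null_vals: list[float] = []
    for _ in range(reps):
        rw = rewire_degree_preserving(net, n_swaps_per_edge, int(rng.integers(2**31)))
        res = hub_group_distance(rw, groups, funcdist, hub_min_degree,
                                 exclude_interacting, dup_clusters)
        if pool == "per_rep":
            if len(res.group_distances):
                null_vals.append(float(res.group_distances.mean()))
        else:
            null_vals.extend(res.group_distances.tolist())
    null = np.array(null_vals)
    if len(emp.group_distances) and len(null):
        try:
            H, p = stats.kruskal(emp.group_distances, null)
        except ValueError:
            H, p = 0.0, 1.0
        direction = float(emp.group_distances.mean() - null.mean())
    else:
        H, p, direction = np.nan, np.nan, np.nan
    return {"empirical": emp, "null_values": null, "H": float(H), "p": float(p),
            "df": 1, "direction": direction, "reps": reps}


def hub_partner_pairs(net: PPINetwork, groups: dict[str, int],
                      hub_min_degree: int = 50) -> set[tuple[str, str]]:
    """All unordered cross-group partner pairs over all hubs."""
    pairs: set[tuple[str, str]] = set()
    for node in net.graph.nodes:
        if net.graph.degree[node] < hub_min_degree:
            continue
        partners = [p for p in net.graph.neighbors(node) if p in groups]
        for a, b in combinations(partners, 2):
            if groups[a] != groups[b]:
                pairs.add((a, b) if a < b else (b, a))
    return pairs


def distance2_baseline(hub_pair_values: np.ndarray, d2_values: np.ndarray,
                       hub_pairs: list[tuple[str, str]] | None = None,
                       d2_pairs: list[tuple[str, str]] | None = None) -> dict:
    """Z-test of hub partner-pair distances vs all network-distance-2 pairs.

    Z = (mean_hub - mean_d2) / SE(difference), two-sided Gaussian p.  A
    negative Z means hub neighborhoods are functionally tighter than
    generic distance-2 pairs.

    Pair values sharing a gene are correlated, so the iid SE is
    anti-conservative.  When the pair gene ids are supplied the SE comes
    from a leave-one-gene-out jackknife of the mean difference, which
    restores null calibration; otherwise the naive iid SE is used.
    """
    a = np.asarray(hub_pair_values, dtype=float)
    b = np.asarray(d2_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values on each side")
    diff = a.mean() - b.mean()
    if hub_pairs is not None and d2_pairs is not None:
        se = _jackknife_se_diff(a, b, hub_pairs, d2_pairs)
        se_kind = "gene_jackknife"
    else:
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        se_kind = "naive"
    z = diff / se if se > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z))
    return {"Z": float(z), "p": float(p), "n_hub_pairs": int(a.size),
            "n_d2_pairs": int(b.size), "se": float(se), "se_kind": se_kind}


def _jackknife_se_diff(a: np.ndarray, b: np.ndarray,
                       a_pairs: list[tuple[str, str]],
                       b_pairs: list[tuple[str, str]]) -> float:
    """Leave-one-gene-out jackknife SE for mean(a) - mean(b)."""
    sa: dict[str, float] = {}
    ca: dict[str, int] = {}
    for v, (x, y) in zip(a, a_pairs):
        for g in (x, y):
            sa[g] = sa.get(g, 0.0) + v
            ca[g] = ca.get(g, 0) + 1
    sb: dict[str, float] = {}
    cb: dict[str, int] = {}
    for v, (x, y) in zip(b, b_pairs):
        for g in (x, y):
            sb[g] = sb.get(g, 0.0) + v
            cb[g] = cb.get(g, 0) + 1
    genes = sorted(set(sa) | set(sb))
    Sa, Na, Sb, Nb = a.sum(), a.size, b.sum(), b.size
    thetas = []
    for g in genes:
        na = Na - ca.get(g, 0)
        nb = Nb - cb.get(g, 0)
        if na < 1 or nb < 1:
            continue
        thetas.append((Sa - sa.get(g, 0.0)) / na - (Sb - sb.get(g, 0.0)) / nb)
    th = np.array(thetas)
    G = th.size
    if G < 2:
        return float("nan")
    return float(np.sqrt((G - 1) / G * np.sum((th - th.mean()) ** 2)))


def controlled_correlation(prop: dict[str, float], groups: dict[str, int],
                           categories: dict[str, set[str]], min_genes: int = 10,
                           weighted: bool = False) -> dict:
    """Global vs function-controlled correlation of a property with gene age.

    The global coefficient is Spearman rho(property, group index).  The
    controlled coefficient recomputes rho within each functional category
    and averages; a one-sample t-test of the per-category coefficients
    against the global value (df = categories - 1) asks whether controlling
    for function changed the correlation.
    """
    genes = [g for g in prop if g in groups and not np.isnan(prop[g])]
    gp = np.array([prop[g] for g in genes])
    gi = np.array([groups[g] for g in genes])
    global_rho = float(stats.spearmanr(gp, gi)[0])
    cat_rhos, cat_names, cat_sizes = [], [], []
    for name, members in categories.items():
        sub = [g for g in genes if g in members]
        if len(sub) < min_genes:
            continue
        x = np.array([prop[g] for g in sub])
        y = np.array([groups[g] for g in sub])
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        r = stats.spearmanr(x, y)[0]
        if np.isnan(r):
            continue
        cat_rhos.append(float(r))
        cat_names.append(name)
        cat_sizes.append(len(sub))
    if len(cat_rhos) < 2:
        raise ValueError("need >= 2 usable categories")
    rhos = np.array(cat_rhos)
    if weighted:
        w = np.array(cat_sizes, dtype=float)
        controlled = float(np.average(rhos, weights=w))
    else:
        controlled = float(rhos.mean())
    df = len(rhos) - 1
    sd = rhos.std(ddof=1)
    t = (rhos.mean() - global_rho) / (sd / np.sqrt(len(rhos))) if sd > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), df)
    return {"global_rho": global_rho, "controlled_rho": controlled,
            "per_category_rho": dict(zip(cat_names, cat_rhos)),
            "t": float(t), "df": df, "p": float(p)}


def group_term_enrichment(groups: dict[str, int], gene_terms: dict[str, set[str]],
                          background: set[str] | None = None,
                          alpha: float = 0.05) -> dict:
    """Hypergeometric sub-root term enrichment per temporal group.

    Upper-tail p for the term count within a group given the background
    totals; BH correction within each group's family.  Also reports, per
    group, the significant terms and those significant in exactly one group.
    """
    bg = set(background) if background is not None else set(groups)
    bg &= set(gene_terms)
    terms = sorted({t for g in bg for t in gene_terms.get(g, ())})
    bg_count = {t: sum(1 for g in bg if t in gene_terms.get(g, ())) for t in terms}
    M = len(bg)
    rows = []
    group_ids = sorted(set(groups.values()))
    for gi in group_ids:
        members = [g for g in bg if groups.get(g) == gi]
        n = len(members)
        fam = []
        for t in terms:
            K = bg_count[t]
            if K == 0:
                continue
            k = sum(1 for g in members if t in gene_terms.get(g, ()))
            p = stats.hypergeom.sf(k - 1, M, K, n)
            fam.append((gi, t, k, K, float(p)))
        if fam:
            pvals = [r[4] for r in fam]
            _, q, _, _ = multipletests(pvals, method="fdr_bh")
            for r, qv in zip(fam, q):
                rows.append(r + (float(qv),))
    sig = {gi: {r[1] for r in rows if r[0] == gi and r[5] <= alpha} for gi in group_ids}
    all_sig = [t for gi in group_ids for t in sig[gi]]
    unique = {gi: {t for t in sig[gi] if all_sig.count(t) == 1} for gi in group_ids}
    return {"rows": rows, "significant": sig, "unique": unique}


def property_zscore_enrichment(prop: dict[str, float],
                               categories: dict[str, set[str]]) -> list[dict]:
    """z-score for category means of a network property, BH across categories.

    z = (mean_cat - mean_all) / (sd_all / sqrt(n_cat)), two-sided Gaussian p.
    """
    genes = [g for g in prop if not np.isnan(prop[g])]
    vals = np.array([prop[g] for g in genes])
    mu, sd = vals.mean(), vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero overall variance")
    gset = set(genes)
    rows = []
    for name, members in categories.items():
        sub = [prop[g] for g in members & gset]
        if len(sub) < 2:
            continue
        n = len(sub)
        z = (np.mean(sub) - mu) / (sd / np.sqrt(n))
        rows.append({"category": name, "n": n, "mean": float(np.mean(sub)),
                     "z": float(z), "p": float(2 * stats.norm.sf(abs(z)))})
    if rows:
        _, q, _, _ = multipletests([r["p"] for r in rows], method="fdr_bh")
        for r, qv in zip(rows, q):
            r["q"] = float(qv)
    return rows
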