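"""Graph statistics for the grouped interaction network.

Per-node degree and clustering coefficient, shortest-path (network)
distances, group-pair summary matrices, interaction density, per-stage
rates of topological change and the Erdos-Renyi clustering comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .io import N_GROUPS, GroupMatrix, PPINetwork


def clustering_coefficient(net: PPINetwork, node: str) -> float:
    """Fraction of a node's neighbor pairs that are themselves connected.

    2*T / (k*(k-1)) with T the triangles through the node; NaN for k < 2
    (undefined, not zero).
    """
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network")
    k = net.graph.degree[node]
    if k < 2:
        return float("nan")
    t = nx.triangles(net.graph, node)
    return 2.0 * t / (k * (k - 1))


def clustering_coefficients(net: PPINetwork) -> dict[str, float]:
    tri = nx.triangles(net.graph)
    out = {}
    for n in net.graph.nodes:
        k = net.graph.degree[n]
        out[n] = float("nan") if k < 2 else 2.0 * tri[n] / (k * (k - 1))
    return out


def mean_clustering(net: PPINetwork) -> float:
    """Mean clustering coefficient over nodes where it is defined."""
    vals = [c for c in clustering_coefficients(net).values() if not np.isnan(c)]
    return float(np.mean(vals)) if vals else float("nan")


def all_pairs_distances(net: PPINetwork):
    """BFS shortest-path lengths from every node.

    Returns ``{source: {target: hops}}``; unreachable pairs are simply
    absent, so callers exclude them from averages.
    """
    return dict(nx.all_pairs_shortest_path_length(net.graph))


def group_distance_matrix(net: PPINetwork, groups: dict[str, int],
                          distances: dict | None = None) -> GroupMatrix:
    """Mean shortest-path distance for every temporal-group pair.

    Unordered node pairs are counted once; unreachable pairs are excluded.
    Per-group means "to all other proteins" follow by pair-count weighting
    of a group's row (see :func:`per_group_mean_distance`).
    """
    if distances is None:
        distances = all_pairs_distances(net)
    S = np.zeros((N_GROUPS, N_GROUPS))
    C = np.zeros((N_GROUPS, N_GROUPS), dtype=np.int64)
    for u, du in distances.items():
        gu = groups.get(u)
        if gu is None:
            continue
        for v, d in du.items():
            if v == u:
                continue
            gv = groups.get(v)
            if gv is None:
                continue
            S[gu - 1, gv - 1] += d
            C[gu - 1, gv - 1] += 1
    # every unordered pair appears twice (u->v and v->u) in the ordered sums
    Ssym, Csym = (S + S.T) / 2.0, (C + C.T) // 2
    with np.errstate(invalid="ignore", divide="ignore"):
        # ordered/2 double-counts the diagonal's unordered pairs consistently
        values = np.where(Csym > 0, Ssym / np.maximum(Csym, 1), np.nan)
    counts = Csym.copy()
    counts[np.diag_indices(N_GROUPS)] //= 2  # unordered within-group pairs
    return GroupMatrix(values, counts, "network_distance")


def per_group_mean_distance(mat: GroupMatrix, group_sizes: np.ndarray) -> np.ndarray:
    """Weighted mean of each group's row: mean distance to all other proteins."""
    out = np.full(N_GROUPS, np.nan)
    for m in range(N_GROUPS):
        w = group_sizes.astype(float).copy()
        w[m] -= 1
        ok = ~np.isnan(mat.values[m]) & (w > 0)
        if ok.any():
            out[m] = np.average(mat.values[m][ok], weights=w[ok])
    return out


@dataclass
class InteractionDensity:
    """Observed vs possible interactions between temporal groups.

    D[m,n] = I[m,n] / E[m,n] with E = N_m*N_n off-diagonal and
    N_m*(N_m-1)/2 on the diagonal.  ``normalized`` divides each row by that
    group's aggregate density so rows are comparable.
    """

    I: np.ndarray
    E: np.ndarray
    N: np.ndarray
    D: np.ndarray
    normalized: np.ndarray | None = None


def interaction_density(net: PPINetwork, groups: dict[str, int],
                        normalize: bool = False,
                        normalize_by: str = "row") -> InteractionDensity:
    missing = [n for n in net.graph.nodes if n not in groups]
    if missing:
        raise ValueError(f"{len(missing)} network nodes lack a temporal group")
    N = np.zeros(N_GROUPS, dtype=np.int64)
    for n in net.graph.nodes:
        N[groups[n] - 1] += 1
    I = np.zeros((N_GROUPS, N_GROUPS), dtype=np.int64)
    for u, v in net.graph.edges:
        m, n = groups[u] - 1, groups[v] - 1
        I[m, n] += 1
        if m != n:
            I[n, m] += 1
    E = np.outer(N, N)
    np.fill_diagonal(E, N * (N - 1) // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(E > 0, I / np.maximum(E, 1), np.nan)
    norm = None
    if normalize:
        if normalize_by == "row":
            row_density = I.sum(axis=1) / np.maximum(E.sum(axis=1), 1)
            norm = D / row_density[:, None]
        elif normalize_by == "global":
            norm = D / (I[np.triu_indices(N_GROUPS)].sum() / E[np.triu_indices(N_GROUPS)].sum())
        else:
            raise ValueError(f"unknown normalize_by {normalize_by!r}")
    return InteractionDensity(I, E, N, D, norm)


def rate_of_change(values, ages_mya, normalize: str = "sum",
                   include_last_stage: bool = False) -> np.ndarray:
    """Absolute property change per Myr for each consecutive group stage.

    Stage i covers TGi -> TGi+1; the last stage (TG5 -> TG6) is excluded by
    default because its short age gap makes the rate unstable.  Rates are
    normalized by their sum (or max) across stages so different properties
    are comparable.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages_mya, dtype=float)
    if values.shape != ages.shape or values.size < 2:
        raise ValueError("need matching values and ages for >= 2 groups")
    dt = ages[:-1] - ages[1:]
    if np.any(dt == 0):
        raise ValueError("consecutive groups with equal ages")
    rates = np.abs(np.diff(values)) / dt
    if not include_last_stage:
        rates = rates[:-1]
    if normalize == "sum":
        total = rates.sum()
        return rates / total if total > 0 else rates
    if normalize == "max":
        mx = rates.max()
        return rates / mx if mx > 0 else rates
    if normalize == "none":
        return rates
    raise ValueError(f"unknown normalize {normalize!r}")


def er_clustering_test(net: PPINetwork, reps: int = 1000,
                       seed: int | None = None) -> dict:
    """Mean clustering coefficient vs Erdos-Renyi G(n, m) null networks.

    p uses the add-one rule, so it is always in (0, 1].
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    obs = mean_clustering(net)
    n, m = net.n_nodes, net.n_edges
    null = []
    for _ in range(reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        null.append(mean_clustering(PPINetwork(g)))
    null = np.array(null)
    p = (1 + int(np.sum(null >= obs))) / (reps + 1)
    return {"observed": obs, "null": null, "p": p}


def fit_loglog_slope(degrees, n_bins: int = 12) -> tuple[float, float]:
    """Least-squares slope of the log-binned degree density on log-log axes.

    A descriptive summary of heavy-tailed behavior, not an exponent MLE.
    Returns (slope, r_squared).
    """
    degrees = np.asarray(degrees, dtype=float)
    degrees = degrees[degrees > 0]
    kmin, kmax = degrees.min(), degrees.max()
    if kmin == kmax:
        return float("nan"), float("nan")
    edges = np.logspace(np.log10(kmin), np.log10(kmax + 1), n_bins + 1)
    counts, _ = np.histogram(degrees, bins=edges)
    pk = counts / counts.sum() / np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    ok = pk > 0
    slope, _, r, _, _ = stats.linregress(np.log10(centers[ok]), np.log10(pk[ok]))
    return float(slope), float(r**2)


def degree_histogram_loglog(net: PPINetwork, n_bins: int = 12) -> dict:
    """Log-binned degree distribution, C(k) curve and descriptive slope."""
    degrees = np.array([d for _, d in net.graph.degree], dtype=float)
    degrees = degrees[degrees > 0]
    cc = clustering_coefficients(net)
    kmin, kmax = degrees.min(), degrees.max()
    if kmin == kmax:
        return {"bin_centers": np.array([kmin]), "pk": np.array([1.0]),
                "mean_c": np.array([np.nan]), "slope": np.nan, "r2": np.nan}
    edges = np.logspace(np.log10(kmin), np.log10(kmax + 1), n_bins + 1)
    counts, _ = np.histogram(degrees, bins=edges)
    pk = counts / counts.sum() / np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    deg_by_node = dict(net.graph.degree)
    mean_c = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = [cc[n] for n, k in deg_by_node.items()
                if edges[b] <= k < edges[b + 1] and not np.isnan(cc[n])]
        if vals:
            mean_c[b] = np.mean(vals)
    slope, r2 = fit_loglog_slope(degrees, n_bins)
    return {"bin_centers": centers, "pk": pk, "mean_c": mean_c,
            "slope": slope, "r2": r2}


def property_by_group(values: dict[str, float], groups: dict[str, int]) -> dict:
    """Per-group means of a node property plus the Kruskal-Wallis test."""
    samples: dict[int, list[float]] = {}
    for n, v in values.items():
        gi = groups.get(n)
        if gi is not None and not np.isnan(v):
            samples.setdefault(gi, []).append(v)
    populated = {gi: v for gi, v in samples.items() if v}
    means = {gi: float(np.mean(v)) for gi, v in populated.items()}
    if len(populated) >= 2:
        try:
            H, p = stats.kruskal(*[populated[gi] for gi in sorted(populated)])
        except ValueError:
            H, p = 0.0, 1.0
    else:
        H, p = np.nan, np.nan
    return {"means": means, "H": float(H), "p": float(p), "df": len(populated) - 1}


def degree_age_spearman(net: PPINetwork, groups: dict[str, int]) -> tuple[float, float]:
    """Spearman correlation between degree and group index (6 tied age levels).

    Group index increases with recency, so a negative rho means older
    proteins have more interactions.
    """
    nodes = [n for n in net.graph.nodes if n in groups]
    deg = [net.graph.degree[n] for n in nodes]
    idx = [groups[n] for n in nodes]
    rho, p = stats.spearmanr(deg, idx)
    return float(rho), float(p)
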