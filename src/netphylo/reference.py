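"""Published group-level summary tables for the integrated human PPI network.

The original study assigned 9,530 network proteins to six temporal groups
(TG1 oldest ... TG6 human-lineage-specific) and reported group ages,
per-group gene counts and the 6x6 matrices of mean pairwise network distance
and mean pairwise functional (Mahalanobis) distance.  Those printed summary
tables are inputs to the reconstruction analyses in this package: per-group
weighted mean network distances, the functional-distance/age correlation and
the temporal-group dendrogram are all recomputed from them at run time.
"""

from __future__ import annotations

import numpy as np

from .io import GroupMatrix

#: Approximate group ages in millions of years (TG1..TG6).
AGES_MYA = np.array([990.0, 450.0, 360.0, 310.0, 90.0, 50.0])

#: Genes per temporal group in the genome.
GENOME_COUNTS = np.array([720, 5211, 1929, 2694, 6663, 1313])

#: Genes per temporal group present in the interaction network.
NETWORK_COUNTS = np.array([544, 3546, 1093, 1348, 2794, 205])

#: Per-group mean interaction degree.
MEAN_DEGREE = np.array([29.509, 17.399, 13.100, 10.061, 8.623, 3.434])

#: Per-group mean clustering coefficient.
MEAN_CLUSTERING = np.array([0.212, 0.196, 0.193, 0.180, 0.169, 0.176])

#: Per-group mean omega (Ka/Ks against mouse orthologs).
MEAN_OMEGA = np.array([0.034, 0.089, 0.096, 0.128, 0.179, 0.168])


def _sym(upper: list[list[float]]) -> np.ndarray:
    m = np.zeros((6, 6))
    for i, row in enumerate(upper):
        for k, v in enumerate(row):
            j = i + k
            m[i, j] = m[j, i] = v
    return m


#: Mean shortest-path distance between temporal groups (upper triangle rows).
NETWORK_DISTANCE = _sym([
    [3.611, 3.771, 3.835, 3.931, 4.035, 4.183],
    [3.922, 3.986, 4.078, 4.181, 4.325],
    [4.044, 4.138, 4.239, 4.387],
    [4.227, 4.322, 4.463],
    [4.404, 4.538],
    [4.655],
])

#: Mean Mahalanobis functional distance between temporal groups.
FUNCTIONAL_DISTANCE = _sym([
    [4.413, 4.560, 5.344, 6.109, 6.512, 6.018],
    [4.321, 5.054, 5.643, 6.070, 6.311],
    [4.996, 5.900, 6.189, 5.595],
    [5.921, 5.938, 4.967],
    [4.903, 4.377],
    [2.975],
])


def _pair_counts(n: np.ndarray) -> np.ndarray:
    c = np.outer(n, n)
    np.fill_diagonal(c, n * (n - 1) // 2)
    return c


def network_distance_matrix() -> GroupMatrix:
    """The published mean network-distance matrix as a GroupMatrix."""
    return GroupMatrix(NETWORK_DISTANCE, _pair_counts(NETWORK_COUNTS), "network_distance")


def functional_distance_matrix() -> GroupMatrix:
    """The published mean functional-distance matrix as a GroupMatrix."""
    return GroupMatrix(FUNCTIONAL_DISTANCE, _pair_counts(NETWORK_COUNTS), "functional_distance")


def weighted_row_mean(matrix: np.ndarray, counts: np.ndarray, group: int) -> float:
    """Pair-count-weighted mean of one group's row.

    Weights are the partner-group gene counts (own group uses N-1), which
    recovers the per-group mean distance to all other proteins in the
    network from the printed group-pair matrix.
    """
    m = group - 1
    w = counts.astype(float).copy()
    w[m] -= 1
    return float(np.average(matrix[m], weights=w))
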