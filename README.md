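# netphylo

Phylostratigraphic analysis of protein–protein interaction (PPI) networks:
how network topology and gene function co-vary with evolutionary age, and
whether the topological unit (a hub plus its partners) is also a functional
unit.

The package is aimed at systems-biology researchers who have an interaction
edge list, BLAST-tabular homology hits, GO-style annotations (GAF + OBO)
and optionally a per-gene Ka/Ks table, and want a tested, reproducible
pipeline for:

1. **Temporal groups** — each gene is assigned the oldest clade with a
   homology hit at e-value ≤ threshold (six groups, TG1 oldest → TG6
   lineage-specific), plus single-linkage duplication clusters from
   human-vs-human similarity.
2. **Topology by age** — per-group degree and clustering coefficient
   `C = 2T/k(k−1)`, the 6×6 matrix of mean shortest-path distances,
   interaction densities `D(m,n) = I(m,n)/E(m,n)`, per-stage rates of
   change, and an Erdős–Rényi clustering comparison.
3. **Function by age** — genes embedded as binary vectors over the sub-root
   GO terms, Mahalanobis distance `sqrt((x−y)ᵀΣ⁻¹(x−y))` under the term
   covariance (Resnik `(1/2)^maxIC` backend available), the 6×6 TG
   functional-distance matrix, its average-linkage dendrogram with a
   gene-label permutation test, and the Spearman correlation of functional
   distance with group-age separation.
4. **Hub coherence** — for every hub, the *group distance* (mean functional
   distance over partner pairs from different temporal groups), compared
   against degree-preserving rewired networks (Kruskal–Wallis, df = 1),
   with bias controls for directly interacting pairs and duplicated genes,
   and a distance-2 baseline Z-test with a gene-jackknife standard error.

A synthetic-data generator (duplication–divergence network growth with
age-graded annotations and tunable hub coherence) provides planted-truth
inputs, so every stage has recovery and type-I calibration tests. The
published six-group summary tables of the human PPI network ship as
reference data for the reconstruction analyses.

## Worked example

Run the numbered drivers in order (each is a thin script over the library
that prints what it found and writes tables under `results/`):

```sh
python analysis/01_simulate.py --seed 1        # emit synthetic study inputs
python analysis/02_temporal_groups.py          # assign TGs, clusters, omega
python analysis/03_topology.py                 # per-group topology
python analysis/04_functional_distance.py      # functional organization
python analysis/05_hub_coherence.py            # hub test vs rewired nulls
python analysis/06_published_reconstructions.py
```

Selected output from a run with `--seed 1` (n = 1000 genes, 11,823 edges):

```
degree by group: KW H = 298.1, p = 2.6e-62
degree vs group index: Spearman rho = -0.515 (p = 7.46e-69)
per-group mean network distance: [2.351, 2.531, 2.625, 2.703, 2.681, 2.729]
functional distance vs age separation: Spearman rho = 0.783 (p = 1.66e-08)
dendrogram permutation test: statistic = 115.81, p = 0.004 (499 permutations)
hubs (n=20): group distance 7.624 vs rewired 7.756; KW H = 15.63, df = 1, p = 7.71e-05
hub partner pairs vs all distance-2 pairs: Z = -6.67, p = 2.52e-11 (gene-jackknife SE)
```

Older groups have more interactions (negative degree–age-rank rho), sit
closer to the rest of the network (mean distance rises from TG1 to TG6),
functional distance between groups grows with their age separation (rho =
0.783 with a significant dendrogram), and hub neighborhoods are
functionally tighter than in degree-matched rewired networks (smaller group
distance, negative Z) — the four signatures the generator plants and the
pipeline is built to detect.

`06_published_reconstructions.py` works from the bundled human-network
summary tables: the pair-count-weighted row means reproduce the printed
per-group network distances (TG1 3.878 … TG6 4.413), the
functional-distance/age-rank correlation is 0.725, and average-linkage
clustering separates TG3 and TG4 into different clades.

A `netphylo` console script exposes the same stages
(`simulate`, `assign-groups`, `dup-clusters`, `topology`, `funcdist`,
`run`) for shell use; see `netphylo --help`.

## Layout

```
src/netphylo/      library: io, temporal, topology, funcspace, modularity,
                   simulate, pipeline, reference, cli
analysis/          numbered narrative drivers (01..06)
tests/             pytest suite: unit, property, oracle, calibration
scripts/           acceptance.py
docs/methods.md    models, parameter choices, generator scope, limitations
```
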