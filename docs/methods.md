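# Methods

`netphylo` analyses how a protein–protein interaction (PPI) network is
organized in evolutionary time: genes are binned into six temporal groups
(TGs) by phylostratigraphy, topology and function are summarized per group
pair, and the functional coherence of hub neighborhoods is tested against
degree-preserving null networks. This note records the models, the choices
behind every tunable, and what the bundled synthetic generator does and does
not emulate.

## Temporal groups (phylostratigraphy)

A gene is assigned the oldest clade in which it has a homology hit at or
below the e-value threshold (default `1e-20`, inclusive comparison); genes
with no qualifying hit in any clade fall into the newest group (TG6,
lineage-specific). The default clade scheme maps five clades to TG1–TG5
(protostomes → teleost fish → amphibians → birds → non-primate mammals) with
approximate ages 990/450/360/310/90/50 Mya; TG1 is the oldest. Assignment is
monotone in the threshold: loosening it can only move genes to older groups,
which the test suite asserts on random hit tables. Only the e-value is used;
no minimum alignment-length filter is applied, since hit tables arrive
pre-filtered from the search tool.

Duplication clusters are single-linkage closures (connected components) of
the human-vs-human similarity graph at threshold `1e-25`: if A resembles B
and B resembles C, all three share a cluster even if A and C do not match
directly. Clusters of two or more genes mark detectable duplication
histories and can be excluded from the hub analysis.

Selective constraint arrives as a per-gene omega (Ka/Ks) table computed
externally; codon-model maximum likelihood estimation is out of scope here.
Group differences in omega, degree, and clustering are tested with the
Kruskal–Wallis test (equivalent to Mann–Whitney for two samples, df = 1).

## Topology

- **Degree** and **clustering coefficient** `C = 2T / k(k-1)` on the cleaned
  simple graph; `C` is *undefined* (not zero) for `k < 2` and such nodes are
  excluded from group means.
- **Network distance** is the unweighted shortest-path length (BFS from every
  node). Unreachable pairs are excluded from averages — the only convention
  that keeps means finite; cell coverage is retained via pair counts. The
  per-group mean distance "to all other proteins" is the pair-count-weighted
  mean of that group's row of the 6×6 matrix (own group weighted `N−1`).
- **Interaction density** `D(m,n) = I(m,n) / E(m,n)` with
  `E = N_m N_n` off-diagonal and `N_m (N_m − 1)/2` on the diagonal. The
  normalized variant divides each row by that group's aggregate density
  (`ΣI/ΣE` over the row), making rows comparable; a whole-network
  normalization is available via a flag. Σ of `I` over the upper triangle
  equals the edge count — asserted on every run.
- **Rate of change** per evolutionary stage is `|Δvalue| / Δage` for
  consecutive groups, normalized by the sum over stages (flag for
  divide-by-max). The TG5→TG6 stage is excluded by default: its 40-Myr span
  makes the ratio numerically unstable.
- **ER comparison**: mean clustering against `G(n, m)` draws with matched
  node and edge counts, add-one permutation p-value.
- The degree-distribution slope is a least-squares fit on log-binned
  densities in log-log axes — a descriptive summary, not an exponent MLE; it
  carries a small (≈0.1–0.2) discreteness bias that the tests tolerate.

## Functional space

Genes are embedded as binary vectors over the **sub-root terms** (direct
is_a children of the `biological_process` or `molecular_function` root).
Each annotation is propagated up the is_a graph; a vector entry is 1 iff the
sub-root term is an ancestor-or-self of any annotation. GAF rows with a
`NOT` qualifier are dropped; evidence codes are not filtered; terms missing
from the ontology are skipped with a logged count.

The primary distance is **Mahalanobis**:
`d(x, y) = sqrt((x−y)ᵀ Σ⁻¹ (x−y))`, with Σ the term covariance estimated
over the full annotation universe (not just network genes, so the metric
does not depend on network membership). When Σ is singular a ridge of
`1e-6` is added to the diagonal before inversion, with a pseudoinverse
fallback; with identity covariance the distance reduces to Euclidean, which
the property tests exploit. Pairwise distances are computed blockwise via
the whitening decomposition of Σ⁻¹.

The alternative backend is a **Resnik** information-content distance:
`IC(t) = −log2 p(t)` with `p` the fraction of annotated genes hitting `t`
or a descendant; gene similarity is the maximum IC over the most informative
common ancestors of all term pairs, transformed to a distance by `(1/2)^sim`
(log base 2 matches the transform, so an identical single-term pair has
distance `2^−IC`). A vectorized path resolves gene pairs in descending
MICA-IC order.

Group-level structure:

- The **6×6 TG functional-distance matrix** averages pairwise distances per
  group pair (unordered pairs once, self-pairs excluded).
- The **dendrogram** clusters the off-diagonal cells with average linkage
  (UPGMA; single/complete via flag). The tree statistic is the summed
  cophenetic (along-tree) distance over the 15 leaf pairs. Significance
  comes from permuting the gene→TG labels (group sizes preserved),
  rebuilding the matrix and reclustering; because label permutation
  homogenizes every cell toward the grand-mean pairwise distance, genuine
  structure shows up as an *extreme* statistic on either side, so the
  add-one p-value is two-sided. (The summed merge heights, an alternative
  statistic, turned out to be nearly permutation-invariant and powerless;
  it is still reported.)
- The **functional-distance/age correlation** is Spearman's rho between the
  cells of the symmetric 6×6 matrix and the separation in group age *rank*
  (the six ages form an ordinal scale). Flags switch to upper-triangle-only
  cells and to age differences in Myr; the default full-matrix/rank reading
  reproduces the published value for the reference tables.
- The **profile of functional distance by network distance** averages
  functional distance per hop count (distances ≥ 8 pooled), with optional
  seeded pair subsampling for large networks.

## Hub coherence (the topological unit as functional unit)

A hub is a node with degree ≥ 50 on the human-scale network (on synthetic
data, the top 2% of degrees). Its **group distance** is the mean functional
distance over partner pairs from *different* temporal groups — restricting
to cross-group pairs removes the within-group similarity already
established by the age gradient. The empirical per-hub distribution is
compared against networks rewired by repeated double-edge swaps (default 10
attempted swaps per edge; degree sequence preserved exactly and asserted;
swap-acceptance logged when a graph is too constrained). Per-hub null
values from all replicates (default 20) are pooled; a per-replicate-mean
variant is available. Bias controls: drop partner pairs that are themselves
edges, and drop genes from multi-gene duplication clusters.

The **distance-2 baseline** compares hub partner-pair distances with all
pairs at network distance 2. Because pairs share genes, the iid standard
error is anti-conservative; the default SE is a leave-one-gene-out
jackknife of the mean difference, which restored nominal type-I rates in
the null calibration suite (the naive SE produced |Z| ≈ 4 on null data).

The **function-controlled correlation** recomputes Spearman's rho between a
node property and group index within each sub-root category (≥ 10 genes),
averages the per-category coefficients (unweighted; weighted via flag), and
tests them against the global coefficient with a one-sample t-test,
df = categories − 1. This construction reproduces the df pattern of
sub-root-level control and is an interpretation choice, flagged as such.

Enrichment uses the hypergeometric upper tail per (group, sub-root term)
with Benjamini–Hochberg correction within each group's family; background
defaults to network genes. Property-level enrichment uses
`z = (mean_cat − mean_all) / (sd_all / √n_cat)` with Gaussian two-sided p
and BH across categories.

## Synthetic-data generator

The generator emulates the study inputs with planted, tunable truth:

- **Network**: duplication–divergence growth from a 4-clique — duplicate a
  uniform node, keep each parent edge with `p_edge_retain = 0.45`, link to
  the template with `p_parent_link = 0.25`, gain `Poisson(0.1 × mean
  degree)` random edges — plus age-weighted triadic closure
  (`triangle_rate = 2` closures per step at nodes sampled by age) so that
  older proteins are both more connected and locally clustered. This yields
  heavy-tailed degrees (top-decile mean ≈ 4× median) and a negative
  birth-time/degree correlation. It does not reproduce the human network's
  exact degree exponent, density, or assortativity — recovery tests are
  about planted truth, not human-data replication.
- **Groups**: birth-order quantile cut into six equal groups; ages attached
  from the config (defaults mirror the six published ages).
- **Annotations**: a two-level toy ontology (one root, ~32 leaf terms).
  Each group term anchors at the oldest or newest group and is carried with
  probability `0.05 + 0.55·exp(−age_gradient·|group − home|)`
  (`age_gradient = 0.5`). Anchoring at the extremes keeps the six group
  profiles on a low-rank monotone gradient that survives Mahalanobis
  whitening; profiles with six cyclic home groups put the group means on a
  maximally-curved manifold whose whitened pairwise separations are
  equalized, erasing the age signal — a property of the metric worth
  remembering when interpreting real data. Two shared terms are carried by
  all genes.
- **Hub coherence**: each planted hub (top 2% by degree) draws a random
  ±`hub_tilt` (0.45) offset per term; each partner adopts the average tilt
  of its hubs with probability `hub_coherence` (0.8) on top of its own
  group profile. Partners of one hub therefore correlate — smaller mutual
  distances — while group-mean profiles stay unbiased, so the age gradient
  and the hub signal coexist. Rewiring destroys the co-location of
  same-tilt genes, which is what the group-distance test detects.
- **Hit tables**: every TG<6 gene gets one qualifying hit in its clade and
  a non-qualifying decoy in an older clade; TG6 genes only decoys — so
  assignment recovery is exact by construction and corruption experiments
  bound misassignment. Self-hits contain the *detectable* parent–child
  pairs (`p_dup_detect = 0.15` per duplication), and the truth record keeps
  exactly those edges, so duplication clusters equal the recorded parentage
  forest while staying realistically sparse (every non-seed node has a
  parent, so recording all parentage would collapse everything into one
  cluster).
- **Omega**: Gamma(shape 2) with mean `0.03 + 0.03·(group − 1)`.
- Setting `age_gradient = hub_coherence = omega_slope = 0` ablates all
  structure — the exact null used for type-I calibration.
- One seed drives everything; per-stage streams are derived by hashing
  `(seed, stage)` so each emitted file is independently reproducible.

What passing tests show — and do not show. The generator's annotations are
conditionally independent Bernoulli draws over a flat two-level ontology;
real GO annotations are deeper, sparser, strongly inter-dependent and
biased by study effort. Planted-truth recovery therefore validates the
*machinery* (estimators, tests, null constructions, calibration), not the
biological conclusions on real data. In particular the Resnik backend's age
correlation is weakly positive on synthetic data because a two-level
ontology gives the max-IC statistic little resolution.

## Problem sizes and numerics

Default analysis scale is n = 1000 genes; the test suite uses n = 240–1000
(calibration at 20 seeds × n = 240; flagship recovery at n = 1000) and the
acceptance script one n = 1000 study with 499 dendrogram permutations, 10
rewired replicates and 199 ER draws. Permutation p-values use the add-one
rule and are always in (0, 1]. Ties in all rank statistics use average
ranks. Degenerate inputs (empty groups, singleton-group densities,
unreachable pairs, zero-annotation genes) produce flagged missing values,
never silent zeros or infinities.

## Known limitations

- Cross-database identifier normalization is out of scope; the loader
  treats gene IDs as opaque strings and only cleans the graph (self-loops,
  duplicate and reversed edges counted).
- The published network's absolute magnitudes (node/edge counts, H
  statistics, hub counts) depend on a 2011-era database snapshot and are
  not reproducible from the bundled tables; the package recovers the
  printed group-level reconstructions and verifies directions and
  calibration on synthetic data instead.
- Mahalanobis whitening normalizes away dominant between-group variance
  directions (see above); with strongly age-structured annotation sets the
  functional gradient can be understated.
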