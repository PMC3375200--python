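"""Assign temporal groups from homology hits and summarize selection.

Reads the species hit table emitted by 01_simulate.py, classifies every
gene into one of six temporal groups by oldest-clade homology (e-value
threshold 1e-20), builds single-linkage duplication clusters from the human
self-hit table (threshold 1e-25) and tests the omega (Ka/Ks) gradient
across groups.
"""

import argparse
import json
from pathlib import Path

from netphylo.io import default_scheme, read_hit_table, read_omega_table
from netphylo.temporal import (assign_temporal_groups, build_duplication_clusters,
                               omega_by_group)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.parse_args()
    data = ROOT / "results" / "data"
    out = ROOT / "results"

    hits = read_hit_table(data / "hits_species.tsv", evalue_col=3, species_col=2)
    scheme = default_scheme()
    genes = set(hits["query"])
    groups = assign_temporal_groups(hits, scheme, genes=genes)
    with open(out / "groups.tsv", "w") as fh:
        for g in sorted(groups):
            fh.write(f"{g}\t{groups[g]}\n")
    sizes = {i: sum(1 for v in groups.values() if v == i) for i in range(1, 7)}
    print("temporal group sizes:", sizes)

    self_hits = read_hit_table(data / "hits_self.tsv", evalue_col=3, species_col=2)
    clusters = build_duplication_clusters(self_hits, 1e-25, genes=genes)
    n_dup = len(clusters.duplicated_genes())
    print(f"duplication clusters with >= 2 genes: "
          f"{sum(1 for c in clusters.clusters if len(c) >= 2)} "
          f"({n_dup} genes with detectable duplicates)")
    with open(out / "dup_clusters.tsv", "w") as fh:
        for i, c in enumerate(clusters.clusters):
            for g in sorted(c):
                fh.write(f"{g}\t{i}\n")

    omega = read_omega_table(data / "omega.tsv")
    res = omega_by_group(groups, omega)
    print(f"omega gradient: H = {res['H']:.2f}, df = {res['df']}, p = {res['p']:.3g}")
    print("  group means:", {k: round(v, 3) for k, v in sorted(res["means"].items())})
    (out / "omega_by_group.json").write_text(json.dumps(
        {"means": res["means"], "H": res["H"], "p": res["p"]}, indent=1))


if __name__ == "__main__":
    main()
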