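#!/usr/bin/env python
"""Gene-order comparison: inversion distances and conserved clusters.

Computes the all-pairs exact inversion distance matrix, the number of
conserved gene clusters across the whole genome set, and checks every
loss-free pair against the planted inversion count from the truth log
(the inferred distance can never exceed it).  Writes
results/distances.tsv.
"""

import itertools
import json
from pathlib import Path

from rhodoplast import genome_io
from rhodoplast.simulate import SimulationConfig, TruthLog, BranchRecord
from rhodoplast.synteny import (
    conserved_cluster_count,
    encode_permutation,
    inversion_distance,
    inversion_scenario,
    pairwise_distance_matrix,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def load_truth(path: Path) -> TruthLog:
    payload = json.loads(path.read_text())
    branches = {
        k: BranchRecord(
            inversions=[tuple(x) for x in b["inversions"]],
            losses=b["losses"],
            gains=[tuple(g) for g in b["gains"]],
            order_after=[tuple(e) for e in b["order_after"]],
            gene_events=b["gene_events"],
        )
        for k, b in payload["branches"].items()
    }
    return TruthLog(
        config=SimulationConfig(**payload["config"]),
        ancestral_order=[tuple(e) for e in payload["ancestral_order"]],
        branches=branches,
        parent=payload["parent"],
        leaf_keys=payload["leaf_keys"],
        gene_params=payload["gene_params"],
    )


def main() -> None:
    gdir = BASE / "synthetic"
    paths = sorted(gdir.glob("*.gbk"))
    if not paths:
        raise SystemExit("run analysis/01_simulate.py first")
    records = [
        genome_io.normalize_gene_names(genome_io.read_genbank_file(p)) for p in paths
    ]
    truth = load_truth(gdir / "truth.json")

    dmat = pairwise_distance_matrix(records)
    dmat.to_csv(BASE / "distances.tsv", sep="\t")
    print("pairwise inversion distances:")
    print(dmat.to_string())
    print(f"\nconserved gene clusters across all genomes: "
          f"{conserved_cluster_count(records)}")

    by_id = {r.taxon_id: r for r in records}
    exact = checked = 0
    for a, b in itertools.combinations(sorted(by_id), 2):
        path = truth.path_branches(a, b)
        if any(truth.branches[k].losses for k in path):
            continue
        planted = truth.planted_inversions_between(a, b)
        d = inversion_distance(encode_permutation(by_id[a], by_id[b]))
        assert d <= planted, (a, b)
        checked += 1
        exact += d == planted
    if checked:
        print(f"loss-free pairs where inferred distance equals planted count: "
              f"{exact}/{checked}")

    a, b = "Porphyra", "Chondrus"
    scen = inversion_scenario(encode_permutation(by_id[a], by_id[b]))
    print(f"\nexample optimal scenario {a} -> {b}: {scen.distance} reversals "
          f"{list(scen.reversals)}")


if __name__ == "__main__":
    main()
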