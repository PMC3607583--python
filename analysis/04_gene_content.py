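#!/usr/bin/env python
"""Gene content: shared-gene partitions and parsimony loss/gain mapping.

Builds the presence matrix over the synthetic genomes, counts genes of
cyanobacterial descent shared among the three major lineage groups
(Venn partition), and maps losses and gains onto the species tree:
Dollo parsimony for ancestral genes, single-gain parsimony for the
planted acquisitions (the maturase-like ORF and the leuC/leuD operon).
Writes results/presence_matrix.tsv, results/partitions.tsv, and
results/events.json.
"""

from pathlib import Path

from rhodoplast import genome_io
from rhodoplast.gene_content import (
    annotated_newick,
    build_presence_matrix,
    default_tree,
    map_events,
    partition_counts,
)

BASE = Path(__file__).resolve().parent.parent / "results"

GROUPS = {
    "Porphyra": "Bangiales",
    "Pyropia": "Bangiales",
    "Calliarthron": "florideophytes",
    "Chondrus": "florideophytes",
    "Cruoria": "florideophytes",
    "Gracilaria": "florideophytes",
    "Grateloupia": "florideophytes",
    "Cyanidium": "Cyanidiales",
    "Cyanidioschyzon": "Cyanidiales",
}


def main() -> None:
    gdir = BASE / "synthetic"
    paths = sorted(gdir.glob("*.gbk"))
    if not paths:
        raise SystemExit("run analysis/01_simulate.py first")
    records = [
        genome_io.normalize_gene_names(genome_io.read_genbank_file(p)) for p in paths
    ]
    matrix = build_presence_matrix(records)
    matrix.occupancy.to_csv(BASE / "presence_matrix.tsv", sep="\t")

    partitions = partition_counts(matrix, GROUPS)
    with open(BASE / "partitions.tsv", "w") as fh:
        fh.write("region\tcount\n")
        for k in sorted(partitions):
            fh.write(f"{k}\t{partitions[k]}\n")
    print("cyanobacterial genes by lineage partition:")
    for k in sorted(partitions):
        if partitions[k]:
            print(f"  {k}: {partitions[k]}")

    tree = default_tree()
    events = map_events(matrix, tree)
    (BASE / "events.json").write_text(events.to_json())
    (BASE / "events.nwk").write_text(annotated_newick(events, tree))
    print(f"\nparsimony mapping: {events.loss_count()} losses, "
          f"{events.gain_count()} gains")
    gains = {g: k for k, genes in events.gains.items() for g in genes}
    for gene, branch in sorted(gains.items()):
        print(f"  gain of {gene} on branch to [{branch}]")


if __name__ == "__main__":
    main()
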