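"""Shared fixtures: handcrafted genomes, BFS oracle caches, small
simulated datasets.  Everything is generated programmatically."""

from __future__ import annotations

from collections import deque
from functools import lru_cache

import pytest

from rhodoplast.genome_io import GeneFeature, GenomeRecord
from rhodoplast.simulate import SimulationConfig, simulate_dataset


def make_record(
    taxon: str,
    genes: list[tuple[str, str]],
    gene_len: int = 30,
    spacer: int = 10,
    topology: str = "circular",
    sequence: bool = True,
) -> GenomeRecord:
    """A toy annotated genome from (gene, strand) pairs, evenly spaced."""
    features = []
    pos = spacer
    parts = ["A" * spacer]
    for name, strand in genes:
        features.append(
            GeneFeature(
                canonical_name=name,
                raw_name=name,
                feature_class="ORF" if name.lower().startswith("orf") else "protein",
                start=pos,
                end=pos + gene_len,
                strand=strand,
            )
        )
        parts.append("ATG" * (gene_len // 3))
        parts.append("A" * spacer)
        pos += gene_len + spacer
    seq = "".join(parts)
    return GenomeRecord(
        taxon_id=taxon,
        length=len(seq),
        topology=topology,
        sequence=seq if sequence else None,
        features=features,
    )


@lru_cache(maxsize=8)
def bfs_reversal_distances(n: int) -> dict[tuple[int, ...], int]:
    """Exact reversal distances for every signed permutation of 1..n,
    by breadth-first search of the full reversal graph (test oracle,
    independent of the production solver)."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    queue = deque([ident])
    while queue:
        cur = queue.popleft()
        d = dist[cur]
        for i in range(n):
            for j in range(i, n):
                nxt = (
                    cur[:i]
                    + tuple(-e for e in reversed(cur[i : j + 1]))
                    + cur[j + 1 :]
                )
                if nxt not in dist:
                    dist[nxt] = d + 1
                    queue.append(nxt)
    return dist


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across tests (fixed seed)."""
    config = SimulationConfig(seed=11, ancestral_gene_count=20)
    return simulate_dataset(config)


MINIMAL_GENBANK = """\
LOCUS       TOYPLAST                 300 bp    DNA     circular PLN 01-JAN-2000
DEFINITION  Toy plastid fragment.
ACCESSION   TOYPLAST
FEATURES             Location/Qualifiers
     source          1..300
     CDS             11..40
                     /gene="rbcL"
     CDS             complement(101..130)
                     /gene="psbA"
     CDS             join(281..300,1..10)
                     /gene="atpA"
ORIGIN
        1 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
       61 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
      121 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
      181 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
      241 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
//
"""


@pytest.fixture()
def minimal_genbank_text() -> str:
    return MINIMAL_GENBANK
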