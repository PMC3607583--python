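"""Genetic codes, codon alignments, and back-translation.

Pairwise rate estimation works on codon-synchronised nucleotide
alignments.  Protein-coding genes are aligned at the amino-acid level
and the alignment is back-translated onto the unaligned CDS, expanding
each residue to its source codon and each gap to a triplet gap.

Two genetic codes matter for the red algal marker set: the standard
(plastid) code, and the 'mold, protozoan, and coelenterate'
mitochondrial code used for the mitochondrial barcoding marker cox1
(NCBI translation tables 1 and 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Data import CodonTable

BASES = "TCAG"
GAP_CODON = "---"


class CodonError(ValueError):
    pass


@dataclass(frozen=True)
class GeneticCode:
    """A codon → amino-acid table with its stop set."""

    name: str
    table: Mapping[str, str]
    stops: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.table) + len(self.stops) != 64:
            raise ValueError("genetic code must cover all 64 codons")

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            name=t.names[0] if t.names else str(table_id),
            table=dict(t.forward_table),
            stops=frozenset(t.stop_codons),
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        """NCBI table 1, used for plastid genes."""
        return cls.from_ncbi_id(1)

    @classmethod
    def mold_mito(cls) -> "GeneticCode":
        """NCBI table 4 ('mold, protozoan, and coelenterate'
        mitochondrial), used for cox1."""
        return cls.from_ncbi_id(4)

    @classmethod
    def by_name(cls, name: str) -> "GeneticCode":
        key = name.lower().replace("-", "_")
        if key in ("standard", "plastid", "1"):
            return cls.standard()
        if key in ("mold_mito", "mold", "mold_mitochondrial", "4"):
            return cls.mold_mito()
        raise CodonError(f"unknown genetic code {name!r}")

    def translate(self, cds: str) -> str:
        if len(cds) % 3:
            raise CodonError(f"CDS length {len(cds)} not divisible by 3")
        aas = []
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3].upper()
            if codon in self.stops:
                aas.append("*")
            elif codon in self.table:
                aas.append(self.table[codon])
            else:
                aas.append("X")
        return "".join(aas)

    def sense_codons(self) -> list[str]:
        return sorted(self.table.keys())

    def is_synonymous(self, a: str, b: str) -> bool:
        return self.table.get(a) == self.table.get(b)


@dataclass
class CodonAlignment:
    """Codon-synchronised aligned CDS for one gene.

    All rows have equal length divisible by 3; ungapped rows contain no
    internal stop codons.
    """

    gene: str
    sequences: dict[str, str]
    code: GeneticCode = field(default_factory=GeneticCode.standard)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise CodonError(f"{self.gene}: unequal aligned lengths {lengths}")
        if lengths and next(iter(lengths)) % 3:
            raise CodonError(f"{self.gene}: aligned length not divisible by 3")
        for taxon, seq in self.sequences.items():
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3].upper()
                if codon in self.code.stops and i + 3 < len(seq):
                    raise CodonError(
                        f"{self.gene}/{taxon}: internal stop codon {codon} at "
                        f"codon {i // 3}"
                    )

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def pair_codons(self, a: str, b: str) -> list[tuple[str, str]]:
        """Codon columns for a taxon pair, skipping gapped/ambiguous ones."""
        sa, sb = self.sequences[a].upper(), self.sequences[b].upper()
        out = []
        valid = set("ACGT")
        for i in range(0, len(sa), 3):
            ca, cb = sa[i : i + 3], sb[i : i + 3]
            if set(ca) <= valid and set(cb) <= valid:
                out.append((ca, cb))
        return out

    def ungapped_length(self, taxon: str) -> int:
        return sum(3 for i in range(0, len(self.sequences[taxon]), 3)
                   if self.sequences[taxon][i : i + 3] != GAP_CODON)


def backtranslate(
    protein_alignment: Mapping[str, str],
    cds: Mapping[str, str],
    code: GeneticCode | None = None,
    gene: str = "",
) -> CodonAlignment:
    """Thread unaligned CDS onto an amino-acid alignment.

    Each amino-acid column becomes a codon column; gaps expand to
    triplet gaps.  Every CDS must translate exactly to its ungapped
    protein row (a terminal stop codon is trimmed first).
    """
    code = code or GeneticCode.standard()
    aligned: dict[str, str] = {}
    for taxon, prot in protein_alignment.items():
        if taxon not in cds:
            raise CodonError(f"{gene}: no CDS for taxon {taxon!r}")
        nt = cds[taxon].upper().replace("U", "T")
        if len(nt) % 3:
            raise CodonError(f"{gene}/{taxon}: CDS length not divisible by 3")
        if nt[-3:] in code.stops:
            nt = nt[:-3]
        translated = code.translate(nt)
        ungapped = prot.replace("-", "")
        if translated != ungapped:
            k = next(
                (i for i, (x, y) in enumerate(zip(translated, ungapped)) if x != y),
                min(len(translated), len(ungapped)),
            )
            raise CodonError(
                f"{gene}/{taxon}: translation disagrees with protein row at "
                f"position {k} ({translated[k:k+1] or '?'} vs {ungapped[k:k+1] or '?'})"
            )
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        row = []
        ci = 0
        for aa in prot:
            if aa == "-":
                row.append(GAP_CODON)
            else:
                row.append(codons[ci])
                ci += 1
        aligned[taxon] = "".join(row)
    return CodonAlignment(gene=gene, sequences=aligned, code=code)


def degap_pair(a: Sequence[str], b: Sequence[str]) -> list[tuple[str, str]]:
    """Utility: paired codon lists with gap/ambiguity columns removed."""
    valid = set("ACGT")
    return [
        (ca, cb)
        for ca, cb in zip(a, b)
        if set(ca.upper()) <= valid and set(cb.upper()) <= valid
    ]
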