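"""Annotated genome I/O and per-genome architecture statistics.

Plastid genomes are distributed as annotated GenBank flat files.  This
module reads them into a light-weight :class:`GenomeRecord`, normalises
gene identities against a synonym table (a precondition for every
cross-genome comparison), and computes the architecture statistics used
to characterise genome compaction: intergenic spacer medians/means, GC
content overall and per feature class, gene counts, and coding density.

Coordinates are converted from GenBank's 1-based inclusive convention to
0-based half-open on input; all internal arithmetic is half-open, which
removes the usual off-by-one ambiguity in gap lengths.  Features that
span the origin of a circular chromosome are kept as a single feature
with ``wraps_origin=True`` (their stored ``end`` is the post-wrap
coordinate and is smaller than ``start``).
"""

from __future__ import annotations

import io
import logging
import re
import statistics
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Annotation categories recognised in feature tables.
FEATURE_CLASSES = ("protein", "rRNA", "tRNA", "smallRNA", "ORF", "intron")

_GENBANK_TYPE_TO_CLASS = {
    "CDS": "protein",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "ncRNA": "smallRNA",
    "misc_RNA": "smallRNA",
    "tmRNA": "smallRNA",
    "intron": "intron",
}

_CLASS_TO_GENBANK_TYPE = {
    "protein": "CDS",
    "ORF": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "smallRNA": "ncRNA",
    "intron": "intron",
}

_ORF_RE = re.compile(r"^orf[_-]?\d+[a-z]?$", re.IGNORECASE)


class GenomeIOError(ValueError):
    """Raised for malformed GenBank input or invalid statistic requests."""


@dataclass(frozen=True)
class GeneFeature:
    """One strand-aware annotated feature on a genome.

    ``start``/``end`` are 0-based half-open.  For origin-spanning
    features on circular genomes ``wraps_origin`` is true and ``end``
    (the coordinate where the feature stops after the wrap) is smaller
    than ``start``.
    """

    canonical_name: str
    raw_name: str
    feature_class: str
    start: int
    end: int
    strand: str
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.wraps_origin and not self.start < self.end:
            raise ValueError(
                f"feature {self.raw_name!r}: start {self.start} must be < end "
                f"{self.end} unless the feature wraps the origin"
            )

    def span(self, genome_length: int) -> int:
        """Feature length in bp, accounting for origin wrap."""
        if self.wraps_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A circular or linear annotated genome.

    ``sequence`` may be ``None`` for gene-order-only records (e.g. plain
    gene-order text files); statistics that need nucleotides then raise.
    Features are kept sorted by ``start``.
    """

    taxon_id: str
    length: int
    topology: str = "circular"
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular/linear, got {self.topology!r}")
        for f in self.features:
            if f.start >= self.length or f.end > self.length:
                raise ValueError(
                    f"{self.taxon_id}: feature {f.raw_name!r} exceeds genome "
                    f"length {self.length}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.taxon_id}: sequence length {len(self.sequence)} != "
                f"declared length {self.length}"
            )

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Nucleotide sequence of a feature on its coding strand."""
        if self.sequence is None:
            raise GenomeIOError(f"{self.taxon_id}: record has no sequence")
        if feat.wraps_origin:
            nt = self.sequence[feat.start :] + self.sequence[: feat.end]
        else:
            nt = self.sequence[feat.start : feat.end]
        if feat.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        return nt


@dataclass
class GenomeStats:
    """Per-genome architecture statistics (one Table-style row)."""

    taxon_id: str
    length: int
    total_gc_percent: float
    unique_gene_count: int
    class_counts: dict[str, int]
    class_gc_percent: dict[str, float]
    species_specific_orf_count: int | None
    median_intergenic_bp: float
    mean_intergenic_bp: float
    coding_density_fraction: float


def _feature_name(feat: SeqFeature) -> str:
    q = feat.qualifiers
    for key in ("gene", "locus_tag", "product", "note"):
        if key in q and q[key]:
            return str(q[key][0])
    return f"{feat.type}_{int(feat.location.start)}"


def _to_gene_feature(feat: SeqFeature, genome_length: int, circular: bool) -> GeneFeature:
    name = _feature_name(feat)
    fclass = _GENBANK_TYPE_TO_CLASS[feat.type]
    if fclass == "protein" and _ORF_RE.match(name):
        fclass = "ORF"
    strand = "-" if feat.location.strand == -1 else "+"
    loc = feat.location
    wraps = False
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        start, end = int(parts[0].start), int(parts[-1].end)
        if circular and int(parts[-1].end) == genome_length and int(parts[0].start) == 0:
            # join(x..length,1..y): one biological feature across the origin
            wraps = True
            interior = [p for p in loc.parts]
            start = min(int(p.start) for p in interior if int(p.end) == genome_length)
            end = max(int(p.end) for p in interior if int(p.start) == 0)
    else:
        start, end = int(loc.start), int(loc.end)
    return GeneFeature(
        canonical_name=name,
        raw_name=name,
        feature_class=fclass,
        start=start,
        end=end,
        strand=strand,
        wraps_origin=wraps,
    )


def parse_genbank(text: str) -> GenomeRecord:
    """Parse one GenBank flat-file record into a :class:`GenomeRecord`.

    Every CDS/rRNA/tRNA/ncRNA/misc_RNA/tmRNA/intron feature becomes one
    :class:`GeneFeature`; bare ``gene`` features are skipped to avoid
    double-counting their product features.  Compound locations that
    span the origin of a circular record collapse to one feature with
    ``wraps_origin=True``.
    """
    try:
        rec = SeqIO.read(io.StringIO(text), "genbank")
    except ValueError as exc:
        raise GenomeIOError(f"malformed GenBank record: {exc}") from exc
    if not rec.seq or len(rec.seq) == 0:
        # gene-order-only records still need a declared LOCUS length
        length = len(rec)
        if length == 0:
            raise GenomeIOError("missing LOCUS length")
    length = len(rec)
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    features = []
    for feat in rec.features:
        if feat.type not in _GENBANK_TYPE_TO_CLASS:
            continue
        try:
            features.append(_to_gene_feature(feat, length, topology == "circular"))
        except ValueError as exc:
            raise GenomeIOError(
                f"malformed feature location for {_feature_name(feat)!r}: {exc}"
            ) from exc
    sequence = str(rec.seq).upper()
    if set(sequence) <= {"N"} and len(set(sequence)) <= 1 and sequence:
        sequence_or_none: str | None = None
    else:
        sequence_or_none = sequence or None
    return GenomeRecord(
        taxon_id=rec.name or rec.id,
        length=length,
        topology=topology,
        sequence=sequence_or_none,
        features=features,
    )


def read_genbank_file(path: str | Path) -> GenomeRecord:
    return parse_genbank(Path(path).read_text())


def write_genbank(record: GenomeRecord) -> str:
    """Serialise a :class:`GenomeRecord` back to GenBank flat-file text."""
    seq = Seq(record.sequence if record.sequence is not None else "N" * record.length)
    rec = SeqRecord(seq, id=record.taxon_id, name=record.taxon_id, description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps_origin:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start, record.length, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        sf = SeqFeature(loc, type=_CLASS_TO_GENBANK_TYPE[f.feature_class])
        sf.qualifiers["gene"] = [f.raw_name]
        rec.features.append(sf)
    out = io.StringIO()
    SeqIO.write(rec, out, "genbank")
    return out.getvalue()


def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Load a raw→canonical gene-name table (tab-separated, ``#`` comments).

    With no argument the packaged default table is used; it covers tRNA
    naming variants (anticodon suffixes), ycf numbering/case variants,
    and common plastid gene symbols.  A raw name claimed by two
    different canonical names is a configuration error.
    """
    if path is None:
        text = resources.files("rhodoplast.data").joinpath("synonyms.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise GenomeIOError(f"synonyms line {lineno}: expected 2 columns")
        raw, canonical = parts[0].strip(), parts[1].strip()
        if raw in table and table[raw] != canonical:
            raise GenomeIOError(
                f"synonyms: raw name {raw!r} mapped to both {table[raw]!r} "
                f"and {canonical!r}"
            )
        table[raw] = canonical
    return table


def normalize_gene_names(
    record: GenomeRecord, synonyms: Mapping[str, str] | None = None
) -> GenomeRecord:
    """Return a copy of *record* with canonical gene names set.

    Lookup is exact first, then case-insensitive.  ORF-like names are
    forced to feature class ``ORF`` and canonicalised to ``orfNNN``.
    Unmapped raw names pass through lower-cased with a logged warning.
    """
    if synonyms is None:
        synonyms = load_synonyms()
    folded = {k.lower(): v for k, v in synonyms.items()}
    new_features = []
    for f in record.features:
        raw = f.raw_name
        fclass = f.feature_class
        if _ORF_RE.match(raw):
            canonical = raw.lower().replace("-", "").replace("_", "")
            if fclass == "protein":
                fclass = "ORF"
        elif raw in synonyms:
            canonical = synonyms[raw]
        elif raw.lower() in folded:
            canonical = folded[raw.lower()]
        else:
            canonical = raw.lower()
            if canonical != raw:
                logger.warning(
                    "%s: no synonym entry for %r; using %r",
                    record.taxon_id,
                    raw,
                    canonical,
                )
        new_features.append(replace(f, canonical_name=canonical, feature_class=fclass))
    return GenomeRecord(
        taxon_id=record.taxon_id,
        length=record.length,
        topology=record.topology,
        sequence=record.sequence,
        features=new_features,
    )


def _gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    gc = sum(seq.count(b) for b in "GCgc")
    acgt = sum(seq.count(b) for b in "ACGTacgt")
    return 100.0 * gc / acgt if acgt else 0.0


def intergenic_lengths(record: GenomeRecord) -> list[float]:
    """Spacer lengths between consecutive features in genomic order.

    Intron features are excluded (a gene with an intron is one span from
    its outermost boundaries, which the parsed feature already is).
    Overlapping features contribute a spacer of 0.  On circular records
    the wrap-around gap is included; an origin-spanning feature anchors
    both ends of the circle.
    """
    feats = [f for f in record.features if f.feature_class != "intron"]
    if len(feats) < 2:
        return []
    wrap = [f for f in feats if f.wraps_origin]
    plain = sorted((f for f in feats if not f.wraps_origin), key=lambda f: f.start)
    gaps: list[float] = []
    for prev, nxt in zip(plain, plain[1:]):
        gaps.append(max(0, nxt.start - prev.end))
    if record.topology == "circular":
        if wrap:
            # at most one wrapping feature is meaningful for spacer stats
            w = wrap[0]
            gaps.append(max(0, plain[0].start - w.end))
            gaps.append(max(0, w.start - plain[-1].end))
        else:
            gaps.append(max(0, (record.length - plain[-1].end) + plain[0].start))
    return gaps


def _coverage(record: GenomeRecord, classes: Iterable[str] | None = None) -> int:
    """Number of positions covered by at least one (non-intron) feature."""
    mask = bytearray(record.length)
    for f in record.features:
        if f.feature_class == "intron":
            continue
        if classes is not None and f.feature_class not in classes:
            continue
        if f.wraps_origin:
            for i in range(f.start, record.length):
                mask[i] = 1
            for i in range(f.end):
                mask[i] = 1
        else:
            for i in range(f.start, f.end):
                mask[i] = 1
    return sum(mask)


def genome_stats(
    record: GenomeRecord, species_specific_orf_count: int | None = None
) -> GenomeStats:
    """Compute architecture statistics for one genome.

    Multi-copy genes (e.g. duplicated rRNA operon genes) count once in
    ``unique_gene_count``.  GC is computed over the whole sequence and
    per concatenated feature class.  ``species_specific_orf_count``
    requires the full genome set (shared-ORF detection) and is injected
    by the gene-content stage; it is ``None`` when unknown.

    Raises :class:`GenomeIOError` if sequence-based statistics are
    requested on a gene-order-only record.
    """
    if record.sequence is None:
        raise GenomeIOError(
            f"{record.taxon_id}: no sequence; cannot compute GC/coding density"
        )
    non_intron = [f for f in record.features if f.feature_class != "intron"]
    unique = {f.canonical_name for f in non_intron}
    class_counts: dict[str, int] = {c: 0 for c in FEATURE_CLASSES}
    class_seqs: dict[str, list[str]] = {c: [] for c in FEATURE_CLASSES}
    seen_per_class: dict[str, set[str]] = {c: set() for c in FEATURE_CLASSES}
    for f in record.features:
        if f.canonical_name not in seen_per_class[f.feature_class]:
            seen_per_class[f.feature_class].add(f.canonical_name)
            if f.feature_class != "intron":
                class_counts[f.feature_class] += 1
        if f.feature_class == "intron":
            class_counts["intron"] += 1
        class_seqs[f.feature_class].append(record.feature_sequence(f))
    gaps = intergenic_lengths(record)
    return GenomeStats(
        taxon_id=record.taxon_id,
        length=record.length,
        total_gc_percent=_gc_percent(record.sequence),
        unique_gene_count=len(unique),
        class_counts=class_counts,
        class_gc_percent={
            c: _gc_percent("".join(seqs)) for c, seqs in class_seqs.items() if seqs
        },
        species_specific_orf_count=species_specific_orf_count,
        median_intergenic_bp=float(statistics.median(gaps)) if gaps else 0.0,
        mean_intergenic_bp=float(statistics.mean(gaps)) if gaps else 0.0,
        coding_density_fraction=_coverage(record) / record.length,
    )


def stats_table(stats: Iterable[GenomeStats]) -> "pandas.DataFrame":  # noqa: F821
    """Assemble per-genome stats into a tidy table (one row per genome)."""
    import pandas as pd

    rows = []
    for s in stats:
        row = {
            "taxon": s.taxon_id,
            "total_length_bp": s.length,
            "total_gc_percent": round(s.total_gc_percent, 1),
            "unique_genes": s.unique_gene_count,
            "protein_coding": s.class_counts.get("protein", 0),
            "unknown_orfs": s.class_counts.get("ORF", 0),
            "species_specific_orfs": s.species_specific_orf_count,
            "rrna_genes": s.class_counts.get("rRNA", 0),
            "trna_genes": s.class_counts.get("tRNA", 0),
            "small_rna_genes": s.class_counts.get("smallRNA", 0),
            "introns": s.class_counts.get("intron", 0),
            "median_intergenic_bp": s.median_intergenic_bp,
            "mean_intergenic_bp": round(s.mean_intergenic_bp, 1),
            "coding_density": round(s.coding_density_fraction, 3),
        }
        rows.append(row)
    return pd.DataFrame(rows)
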