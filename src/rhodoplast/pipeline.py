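"""End-to-end pipeline wiring: inventory → synteny → gene content →
rates → marker classification.

`run_pipeline` drives every stage over a directory of annotated GenBank
genomes (real or simulated), writing per-stage tables under an output
prefix plus a machine-readable summary JSON of all headline statistics
and a short human-readable report.  Stage failures surface as
:class:`StageError` naming the stage; configuration problems are
detected up front as :class:`ValidationError` before any stage runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from rhodoplast import genome_io, synteny, gene_content, rates as rates_mod
from rhodoplast.codon import CodonAlignment, CodonError, GeneticCode

logger = logging.getLogger("rhodoplast.pipeline")


class ValidationError(ValueError):
    """Configuration invalid; nothing has run."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated inputs for one pipeline run."""

    genbank_dir: str | Path
    out_prefix: str | Path
    tree_path: str | Path | None = None
    synonyms_path: str | Path | None = None
    groups: Mapping[str, str] | None = None
    rates_taxa: Sequence[str] | None = None
    method: str = "ml"
    min_taxa: int = 3
    genetic_code: str = "standard"
    seed: int = 0
    max_blocks: int = synteny.MAX_EXACT_BLOCKS

    def validate(self) -> None:
        if not Path(self.genbank_dir).is_dir():
            raise ValidationError(f"genbank dir not found: {self.genbank_dir}")
        if not any(Path(self.genbank_dir).glob("*.gb*")):
            raise ValidationError(f"no GenBank files under {self.genbank_dir}")
        if self.tree_path is not None and not Path(self.tree_path).exists():
            raise ValidationError(f"tree file not found: {self.tree_path}")
        if self.synonyms_path is not None and not Path(self.synonyms_path).exists():
            raise ValidationError(f"synonyms file not found: {self.synonyms_path}")
        if self.method.lower() not in ("ml", "ng86"):
            raise ValidationError(f"unknown rates method {self.method!r}")
        Path(self.out_prefix).parent.mkdir(parents=True, exist_ok=True)


def _identity_protein_alignment(cds: Mapping[str, str], code: GeneticCode) -> dict[str, str]:
    """Deterministic fallback aligner: equal-length CDS align trivially.

    Real datasets with indels need an external protein alignment; the
    synthetic generator produces none, so identity is exact there.
    """
    prots = {}
    for taxon, nt in cds.items():
        nt = nt.upper()
        if nt[-3:] in code.stops:
            nt = nt[:-3]
        prots[taxon] = code.translate(nt)
    lengths = {len(p) for p in prots.values()}
    if len(lengths) > 1:
        raise CodonError(
            f"unequal protein lengths {sorted(lengths)}; supply a protein alignment"
        )
    return prots


def extract_cds(records: Sequence[genome_io.GenomeRecord]) -> dict[str, dict[str, str]]:
    """Per-gene CDS sets from annotated genomes (single-copy protein and
    ORF features with sequence)."""
    cds: dict[str, dict[str, str]] = {}
    for rec in records:
        seen: dict[str, int] = {}
        for f in rec.features:
            if f.feature_class not in ("protein", "ORF"):
                continue
            seen[f.canonical_name] = seen.get(f.canonical_name, 0) + 1
        for f in rec.features:
            if f.feature_class not in ("protein", "ORF"):
                continue
            if seen[f.canonical_name] != 1:
                continue
            nt = rec.feature_sequence(f)
            if len(nt) % 3 == 0:
                cds.setdefault(f.canonical_name, {})[rec.taxon_id] = nt
    return cds


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to
    ``<out_prefix>.summary.json``)."""
    config.validate()
    t0 = time.time()
    prefix = str(config.out_prefix)
    summary: dict = {"stages": {}}

    # --- inventory -------------------------------------------------------
    try:
        synonyms = (
            genome_io.load_synonyms(config.synonyms_path)
            if config.synonyms_path
            else genome_io.load_synonyms()
        )
        paths = sorted(Path(config.genbank_dir).glob("*.gb*"))
        records = [
            genome_io.normalize_gene_names(genome_io.read_genbank_file(p), synonyms)
            for p in paths
        ]
        matrix = gene_content.build_presence_matrix(records)
        orf_counts = matrix.species_specific_orf_counts()
        stats = [
            genome_io.genome_stats(r, species_specific_orf_count=orf_counts[r.taxon_id])
            for r in records
        ]
        table = genome_io.stats_table(stats)
        table.to_csv(f"{prefix}.stats.tsv", sep="\t", index=False)
        summary["stages"]["inventory"] = {
            "n_genomes": len(records),
            "median_intergenic_bp": {
                s.taxon_id: s.median_intergenic_bp for s in stats
            },
            "unique_genes": {s.taxon_id: s.unique_gene_count for s in stats},
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("inventory", exc) from exc

    # --- synteny ---------------------------------------------------------
    try:
        dmat = synteny.pairwise_distance_matrix(records, config.max_blocks)
        dmat.to_csv(f"{prefix}.distances.tsv", sep="\t")
        clusters = synteny.conserved_cluster_count(records)
        summary["stages"]["synteny"] = {
            "max_pairwise_inversion_distance": int(dmat.values.max()),
            "conserved_cluster_count": int(clusters),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("synteny", exc) from exc

    # --- gene content ----------------------------------------------------
    try:
        tree = (
            gene_content.load_tree(config.tree_path)
            if config.tree_path
            else gene_content.default_tree()
        )
        groups = dict(config.groups) if config.groups else {t: "all" for t in matrix.taxa}
        partitions = gene_content.partition_counts(matrix, groups)
        with open(f"{prefix}.partitions.tsv", "w") as fh:
            fh.write("region\tcount\n")
            for k in sorted(partitions):
                fh.write(f"{k}\t{partitions[k]}\n")
        events = gene_content.map_events(matrix, tree)
        Path(f"{prefix}.events.json").write_text(events.to_json())
        summary["stages"]["gene_content"] = {
            "cyanobacterial_union": partitions["union"],
            "total_losses": events.loss_count(),
            "total_gains": events.gain_count(),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("gene_content", exc) from exc

    # --- rates -----------------------------------------------------------
    try:
        code = GeneticCode.by_name(config.genetic_code)
        rates_taxa = (
            list(config.rates_taxa) if config.rates_taxa else list(matrix.taxa)
        )
        selected = rates_mod.select_genes(matrix, config.min_taxa, taxa=rates_taxa)
        cds_sets = extract_cds(records)
        all_rates = []
        summaries = []
        for gene in selected:
            cds = {
                t: s for t, s in cds_sets.get(gene, {}).items() if t in rates_taxa
            }
            if len(cds) < 2:
                continue
            prots = _identity_protein_alignment(cds, code)
            aln = _codon_alignment_from_cds(gene, cds, prots, code)
            pr = rates_mod.pairwise_rates(aln, method=config.method)
            all_rates.extend(pr)
            length = max(aln.ungapped_length(t) for t in aln.taxa)
            summaries.append(rates_mod.gene_summary(pr, length_nt=length))
        rates_mod.rates_table(all_rates).to_csv(
            f"{prefix}.rates.tsv", sep="\t", index=False
        )
        rates_mod.summaries_table(summaries).to_csv(
            f"{prefix}.summaries.tsv", sep="\t", index=False
        )
        corr = rates_mod.dn_iqr_correlation(summaries)
        summary["stages"]["rates"] = {
            "n_genes": len(summaries),
            "n_pairs": rates_mod.total_pair_count(summaries),
            "dn_iqr_r_raw": round(corr["r_raw"], 4),
            "dn_iqr_r_log2": round(corr["r_log2"], 4),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("rates", exc) from exc

    # --- classification --------------------------------------------------
    try:
        classes = rates_mod.classify_markers(summaries, total_taxa=len(rates_taxa))
        rates_mod.classification_table(classes).to_csv(
            f"{prefix}.markers.tsv", sep="\t", index=False
        )
        summary["stages"]["classify"] = {
            "n_candidates": sum(c.candidate for c in classes),
            "n_unsuitable": sum(c.unsuitable for c in classes),
            "n_deep_tier": sum(c.deep_phylogeny_tier for c in classes),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    summary["elapsed_s"] = round(time.time() - t0, 1)
    Path(f"{prefix}.summary.json").write_text(
        json.dumps({k: v for k, v in summary.items() if k != "elapsed_s"},
                   indent=1, sort_keys=True)
    )
    _write_report(prefix, summary)
    return summary


def _codon_alignment_from_cds(
    gene: str, cds: Mapping[str, str], prots: Mapping[str, str], code: GeneticCode
) -> CodonAlignment:
    from rhodoplast.codon import backtranslate

    return backtranslate(prots, cds, code=code, gene=gene)


def _write_report(prefix: str, summary: dict) -> None:
    lines = ["rhodoplast pipeline report", "=" * 26, ""]
    for stage, payload in summary["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in payload.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    Path(f"{prefix}.report.txt").write_text("\n".join(lines))
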