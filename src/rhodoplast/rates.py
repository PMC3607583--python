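"""Gene evolutionary-rate summaries and barcoding-marker classification.

For every selected protein-coding gene, pairwise nonsynonymous rates
(dN) are estimated between all taxon pairs carrying the gene, then
summarised as a median and interquartile range (IQR).  dN serves as a
proxy for overall gene divergence (synonymous sites are saturated at
these evolutionary distances), and the IQR as a dispersion proxy: a
large IQR means unequal rates among species, an undesirable property
for a barcoding or phylogenetic marker.

Genes are then binned by median dN and, within each bin, ranked into
LOW/MEDIUM/HIGH relative-IQR tertiles.  The most reliable barcoding
candidates are restricted to the lowest IQR category, low-to-medium dN
(0.1–0.4), length over 300 nucleotides, and presence in all taxa; genes
below dN 0.1 that otherwise qualify are flagged as the deep-phylogeny
tier (better suited to resolving higher-level relationships than to
discriminating close species).

Quantiles use linear interpolation between order statistics (the
convention where {1,2,3,4} gives Q1 = 1.75, Q3 = 3.25).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from rhodoplast.codon import CodonAlignment
from rhodoplast.dnds import PairwiseRate, dn_ml, dn_ng86
from rhodoplast.gene_content import PresenceMatrix

logger = logging.getLogger(__name__)

#: Left-closed dN bin edges; medians ≥ 0.5 fall in the open top bin.
DN_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)

#: Extra (mitochondrial) markers admitted alongside the plastid gene set.
EXTRA_MARKERS = ("cox1", "cox1_5prime")


class RatesError(ValueError):
    pass


@dataclass
class GeneRateSummary:
    """Median/IQR summary of one gene's pairwise dN values."""

    gene: str
    n_taxa: int
    n_pairs: int
    median_dn: float | None
    q1_dn: float | None
    q3_dn: float | None
    iqr_dn: float | None
    length_nt: int
    n_undefined: int = 0

    @property
    def empty(self) -> bool:
        return self.median_dn is None


@dataclass
class MarkerClass:
    """A gene's dN bin, relative-IQR category, and suitability flags."""

    gene: str
    dn_bin: str
    iqr_category: str
    candidate: bool
    unsuitable: bool
    deep_phylogeny_tier: bool = False


def select_genes(
    matrix: PresenceMatrix,
    min_taxa: int = 3,
    taxa: Sequence[str] | None = None,
    extra_markers: Sequence[str] = EXTRA_MARKERS,
) -> list[str]:
    """Protein-coding genes present in at least *min_taxa* of the given
    taxa (default: all matrix taxa); unknown ORFs are excluded.  Extra
    markers (mitochondrial cox1 and its 5' barcode region) are admitted
    whenever present in the matrix regardless of class."""
    taxa = list(taxa) if taxa is not None else matrix.taxa
    selected = []
    for gene in matrix.genes:
        if gene in extra_markers:
            selected.append(gene)
            continue
        if matrix.gene_class.get(gene) != "protein":
            continue
        count = sum(1 for t in taxa if t in matrix.taxa_with(gene))
        if count >= min_taxa:
            selected.append(gene)
    return selected


def pairwise_rates(
    alignment: CodonAlignment,
    method: str = "ml",
    equal_frequencies: bool = False,
) -> list[PairwiseRate]:
    """All-pairs dN estimates for one gene's codon alignment."""
    estimator = {"ml": dn_ml, "ng86": dn_ng86}.get(method.lower())
    if estimator is None:
        raise RatesError(f"unknown method {method!r}")
    out = []
    for a, b in itertools.combinations(alignment.taxa, 2):
        codons_a = []
        codons_b = []
        for ca, cb in alignment.pair_codons(a, b):
            codons_a.append(ca)
            codons_b.append(cb)
        kwargs = {"equal_frequencies": equal_frequencies} if method.lower() == "ml" else {}
        out.append(
            estimator(
                codons_a,
                codons_b,
                code=alignment.code,
                gene=alignment.gene,
                taxon_a=a,
                taxon_b=b,
                **kwargs,
            )
        )
    return out


def _interpolated_quantile(values: Sequence[float], q: float) -> float:
    return float(np.quantile(np.asarray(values, dtype=float), q, method="linear"))


def gene_summary(
    rates: Sequence[PairwiseRate], length_nt: int = 0
) -> GeneRateSummary:
    """Median and IQR of one gene's pairwise dN values.

    Undefined pairwise values are excluded with a logged count; a gene
    whose pairs are all undefined yields an empty (flagged) summary.
    """
    if not rates:
        raise RatesError("no pairwise rates given")
    gene = rates[0].gene
    taxa = set()
    for r in rates:
        taxa.add(r.taxon_a)
        taxa.add(r.taxon_b)
    defined = [r.dn for r in rates if r.dn is not None]
    n_undef = len(rates) - len(defined)
    if n_undef:
        logger.warning("%s: %d undefined pairwise dN excluded", gene, n_undef)
    if not defined:
        return GeneRateSummary(
            gene, len(taxa), len(rates), None, None, None, None, length_nt, n_undef
        )
    q1 = _interpolated_quantile(defined, 0.25)
    q3 = _interpolated_quantile(defined, 0.75)
    return GeneRateSummary(
        gene=gene,
        n_taxa=len(taxa),
        n_pairs=len(rates),
        median_dn=_interpolated_quantile(defined, 0.5),
        q1_dn=q1,
        q3_dn=q3,
        iqr_dn=q3 - q1,
        length_nt=length_nt,
        n_undefined=n_undef,
    )


def total_pair_count(summaries: Iterable[GeneRateSummary]) -> int:
    """Total pairwise comparisons: Σ over genes of n·(n−1)/2."""
    return sum(s.n_taxa * (s.n_taxa - 1) // 2 for s in summaries)


def dn_iqr_correlation(
    summaries: Iterable[GeneRateSummary],
) -> dict[str, float]:
    """Pearson correlation of median dN vs IQR, raw and log2-transformed.

    Genes with undefined summaries are skipped; for the log2 variant,
    genes with zero median or IQR are excluded with a logged count.
    Returns r_raw, p_raw, r_log2, p_log2 (NaN where undefined, e.g.
    zero variance).
    """
    pts = [
        (s.median_dn, s.iqr_dn)
        for s in summaries
        if s.median_dn is not None and s.iqr_dn is not None
    ]
    if len(pts) < 3:
        raise RatesError("need at least 3 summarised genes for a correlation")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # zero variance: r undefined
        r_raw, p_raw = math.nan, math.nan
    else:
        r_raw, p_raw = sps.pearsonr(x, y)
    pos = (x > 0) & (y > 0)
    dropped = int((~pos).sum())
    if dropped:
        logger.warning("dn_iqr_correlation: %d genes excluded from log2 variant", dropped)
    if pos.sum() >= 3 and np.std(np.log2(x[pos])) > 0 and np.std(np.log2(y[pos])) > 0:
        r_log2, p_log2 = sps.pearsonr(np.log2(x[pos]), np.log2(y[pos]))
    else:
        r_log2, p_log2 = math.nan, math.nan
    return {
        "r_raw": float(r_raw),
        "p_raw": float(p_raw),
        "r_log2": float(r_log2),
        "p_log2": float(p_log2),
        "n": len(pts),
        "n_log2": int(pos.sum()),
    }


def _dn_bin(median_dn: float) -> str:
    edges = DN_BIN_EDGES
    for lo, hi in zip(edges, edges[1:]):
        if lo <= median_dn < hi:
            return f"[{lo:.1f},{hi:.1f})"
    return ">=0.5"


def classify_markers(
    summaries: Sequence[GeneRateSummary],
    total_taxa: int | None = None,
    min_length_nt: int = 300,
) -> list[MarkerClass]:
    """Bin genes by median dN and relative IQR; flag marker candidates.

    Within each dN bin, genes are ranked by IQR (ties broken by gene
    name) and split into LOW/MEDIUM/HIGH tertiles; bins with fewer than
    three genes put all members in LOW.  A gene is unsuitable when its
    median dN ≥ 0.5 or its relative IQR is HIGH.  Candidates are LOW-IQR
    genes with 0.1 ≤ median dN < 0.4, length > *min_length_nt*, present
    in all *total_taxa* taxa.  Qualifying genes below dN 0.1 are flagged
    as the deep-phylogeny tier instead.
    """
    usable = [s for s in summaries if not s.empty]
    if total_taxa is None:
        total_taxa = max((s.n_taxa for s in usable), default=0)
    by_bin: dict[str, list[GeneRateSummary]] = {}
    for s in usable:
        by_bin.setdefault(_dn_bin(s.median_dn), []).append(s)
    category: dict[str, str] = {}
    for members in by_bin.values():
        members = sorted(members, key=lambda s: (s.iqr_dn, s.gene))
        n = len(members)
        if n < 3:
            for s in members:
                category[s.gene] = "LOW"
            continue
        cut1 = math.ceil(n / 3)
        cut2 = math.ceil(2 * n / 3)
        for rank, s in enumerate(members):
            if rank < cut1:
                category[s.gene] = "LOW"
            elif rank < cut2:
                category[s.gene] = "MEDIUM"
            else:
                category[s.gene] = "HIGH"
    out = []
    for s in usable:
        cat = category[s.gene]
        unsuitable = s.median_dn >= 0.5 or cat == "HIGH"
        ubiquitous = s.n_taxa >= total_taxa
        base_ok = cat == "LOW" and s.length_nt > min_length_nt and ubiquitous
        candidate = base_ok and 0.1 <= s.median_dn < 0.4 and not unsuitable
        deep = base_ok and s.median_dn < 0.1 and not unsuitable
        out.append(
            MarkerClass(
                gene=s.gene,
                dn_bin=_dn_bin(s.median_dn),
                iqr_category=cat,
                candidate=candidate,
                unsuitable=unsuitable,
                deep_phylogeny_tier=deep,
            )
        )
    return out


def summaries_table(summaries: Iterable[GeneRateSummary]) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene,
            "n_taxa": s.n_taxa,
            "n_pairs": s.n_pairs,
            "median_dN": s.median_dn,
            "Q1": s.q1_dn,
            "Q3": s.q3_dn,
            "IQR": s.iqr_dn,
            "length_nt": s.length_nt,
            "n_undefined": s.n_undefined,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def rates_table(rates: Iterable[PairwiseRate]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "taxon_a": r.taxon_a,
            "taxon_b": r.taxon_b,
            "dN": r.dn,
            "dS": r.ds,
            "t": r.t,
            "omega": r.omega,
            "kappa": r.kappa,
            "method": r.method,
            "n_codons": r.n_codons,
        }
        for r in rates
    ]
    return pd.DataFrame(rows)


def classification_table(classes: Iterable[MarkerClass]) -> pd.DataFrame:
    rows = [
        {
            "gene": c.gene,
            "dN_bin": c.dn_bin,
            "iqr_category": c.iqr_category,
            "candidate": c.candidate,
            "unsuitable": c.unsuitable,
            "deep_phylogeny_tier": c.deep_phylogeny_tier,
        }
        for c in classes
    ]
    return pd.DataFrame(rows)


def extract_five_prime(cds: Mapping[str, str], length_nt: int = 664) -> dict[str, str]:
    """The 5' barcode region of a marker (default 664 nt, the standard
    cox1 barcode length), trimmed to whole codons."""
    length_nt -= length_nt % 3
    return {t: s[:length_nt] for t, s in cds.items()}
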