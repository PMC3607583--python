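"""Gene-rate summaries, dN-IQR correlation, and marker classification."""

import math

import numpy as np
import pytest

from rhodoplast.dnds import PairwiseRate
from rhodoplast.gene_content import build_presence_matrix
from rhodoplast.rates import (
    GeneRateSummary,
    RatesError,
    classify_markers,
    dn_iqr_correlation,
    gene_summary,
    select_genes,
    total_pair_count,
)

from conftest import make_record


def _rate(gene, a, b, dn):
    return PairwiseRate(gene, a, b, dn, None, None, None, None, "NG86")


def _summary(gene, median, iqr, n_taxa=6, length=500):
    return GeneRateSummary(
        gene=gene,
        n_taxa=n_taxa,
        n_pairs=n_taxa * (n_taxa - 1) // 2,
        median_dn=median,
        q1_dn=None if median is None else median - iqr / 2,
        q3_dn=None if median is None else median + iqr / 2,
        iqr_dn=iqr,
        length_nt=length,
    )


class TestGeneSummary:
    def test_interpolated_quantiles(self):
        rates = [_rate("g", "a", str(i), v) for i, v in enumerate([1.0, 2.0, 3.0, 4.0])]
        s = gene_summary(rates)
        assert s.median_dn == pytest.approx(2.5)
        assert s.q1_dn == pytest.approx(1.75)
        assert s.q3_dn == pytest.approx(3.25)
        assert s.iqr_dn == pytest.approx(1.5)

    def test_single_pair(self):
        s = gene_summary([_rate("g", "a", "b", 0.2)])
        assert s.median_dn == pytest.approx(0.2)
        assert s.iqr_dn == 0.0

    def test_all_undefined_flagged_empty(self):
        s = gene_summary([_rate("g", "a", "b", None), _rate("g", "a", "c", None)])
        assert s.empty
        assert s.n_undefined == 2

    def test_undefined_excluded_from_median(self):
        s = gene_summary(
            [_rate("g", "a", "b", 0.1), _rate("g", "a", "c", None), _rate("g", "b", "c", 0.3)]
        )
        assert s.median_dn == pytest.approx(0.2)
        assert s.n_undefined == 1


class TestTotalPairCount:
    def test_closed_form(self):
        sums = [_summary("a", 0.1, 0.01, n_taxa=3),
                _summary("b", 0.1, 0.01, n_taxa=4),
                _summary("c", 0.1, 0.01, n_taxa=6)]
        assert total_pair_count(sums) == 3 + 6 + 15


class TestSelectGenes:
    def test_threshold_orfs_and_extra_markers(self):
        recs = [
            make_record(f"t{i}", [("psbA", "+"), ("orf9", "+")] + ([("rare", "+")] if i < 2 else []))
            for i in range(6)
        ]
        recs.append(make_record("mt", [("cox1", "+")]))
        m = build_presence_matrix(recs)
        selected = select_genes(m, min_taxa=3)
        assert "psbA" in selected
        assert "rare" not in selected  # present in only 2 taxa
        assert "orf9" not in selected  # unknown ORFs excluded
        assert "cox1" in selected  # admitted as extra marker


class TestCorrelation:
    def test_exactly_linear(self):
        sums = [_summary(f"g{i}", 0.1 * i, 0.05 * i) for i in range(1, 8)]
        out = dn_iqr_correlation(sums)
        assert out["r_raw"] == pytest.approx(1.0)
        assert out["r_log2"] == pytest.approx(1.0)

    def test_constant_iqr_flagged(self):
        sums = [_summary(f"g{i}", 0.1 * i, 0.05) for i in range(1, 8)]
        out = dn_iqr_correlation(sums)
        assert math.isnan(out["r_raw"]) or abs(out["r_raw"]) < 1e-12

    def test_too_few_genes_is_error(self):
        with pytest.raises(RatesError):
            dn_iqr_correlation([_summary("g", 0.1, 0.05)])

    def test_heteroscedastic_generator_structure(self):
        """Multiplicative rate spread (IQR proportional to median) gives a
        strong positive log-log correlation."""
        rng = np.random.default_rng(19)
        sums = []
        for i in range(60):
            scale = float(np.exp(rng.normal(np.log(0.15), 0.7)))
            sums.append(_summary(f"g{i:02d}", scale, scale * float(rng.uniform(0.2, 0.6))))
        out = dn_iqr_correlation(sums)
        assert out["r_log2"] > 0.8
        assert out["p_log2"] < 1e-6


class TestClassifyMarkers:
    def test_candidate_rule(self):
        sums = [_summary(f"f{i}", 0.15 + 0.001 * i, 0.02 + 0.01 * i) for i in range(9)]
        classes = {c.gene: c for c in classify_markers(sums, total_taxa=6)}
        # lowest-IQR tertile in the [0.1,0.2) bin qualifies
        assert classes["f0"].candidate
        assert classes["f0"].iqr_category == "LOW"
        assert classes["f8"].iqr_category == "HIGH"
        assert classes["f8"].unsuitable

    def test_very_high_dn_unsuitable(self):
        sums = [_summary("hot", 0.6, 0.01)] + [
            _summary(f"g{i}", 0.15, 0.02 + 0.01 * i) for i in range(5)
        ]
        classes = {c.gene: c for c in classify_markers(sums, total_taxa=6)}
        assert classes["hot"].unsuitable
        assert not classes["hot"].candidate

    def test_exact_half_is_unsuitable(self):
        sums = [_summary("edge", 0.5, 0.01)] + [
            _summary(f"g{i}", 0.15, 0.02) for i in range(3)
        ]
        classes = {c.gene: c for c in classify_markers(sums, total_taxa=6)}
        assert classes["edge"].dn_bin == ">=0.5"
        assert classes["edge"].unsuitable

    def test_slow_gene_goes_to_deep_phylogeny_tier(self):
        sums = [_summary("slow", 0.05, 0.005)] + [
            _summary(f"g{i}", 0.05, 0.02 + 0.01 * i) for i in range(4)
        ]
        classes = {c.gene: c for c in classify_markers(sums, total_taxa=6)}
        assert not classes["slow"].candidate
        assert classes["slow"].deep_phylogeny_tier

    def test_missing_taxon_blocks_candidacy(self):
        sums = [_summary("part", 0.15, 0.01, n_taxa=5)] + [
            _summary(f"g{i}", 0.15, 0.02) for i in range(3)
        ]
        classes = {c.gene: c for c in classify_markers(sums, total_taxa=6)}
        assert not classes["part"].candidate

    def test_short_gene_blocks_candidacy(self):
        sums = [_summary("short", 0.15, 0.01, length=200)] + [
            _summary(f"g{i}", 0.15, 0.02) for i in range(3)
        ]
        classes = {c.gene: c for c in classify_markers(sums, total_taxa=6)}
        assert not classes["short"].candidate

    def test_partition_invariants(self):
        rng = np.random.default_rng(23)
        sums = [
            _summary(f"g{i:02d}", float(rng.uniform(0.01, 0.8)), float(rng.uniform(0.005, 0.3)))
            for i in range(40)
        ]
        classes = classify_markers(sums, total_taxa=6)
        assert len(classes) == len(sums)
        for c in classes:
            assert c.iqr_category in ("LOW", "MEDIUM", "HIGH")
            assert not (c.candidate and c.unsuitable)
            if c.candidate:
                assert c.iqr_category == "LOW"
                assert c.dn_bin in ("[0.1,0.2)", "[0.2,0.3)", "[0.3,0.4)")
        # small bins put everyone in LOW
        tiny = classify_markers(sums[:2], total_taxa=6)
        assert {c.iqr_category for c in tiny} == {"LOW"}
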