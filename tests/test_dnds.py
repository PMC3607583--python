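"""Pairwise dN estimation: counting oracle values, estimator symmetry,
cross-checks against an independent implementation, and ML behaviour."""

import numpy as np
import pytest

from rhodoplast.codon import GeneticCode
from rhodoplast.dnds import (
    ML_START_GRID,
    RateEstimationError,
    _get_model,
    _site_fractions,
    dn_ml,
    dn_ng86,
)
from rhodoplast.simulate import _GeneModel, _evolve_gene, _random_sense_codons


STD = GeneticCode.standard()


def random_cds(rng, n_codons, code=STD):
    return "".join(_random_sense_codons(n_codons, code, rng))


class TestNG86:
    def test_hand_computed_single_codon_pair(self):
        """TTT vs TTA: sites 1/3 and 2/3 synonymous, one nonsynonymous
        difference, so pN = 1/2.5 = 0.4 and dN = -(3/4)ln(1-4/3*0.4)."""
        s_ttt, n_ttt = _site_fractions("TTT", STD)
        s_tta, n_tta = _site_fractions("TTA", STD)
        assert s_ttt == pytest.approx(1 / 3)
        assert s_tta == pytest.approx(2 / 3)
        assert (n_ttt + n_tta) / 2 == pytest.approx(2.5)
        r = dn_ng86(["TTT"], ["TTA"])
        assert r.dn == pytest.approx(0.5716, abs=1e-3)

    def test_identical_sequences_zero(self):
        r = dn_ng86("ATGGCTAAA", "ATGGCTAAA")
        assert r.dn == 0.0

    def test_synonymous_only_change(self):
        # one GCT -> GCC change (Ala, synonymous) among five codons
        a = "ATG" + "GCT" * 4
        b = "ATG" + "GCT" * 3 + "GCC"
        r = dn_ng86(a, b)
        assert r.dn == 0.0
        assert r.ds is not None and r.ds > 0

    def test_saturation_flagged_not_zeroed(self):
        # every codon maximally different nonsynonymously
        a = "ATG" * 20
        b = "CCC" * 20
        r = dn_ng86(a, b)
        assert r.dn is None
        assert not r.defined

    def test_length_mismatch_is_error(self):
        with pytest.raises(RateEstimationError):
            dn_ng86("ATGGCT", "ATG")

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        model = _GeneModel(STD, 2.0, 0.5)
        anc = _random_sense_codons(100, STD, rng)
        a, *_ = _evolve_gene(anc, 0.1, model, rng)
        b, *_ = _evolve_gene(anc, 0.1, model, rng)
        fwd = dn_ng86(a, b)
        rev = dn_ng86(b, a)
        assert fwd.dn == pytest.approx(rev.dn)
        assert fwd.ds == pytest.approx(rev.ds)

    def test_matches_independent_implementation(self):
        """Cross-check against Biopython's NG86 on evolved pairs."""
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import codonalign
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(3)
        model = _GeneModel(STD, 2.0, 0.4)
        for _ in range(5):
            anc = _random_sense_codons(80, STD, rng)
            a, *_ = _evolve_gene(anc, 0.1, model, rng)
            b, *_ = _evolve_gene(anc, 0.1, model, rng)
            ours = dn_ng86(a, b)
            dn_ref, ds_ref = cal_dn_ds(
                CodonSeq("".join(a)), CodonSeq("".join(b)), method="NG86"
            )
            assert ours.dn == pytest.approx(dn_ref, abs=2e-3)
            assert ours.ds == pytest.approx(ds_ref, abs=2e-2)


class TestML:
    def test_identical_sequences_zero_divergence(self):
        seq = "ATGGCTAAACGTGAT" * 10
        r = dn_ml(seq, seq)
        assert r.t == 0.0 and r.dn == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        model = _GeneModel(STD, 2.0, 0.5)
        anc = _random_sense_codons(100, STD, rng)
        a, *_ = _evolve_gene(anc, 0.15, model, rng)
        b, *_ = _evolve_gene(anc, 0.15, model, rng)
        fwd = dn_ml(a, b)
        rev = dn_ml(b, a)
        assert fwd.dn == pytest.approx(rev.dn, rel=1e-4)

    def test_optimum_beats_every_grid_start(self):
        rng = np.random.default_rng(7)
        model = _GeneModel(STD, 2.0, 0.3)
        anc = _random_sense_codons(150, STD, rng)
        a, *_ = _evolve_gene(anc, 0.2, model, rng)
        b, *_ = _evolve_gene(anc, 0.2, model, rng)
        cm = _get_model(STD)
        r = dn_ml(a, b)
        # recompute the log-likelihood surface at the start points
        from rhodoplast.dnds import _f3x4

        pairs = list(zip(a, b))
        pi = _f3x4(pairs, cm)
        patterns = {}
        for ca, cb in pairs:
            key = (cm.index[ca], cm.index[cb])
            patterns[key] = patterns.get(key, 0) + 1
        idx_i = np.array([k[0] for k in patterns])
        idx_j = np.array([k[1] for k in patterns])
        cnt = np.array(list(patterns.values()), dtype=float)

        def loglik(t, kappa, omega):
            q = cm.rate_matrix(kappa, omega, pi)
            p = cm.transition_probs(q, pi, t)
            return float((cnt * (np.log(pi[idx_i]) + np.log(p[idx_i, idx_j]))).sum())

        at_optimum = loglik(r.t, r.kappa, r.omega)
        for t0, k0, w0 in ML_START_GRID:
            assert at_optimum >= loglik(t0, k0, w0) - 1e-6

    def test_low_divergence_concordance_with_counting(self):
        """Where counting is unbiased (pN < 0.05) the two estimators
        agree within 15%."""
        rng = np.random.default_rng(11)
        model = _GeneModel(STD, 2.0, 0.3)
        checked = 0
        while checked < 5:
            anc = _random_sense_codons(400, STD, rng)
            a, *_ = _evolve_gene(anc, 0.03, model, rng)
            b, *_ = _evolve_gene(anc, 0.03, model, rng)
            ng = dn_ng86(a, b)
            if ng.dn is None or ng.dn < 0.005:
                continue
            ml = dn_ml(a, b)
            assert abs(ml.dn - ng.dn) / ng.dn < 0.15
            checked += 1

    def test_degenerate_input_flagged(self):
        r = dn_ml(["---"], ["---"])
        assert not r.defined

    def test_monotone_in_divergence(self):
        """Median estimated dN never decreases as simulation time grows
        (fixed omega)."""
        rng = np.random.default_rng(13)
        model = _GeneModel(STD, 2.0, 0.3)
        medians = []
        for t in (0.05, 0.2, 0.5):
            vals = []
            for _ in range(8):
                anc = _random_sense_codons(150, STD, rng)
                a, *_ = _evolve_gene(anc, t / 2, model, rng)
                b, *_ = _evolve_gene(anc, t / 2, model, rng)
                vals.append(dn_ml(a, b, equal_frequencies=True).dn)
            medians.append(np.median(vals))
        assert medians[0] <= medians[1] <= medians[2]


class TestParameterRecovery:
    @pytest.mark.parametrize("omega,t", [(0.1, 0.5), (0.5, 0.5), (1.0, 0.1)])
    def test_omega_and_dn_recovery(self, omega, t):
        """Median ω̂ within 15% of truth, median dN within 10% of the
        realized rate (stochastic; fixed seeds)."""
        rng = np.random.default_rng(int(omega * 100) + int(t * 10))
        model = _GeneModel(STD, 2.0, omega)
        omega_hats, est, real = [], [], []
        for _ in range(12):
            anc = _random_sense_codons(300, STD, rng)
            a, n1, s1, in1, _ = _evolve_gene(anc, t / 2, model, rng)
            b, n2, s2, in2, _ = _evolve_gene(anc, t / 2, model, rng)
            r = dn_ml(a, b, equal_frequencies=True)
            omega_hats.append(r.omega)
            est.append(r.dn)
            real.append((n1 + n2) / ((in1 + in2) / t))
        assert np.median(omega_hats) == pytest.approx(omega, rel=0.15)
        assert np.median(est) == pytest.approx(np.median(real), rel=0.10)
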