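"""Pairwise dN/dS estimation: Nei–Gojobori counting and codon-model ML.

Two estimators of the nonsynonymous substitution rate between a pair of
coding sequences:

``dn_ng86``
    The Nei–Gojobori (1986) counting method.  Synonymous/nonsynonymous
    site fractions are counted per codon position (mutations to stop
    codons excluded from the opportunity), observed differences on
    multi-hit codons are averaged over all minimal mutational pathways
    that avoid stop intermediates, and proportions are corrected with
    the Jukes–Cantor formula d = −(3/4)·ln(1 − (4/3)·p).  Saturated
    proportions (p ≥ 3/4) are flagged undefined, never zeroed.

``dn_ml``
    Maximum likelihood under a GY94-style codon model with parameters
    (t, κ, ω): substitution rate between sense codons differing at one
    position is π_target · κ^[transition] · ω^[nonsynonymous], scaled to
    one expected substitution per codon per unit t.  Codon frequencies
    are F3×4 from the concatenated pair by default (equal frequencies by
    flag).  Optimisation is multi-start over a fixed grid; dN and dS are
    decomposed from (t̂, κ̂, ω̂) as expected substitutions of each class
    per κ-weighted physical site.

dN is reported as nonsynonymous substitutions per nonsynonymous site in
both cases, so the two estimators agree at low divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize

from rhodoplast.codon import GeneticCode

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class RateEstimationError(ValueError):
    pass


@dataclass
class PairwiseRate:
    """Per gene-pair substitution-rate estimates.

    ``dn``/``ds`` are None when undefined (saturation or degenerate
    input) — undefined is flagged, never silently zero.  ``t`` is the
    expected number of substitutions per codon (ML only).
    """

    gene: str
    taxon_a: str
    taxon_b: str
    dn: float | None
    ds: float | None
    t: float | None
    omega: float | None
    kappa: float | None
    method: str
    n_codons: int = 0

    @property
    def defined(self) -> bool:
        return self.dn is not None


def _jc_correct(p: float) -> float | None:
    if p < 0:
        return 0.0
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _site_fractions(codon: str, code: GeneticCode, kappa: float = 1.0) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Per position, the fraction of possible (non-stop) single-nucleotide
    changes that are synonymous; with ``kappa`` != 1 the changes are
    transition/transversion weighted (used by the ML decomposition; the
    NG86 path uses kappa = 1).
    """
    syn = 0.0
    for pos in range(3):
        w_total = 0.0
        w_syn = 0.0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in code.stops:
                continue
            w = kappa if (codon[pos], base) in _TRANSITIONS else 1.0
            w_total += w
            if code.is_synonymous(codon, alt):
                w_syn += w
        if w_total > 0:
            syn += w_syn / w_total
    return syn, 3.0 - syn


def _pathway_differences(
    ca: str, cb: str, code: GeneticCode
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over minimal mutational pathways avoiding stop
    intermediates (all pathways if every one hits a stop)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    fallback = []
    for order in permutations(diff):
        cur = ca
        syn = nonsyn = 0.0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in code.stops:
                hit_stop = True
            if code.is_synonymous(cur, nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (fallback if hit_stop else results).append((syn, nonsyn))
    pool = results or fallback
    s = sum(p[0] for p in pool) / len(pool)
    n = sum(p[1] for p in pool) / len(pool)
    return s, n


def dn_ng86(
    a: Sequence[str],
    b: Sequence[str],
    code: GeneticCode | None = None,
    gene: str = "",
    taxon_a: str = "a",
    taxon_b: str = "b",
) -> PairwiseRate:
    """Nei–Gojobori (1986) pairwise dN/dS with Jukes–Cantor correction.

    *a* and *b* are codon-synchronised sequences given either as codon
    lists or plain nucleotide strings of equal length; columns with gaps
    or ambiguity are skipped.
    """
    code = code or GeneticCode.standard()
    ca_list = _as_codons(a)
    cb_list = _as_codons(b)
    if len(ca_list) != len(cb_list):
        raise RateEstimationError(
            f"length mismatch: {len(ca_list)} vs {len(cb_list)} codons"
        )
    valid = set("ACGT")
    pairs = [
        (ca.upper(), cb.upper())
        for ca, cb in zip(ca_list, cb_list)
        if set(ca.upper()) <= valid and set(cb.upper()) <= valid
    ]
    if not pairs:
        return PairwiseRate(gene, taxon_a, taxon_b, None, None, None, None, None,
                            "NG86", 0)
    s_sites_a = n_sites_a = s_sites_b = n_sites_b = 0.0
    sd = nd = 0.0
    for ca, cb in pairs:
        sa, na = _site_fractions(ca, code)
        sb, nb = _site_fractions(cb, code)
        s_sites_a += sa
        n_sites_a += na
        s_sites_b += sb
        n_sites_b += nb
        s_diff, n_diff = _pathway_differences(ca, cb, code)
        sd += s_diff
        nd += n_diff
    s_bar = (s_sites_a + s_sites_b) / 2.0
    n_bar = (n_sites_a + n_sites_b) / 2.0
    pn = nd / n_bar if n_bar > 0 else 0.0
    ps = sd / s_bar if s_bar > 0 else 0.0
    dn = _jc_correct(pn)
    ds = _jc_correct(ps) if s_bar > 0 else None
    omega = (dn / ds) if (dn is not None and ds is not None and ds > 0) else None
    return PairwiseRate(
        gene, taxon_a, taxon_b, dn, ds, None, omega, None, "NG86", len(pairs)
    )


def _as_codons(seq: Sequence[str]) -> list[str]:
    if isinstance(seq, str):
        if len(seq) % 3:
            raise RateEstimationError(f"sequence length {len(seq)} not divisible by 3")
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return list(seq)


# ---------------------------------------------------------------------------
# GY94-style pairwise maximum likelihood


class _CodonModel:
    """Precomputed structure of the GY94-style rate matrix for one code."""

    def __init__(self, code: GeneticCode):
        self.code = code
        self.codons = code.sense_codons()
        self.index = {c: i for i, c in enumerate(self.codons)}
        n = len(self.codons)
        pairs_i, pairs_j, is_ts, is_nonsyn = [], [], [], []
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diff = [k for k in range(3) if ci[k] != cj[k]]
                if len(diff) != 1:
                    continue
                k = diff[0]
                pairs_i.append(i)
                pairs_j.append(j)
                is_ts.append((ci[k], cj[k]) in _TRANSITIONS)
                is_nonsyn.append(not code.is_synonymous(ci, cj))
        self.n = n
        self.pi_idx = np.array(pairs_i)
        self.pj_idx = np.array(pairs_j)
        self.ts = np.array(is_ts)
        self.nonsyn = np.array(is_nonsyn)

    def rate_matrix(self, kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
        q = np.zeros((self.n, self.n))
        rates = pi[self.pj_idx] * np.where(self.ts, kappa, 1.0)
        rates = rates * np.where(self.nonsyn, omega, 1.0)
        q[self.pi_idx, self.pj_idx] = rates
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        if scale <= 0:
            raise RateEstimationError("degenerate rate matrix")
        return q / scale

    def transition_probs(self, q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
        # reversible Q: symmetrise, eigendecompose, exponentiate
        sqrt_pi = np.sqrt(pi)
        b = (q * sqrt_pi[None, :]) / sqrt_pi[:, None]
        b = (b + b.T) / 2.0
        w, v = eigh(b)
        expwt = np.exp(w * t)
        p = (v * expwt) @ v.T
        p = p / sqrt_pi[:, None] * sqrt_pi[None, :]
        return np.clip(p, 1e-300, None)

    def substitution_fractions(
        self, kappa: float, omega: float, pi: np.ndarray
    ) -> tuple[float, float]:
        """(synonymous, nonsynonymous) fractions of the substitution flow."""
        q = self.rate_matrix(kappa, omega, pi)
        flow = pi[self.pi_idx] * q[self.pi_idx, self.pj_idx]
        total = flow.sum()
        nonsyn = flow[self.nonsyn].sum()
        return float((total - nonsyn) / total), float(nonsyn / total)

    def site_counts(self, kappa: float, pi: np.ndarray) -> tuple[float, float]:
        """π-averaged (synonymous, nonsynonymous) κ-weighted sites/codon."""
        s_tot = n_tot = 0.0
        for c, p in zip(self.codons, pi):
            s, n = _site_fractions(c, self.code, kappa)
            s_tot += p * s
            n_tot += p * n
        return s_tot, n_tot


_MODEL_CACHE: dict[str, _CodonModel] = {}


def _get_model(code: GeneticCode) -> _CodonModel:
    key = code.name
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = _CodonModel(code)
    return _MODEL_CACHE[key]


def _f3x4(pairs: list[tuple[str, str]], model: _CodonModel) -> np.ndarray:
    counts = np.full((3, 4), 0.5)  # pseudocount keeps all codons reachable
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for ca, cb in pairs:
        for codon in (ca, cb):
            for pos in range(3):
                counts[pos, base_idx[codon[pos]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, base_idx[c[0]]] * freqs[1, base_idx[c[1]]] * freqs[2, base_idx[c[2]]]
            for c in model.codons
        ]
    )
    return pi / pi.sum()


#: Fixed multi-start grid for the ML optimiser: (t, kappa, omega).
ML_START_GRID = (
    (0.1, 2.0, 0.2),
    (0.1, 2.0, 1.0),
    (1.0, 2.0, 0.2),
    (1.0, 2.0, 1.0),
)


def dn_ml(
    a: Sequence[str],
    b: Sequence[str],
    code: GeneticCode | None = None,
    gene: str = "",
    taxon_a: str = "a",
    taxon_b: str = "b",
    equal_frequencies: bool = False,
    tol: float = 1e-8,
) -> PairwiseRate:
    """Pairwise dN/dS by maximum likelihood under a GY94-style model.

    Maximises the two-sequence likelihood over (t, κ, ω) from the fixed
    start grid ``ML_START_GRID`` (convergence tolerance *tol* on the
    log-likelihood scale).  Codon frequencies are F3×4 from the pair
    unless *equal_frequencies* is set.
    """
    code = code or GeneticCode.standard()
    model = _get_model(code)
    ca_list = _as_codons(a)
    cb_list = _as_codons(b)
    if len(ca_list) != len(cb_list):
        raise RateEstimationError(
            f"length mismatch: {len(ca_list)} vs {len(cb_list)} codons"
        )
    valid = set("ACGT")
    pairs = [
        (ca.upper(), cb.upper())
        for ca, cb in zip(ca_list, cb_list)
        if set(ca.upper()) <= valid and set(cb.upper()) <= valid
        and ca.upper() in model.index and cb.upper() in model.index
    ]
    if not pairs:
        return PairwiseRate(gene, taxon_a, taxon_b, None, None, None, None, None,
                            "ML", 0)
    if equal_frequencies:
        pi = np.full(model.n, 1.0 / model.n)
    else:
        pi = _f3x4(pairs, model)

    patterns: dict[tuple[int, int], int] = {}
    n_diff = 0
    for ca, cb in pairs:
        key = (model.index[ca], model.index[cb])
        patterns[key] = patterns.get(key, 0) + 1
        if ca != cb:
            n_diff += 1
    idx_i = np.array([k[0] for k in patterns])
    idx_j = np.array([k[1] for k in patterns])
    cnt = np.array(list(patterns.values()), dtype=float)
    log_pi = np.log(pi)

    if n_diff == 0:
        # likelihood is maximised at zero divergence
        return PairwiseRate(gene, taxon_a, taxon_b, 0.0, 0.0, 0.0, None, None,
                            "ML", len(pairs))

    def negloglik(params: np.ndarray) -> float:
        t, kappa, omega = np.exp(params)
        q = model.rate_matrix(kappa, omega, pi)
        p = model.transition_probs(q, pi, t)
        return -float((cnt * (log_pi[idx_i] + np.log(p[idx_i, idx_j]))).sum())

    best = None
    for t0, k0, w0 in ML_START_GRID:
        res = minimize(
            negloglik,
            np.log([t0, k0, w0]),
            method="L-BFGS-B",
            bounds=[(-9.2, 4.6)] * 3,  # e^-9.2 ≈ 1e-4 .. e^4.6 ≈ 100
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RateEstimationError(
            f"{gene} {taxon_a}-{taxon_b}: ML optimisation failed from all starts"
        )
    t_hat, kappa_hat, omega_hat = np.exp(best.x)
    rho_s, rho_n = model.substitution_fractions(kappa_hat, omega_hat, pi)
    s_sites, n_sites = model.site_counts(kappa_hat, pi)
    dn = (t_hat * rho_n) / n_sites if n_sites > 0 else None
    ds = (t_hat * rho_s) / s_sites if s_sites > 0 else None
    return PairwiseRate(
        gene,
        taxon_a,
        taxon_b,
        dn,
        ds,
        float(t_hat),
        float(omega_hat),
        float(kappa_hat),
        "ML",
        len(pairs),
    )
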