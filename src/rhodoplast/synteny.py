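"""Gene-order comparison: signed permutations, breakpoints, inversions.

The gene order of a query genome is expressed in the coordinate frame of
a reference genome over their shared single-copy genes, giving a signed
permutation (sign = orientation relative to the reference strand).
Rearrangement between red algal plastid genomes is overwhelmingly by
inversion, so distances are computed under the reversal (inversion)
model: the minimum number of signed interval reversals transforming the
query order into the reference order.

Block counts between these genomes are small (~a dozen after collapsing
conserved adjacencies), so an exact iterative-deepening search with the
standard breakpoint lower bound is cheap and a full Hannenhalli–Pevzner
implementation is unnecessary.  Circular genomes are linearised at a
shared anchor gene (the lowest-index shared gene of the reference),
oriented ``+``; distances refer to that linearisation, with an optional
flag minimising over the dihedral symmetries of the circle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rhodoplast.genome_io import GenomeRecord

#: Largest collapsed block count accepted by the exact solver.
MAX_EXACT_BLOCKS = 25


class SyntenyError(ValueError):
    """Raised for empty shared gene sets, duplicates, or guard overruns."""


@dataclass(frozen=True)
class SignedPermutation:
    """A signed permutation of 1..n encoding relative gene order.

    ``elements[i]`` is the reference index (1-based) of the i-th gene of
    the query, negated when the query carries it on the opposite strand.
    ``gene_labels`` maps reference index -> canonical gene name (empty
    for abstract permutations).
    """

    elements: tuple[int, ...]
    topology: str = "linear"
    gene_labels: dict[int, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        n = len(self.elements)
        if n < 1:
            raise ValueError("permutation must have at least one element")
        if 0 in self.elements:
            raise ValueError("elements must be non-zero signed integers")
        if sorted(abs(e) for e in self.elements) != list(range(1, n + 1)):
            raise ValueError("absolute values must be exactly 1..n")

    @property
    def n(self) -> int:
        return len(self.elements)

    def inverse(self) -> "SignedPermutation":
        inv = [0] * self.n
        for pos, e in enumerate(self.elements, 1):
            if e > 0:
                inv[e - 1] = pos
            else:
                inv[-e - 1] = -pos
        return SignedPermutation(tuple(inv), self.topology)

    def is_identity(self) -> bool:
        return self.elements == tuple(range(1, self.n + 1))


@dataclass(frozen=True)
class RearrangementScenario:
    """An ordered list of reversals ((i, j) index intervals, 0-based
    inclusive) transforming a source permutation into the identity."""

    reversals: tuple[tuple[int, int], ...]

    @property
    def distance(self) -> int:
        return len(self.reversals)


def apply_reversal(elements: Sequence[int], i: int, j: int) -> tuple[int, ...]:
    """Reverse the interval [i, j] (0-based, inclusive), flipping signs."""
    if not 0 <= i <= j < len(elements):
        raise IndexError(f"reversal ({i}, {j}) out of range")
    mid = tuple(-e for e in reversed(elements[i : j + 1]))
    return tuple(elements[:i]) + mid + tuple(elements[j + 1 :])


def _shared_single_copy(
    reference: GenomeRecord, query: GenomeRecord
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], set[str]]:
    def order(rec: GenomeRecord) -> list[tuple[str, str]]:
        out = []
        for f in rec.features:
            if f.feature_class in ("ORF", "intron"):
                continue
            out.append((f.canonical_name, f.strand))
        return out

    ref_order = order(reference)
    qry_order = order(query)
    ref_counts: dict[str, int] = {}
    for name, _ in ref_order:
        ref_counts[name] = ref_counts.get(name, 0) + 1
    qry_counts: dict[str, int] = {}
    for name, _ in qry_order:
        qry_counts[name] = qry_counts.get(name, 0) + 1
    shared = {
        g
        for g in ref_counts
        if g in qry_counts and ref_counts[g] == 1 and qry_counts[g] == 1
    }
    if not shared:
        raise SyntenyError(
            f"no shared single-copy genes between {reference.taxon_id} and "
            f"{query.taxon_id}"
        )
    return ref_order, qry_order, shared  # type: ignore[return-value]


def encode_permutation(
    reference: GenomeRecord, query: GenomeRecord
) -> SignedPermutation:
    """Express *query*'s gene order in *reference*'s frame.

    Genes absent in either genome, multi-copy genes, and ORFs are
    dropped (orthology of extra copies is ambiguous).  Circular genomes
    are linearised at the shared gene occurring first in the reference,
    with the anchor oriented ``+`` in both frames.
    """
    ref_order, qry_order, shared = _shared_single_copy(reference, query)
    ref_shared = [(g, s) for g, s in ref_order if g in shared]
    qry_shared = [(g, s) for g, s in qry_order if g in shared]

    circular = reference.topology == "circular" and query.topology == "circular"
    anchor = ref_shared[0][0]
    if circular:
        # rotate the query so the anchor gene comes first; the reference
        # frame already starts at the anchor by construction
        qi = next(i for i, (g, _) in enumerate(qry_shared) if g == anchor)
        qry_shared = qry_shared[qi:] + qry_shared[:qi]
    index = {g: i + 1 for i, (g, _) in enumerate(ref_shared)}
    ref_strand = {g: s for g, s in ref_shared}
    elements = []
    for g, s in qry_shared:
        signed = index[g] if s == ref_strand[g] else -index[g]
        elements.append(signed)
    if circular and elements and elements[0] < 0:
        # flip the query reading direction so the anchor is oriented +
        elements = [-e for e in reversed(elements)]
        k = next(i for i, e in enumerate(elements) if abs(e) == index[anchor])
        elements = elements[k:] + elements[:k]
    labels = {i + 1: g for i, (g, _) in enumerate(ref_shared)}
    return SignedPermutation(tuple(elements), "linear", labels)


def collapse_adjacencies(perm: SignedPermutation) -> SignedPermutation:
    """Merge maximal runs of conserved adjacencies into single blocks.

    Consecutive elements ``a, b`` with ``b == a + 1`` (this covers both
    ``(i, i+1)`` and ``(-(i+1), -i)``) belong to one syntenic block.
    The identity collapses to a single element.
    """
    runs: list[list[int]] = []
    for e in perm.elements:
        if runs and e == runs[-1][-1] + 1:
            runs[-1].append(e)
        else:
            runs.append([e])
    # rank blocks by the absolute span they cover in the reference
    spans = sorted(range(len(runs)), key=lambda k: min(abs(e) for e in runs[k]))
    rank = {k: r + 1 for r, k in enumerate(spans)}
    elements = []
    labels: dict[int, str] = {}
    for k, run in enumerate(runs):
        sign = 1 if run[0] > 0 else -1
        elements.append(sign * rank[k])
        if perm.gene_labels:
            names = [perm.gene_labels.get(abs(e), str(abs(e))) for e in run]
            labels[rank[k]] = names[0] if len(names) == 1 else f"{names[0]}..{names[-1]}"
    return SignedPermutation(tuple(elements), perm.topology, labels)


def breakpoint_count(perm: SignedPermutation) -> int:
    """Breakpoints against the identity, with frame extension 0 and n+1."""
    ext = (0,) + perm.elements + (perm.n + 1,)
    return sum(1 for a, b in zip(ext, ext[1:]) if b != a + 1)


def _cycle_lower_bound(els: tuple[int, ...]) -> int:
    """Breakpoint-graph bound: d ≥ (n+1) − #cycles (tight except for
    hurdles, so iterative deepening rarely overshoots by more than 1)."""
    n = len(els)
    seq = [0]
    for e in els:
        if e > 0:
            seq.extend((2 * e - 1, 2 * e))
        else:
            seq.extend((-2 * e, -2 * e - 1))
    seq.append(2 * n + 1)
    # black edges join seq[2i] - seq[2i+1]; gray edges join labels 2k - 2k+1
    black = {}
    for i in range(n + 1):
        a, b = seq[2 * i], seq[2 * i + 1]
        black[a] = b
        black[b] = a
    seen = [False] * (2 * n + 2)
    cycles = 0
    for start in range(2 * n + 2):
        if seen[start]:
            continue
        cycles += 1
        v = start
        while not seen[v]:
            seen[v] = True
            w = black[v]
            seen[w] = True
            v = w ^ 1  # gray edge partner: 2k <-> 2k+1
    return (n + 1) - cycles


def _search(elements: tuple[int, ...], max_blocks: int) -> list[tuple[int, int]]:
    """Exact minimum reversal scenario by iterative deepening.

    Prunes with the breakpoint-graph cycle bound (admissible; exact up
    to hurdles).  Reversals are tried leftmost-shortest first, so the
    first optimal scenario found is lexicographically smallest.
    """
    n = len(elements)
    if n > max_blocks:
        raise SyntenyError(
            f"{n} blocks exceeds the exact-search guard ({max_blocks}); "
            f"report the breakpoint lower bound instead"
        )

    identity = tuple(range(1, n + 1))

    def dfs(
        els: tuple[int, ...],
        depth: int,
        limit: int,
        path: list,
        seen: dict[tuple[int, ...], int],
    ) -> bool:
        if els == identity:
            return True
        budget = limit - depth
        if seen.get(els, -1) >= budget:
            return False
        seen[els] = budget
        lb = _cycle_lower_bound(els)
        if lb > budget:
            return False
        children = [
            (i, j, apply_reversal(els, i, j)) for i in range(n) for j in range(i, n)
        ]
        # hurdle lookahead: a reversal lowers the bound by at most one; if
        # none does, the true distance exceeds the plain cycle bound
        if lb == budget and not any(
            _cycle_lower_bound(nxt) == lb - 1 for _, _, nxt in children
        ):
            return False
        for i, j, nxt in children:
            path.append((i, j))
            if dfs(nxt, depth + 1, limit, path, seen):
                return True
            path.pop()
        return False

    for limit in itertools.count(_cycle_lower_bound(elements)):
        path: list[tuple[int, int]] = []
        # transposition table: state -> largest budget already exhausted
        if dfs(elements, 0, limit, path, {}):
            return path


def inversion_distance(
    perm: SignedPermutation, max_blocks: int = MAX_EXACT_BLOCKS
) -> int:
    """Exact minimum number of signed reversals to reach the identity."""
    collapsed = collapse_adjacencies(perm)
    if collapsed.is_identity():
        return 0
    return len(_search(collapsed.elements, max_blocks))


def inversion_scenario(
    perm: SignedPermutation, max_blocks: int = MAX_EXACT_BLOCKS
) -> RearrangementScenario:
    """One optimal reversal scenario on the *uncollapsed* permutation.

    The search runs on collapsed blocks; block-level reversals are then
    expanded back to element index intervals.  The replayed scenario is
    checked internally to reach the identity.
    """
    if perm.is_identity():
        return RearrangementScenario(())
    collapsed = collapse_adjacencies(perm)
    block_path = _search(collapsed.elements, max_blocks)
    # expand block intervals to element intervals by replaying both levels
    runs: list[list[int]] = []
    for e in perm.elements:
        if runs and e == runs[-1][-1] + 1:
            runs[-1].append(e)
        else:
            runs.append([e])
    blocks = list(collapsed.elements)
    out: list[tuple[int, int]] = []
    elements = perm.elements
    for bi, bj in block_path:
        starts = []
        pos = 0
        for run in runs:
            starts.append(pos)
            pos += len(run)
        i = starts[bi]
        j = starts[bj] + len(runs[bj]) - 1
        out.append((i, j))
        elements = apply_reversal(elements, i, j)
        runs[bi : bj + 1] = [
            [-e for e in reversed(run)] for run in reversed(runs[bi : bj + 1])
        ]
        blocks = list(apply_reversal(tuple(blocks), bi, bj))
    if elements != tuple(range(1, perm.n + 1)):
        raise AssertionError("scenario replay did not reach the identity")
    return RearrangementScenario(tuple(out))


def _linear_adjacency_set(order: list[tuple[str, str]]) -> set[tuple]:
    """Orientation-aware adjacencies of a linearised gene order.

    The adjacency between (g, +)(h, +) equals, read backwards,
    (h, -)(g, -); adjacencies are stored in a canonical direction.
    """
    adjs = set()
    for (g1, s1), (g2, s2) in zip(order, order[1:]):
        fwd = (g1, s1, g2, s2)
        rev = (g2, "-" if s2 == "+" else "+", g1, "-" if s1 == "+" else "+")
        adjs.add(min(fwd, rev))
    return adjs


def conserved_cluster_count(records: Iterable[GenomeRecord]) -> int:
    """Number of maximal gene clusters with identical internal order and
    orientation across *all* genomes.

    Built over genes single-copy in every genome, on the common
    linearised frame (all genomes anchored at the same gene): blocks
    remaining after collapsing adjacencies shared by the whole set.
    Pairwise this equals the collapsed block count.
    """
    records = list(records)
    if len(records) < 2:
        raise SyntenyError("need at least two genomes")
    reference = records[0]
    orders = []
    common_genes: set[str] | None = None
    per_genome: list[list[tuple[str, str]]] = []
    for rec in records:
        counts: dict[str, int] = {}
        order = []
        for f in rec.features:
            if f.feature_class in ("ORF", "intron"):
                continue
            counts[f.canonical_name] = counts.get(f.canonical_name, 0) + 1
            order.append((f.canonical_name, f.strand))
        single = {g for g, c in counts.items() if c == 1}
        per_genome.append(order)
        common_genes = single if common_genes is None else (common_genes & single)
    if not common_genes:
        raise SyntenyError("no genes single-copy in all genomes")
    # linearise every genome at the same anchor, oriented +
    ref_order = [(g, s) for g, s in per_genome[0] if g in common_genes]
    anchor = ref_order[0][0]
    adj_common: set[tuple] | None = None
    for rec, order in zip(records, per_genome):
        shared = [(g, s) for g, s in order if g in common_genes]
        if rec.topology == "circular":
            ai = next(i for i, (g, _) in enumerate(shared) if g == anchor)
            shared = shared[ai:] + shared[:ai]
        if shared[0][1] == "-":
            shared = [(g, "+" if s == "-" else "-") for g, s in reversed(shared)]
            if rec.topology == "circular":
                ai = next(i for i, (g, _) in enumerate(shared) if g == anchor)
                shared = shared[ai:] + shared[:ai]
        adjs = _linear_adjacency_set(shared)
        adj_common = adjs if adj_common is None else (adj_common & adjs)
    n = len(common_genes)
    return n - len(adj_common or set())


def pairwise_distance_matrix(
    records: list[GenomeRecord], max_blocks: int = MAX_EXACT_BLOCKS
) -> "pandas.DataFrame":  # noqa: F821
    """All-pairs inversion distances as a symmetric table."""
    import pandas as pd

    taxa = [r.taxon_id for r in records]
    mat = pd.DataFrame(0, index=taxa, columns=taxa)
    for a, b in itertools.combinations(records, 2):
        d = inversion_distance(encode_permutation(a, b), max_blocks)
        mat.loc[a.taxon_id, b.taxon_id] = d
        mat.loc[b.taxon_id, a.taxon_id] = d
    return mat
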