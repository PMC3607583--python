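"""Gene content comparison and parsimony mapping of losses and gains.

Red algal plastids retain an unusually large complement of genes of
cyanobacterial descent.  This module builds gene × taxon presence
matrices from annotated genomes, counts shared/unique cyanobacterial
genes across taxon groups (Venn-style partitions), and maps gene losses
and gains onto a fixed rooted species tree by maximum parsimony.

Genes of cyanobacterial descent are treated under Dollo parsimony: the
gene is present in the plastid ancestor (single gain at the root) and
can only be lost, possibly repeatedly.  Acquired genes (intron-encoded
maturase ORFs, horizontally transferred operons) are mapped with a
single gain anywhere on the tree — placed at the most recent common
ancestor of the carriers — plus subsequent losses.

Following the convention for Rubisco's atypical (non-cyanobacterial
sensu stricto) phylogenetic origin, ``rbcL``/``rbcS`` together with the
menaquinone operon ``menA``–``menF``, the horizontally acquired
``leuC``/``leuD``, and unknown ORFs are excluded from the cyanobacterial
gene count by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from rhodoplast.genome_io import GenomeRecord

#: Genes excluded from the cyanobacterial count by default.
DEFAULT_CYANO_EXCLUSIONS = frozenset(
    {"rbcL", "rbcS", "menA", "menB", "menC", "menD", "menE", "menF", "leuC", "leuD"}
)


class GeneContentError(ValueError):
    pass


@dataclass
class PresenceMatrix:
    """Binary gene × taxon occupancy with per-gene metadata.

    ``occupancy`` is a pandas DataFrame (index = canonical gene names,
    columns = taxon ids, values 0/1).  ``cyanobacterial_flag`` marks
    genes counted as being of cyanobacterial descent; ``gene_class``
    carries the feature class of each gene.
    """

    occupancy: pd.DataFrame
    cyanobacterial_flag: dict[str, bool]
    gene_class: dict[str, str]
    shared_orfs: set[str] = field(default_factory=set)

    @property
    def genes(self) -> list[str]:
        return list(self.occupancy.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.occupancy.columns)

    def taxa_with(self, gene: str) -> set[str]:
        row = self.occupancy.loc[gene]
        return set(row.index[row == 1])

    def species_specific_orf_counts(self) -> dict[str, int]:
        """Per-taxon ORFs found in that taxon only (shared ORFs excluded)."""
        counts = {t: 0 for t in self.taxa}
        for g in self.genes:
            if self.gene_class.get(g) != "ORF":
                continue
            carriers = self.taxa_with(g)
            if len(carriers) == 1:
                counts[next(iter(carriers))] += 1
        return counts


def build_presence_matrix(
    records: Iterable[GenomeRecord],
    exclusions: frozenset[str] | set[str] = DEFAULT_CYANO_EXCLUSIONS,
    classification: Mapping[str, bool] | None = None,
) -> PresenceMatrix:
    """Build a presence/absence matrix from name-normalised genomes.

    ``cyanobacterial_flag`` is false for excluded genes and for ORFs,
    true otherwise; *classification* overrides individual genes.  ORFs
    present in two or more taxa are recorded as shared ORFs.
    """
    records = list(records)
    taxa = [r.taxon_id for r in records]
    if len(set(taxa)) != len(taxa):
        raise GeneContentError("taxon_id collision in genome set")
    gene_class: dict[str, str] = {}
    data: dict[str, dict[str, int]] = {}
    for rec in records:
        for f in rec.features:
            if f.feature_class == "intron":
                continue
            g = f.canonical_name
            data.setdefault(g, {t: 0 for t in taxa})[rec.taxon_id] = 1
            gene_class.setdefault(g, f.feature_class)
    occupancy = pd.DataFrame.from_dict(data, orient="index")[taxa].sort_index()
    flags = {}
    for g in occupancy.index:
        flag = gene_class[g] != "ORF" and g not in exclusions
        if classification and g in classification:
            flag = bool(classification[g])
        flags[g] = flag
    shared_orfs = {
        g
        for g in occupancy.index
        if gene_class[g] == "ORF" and int(occupancy.loc[g].sum()) >= 2
    }
    return PresenceMatrix(occupancy, flags, gene_class, shared_orfs)


def matrix_from_tsv(path: str | Path) -> PresenceMatrix:
    """Read a plain genes × taxa 0/1 TSV (no class metadata: all genes
    treated as cyanobacterial protein-coding unless named ``orf*``)."""
    occ = pd.read_csv(path, sep="\t", index_col=0)
    occ = (occ > 0).astype(int)
    classes = {g: ("ORF" if str(g).lower().startswith("orf") else "protein") for g in occ.index}
    flags = {g: classes[g] != "ORF" for g in occ.index}
    return PresenceMatrix(occ, flags, classes)


def partition_counts(
    matrix: PresenceMatrix, groups: Mapping[str, str]
) -> dict[str, int]:
    """Count cyanobacterial genes in every intersection region of taxon
    groups (Venn partition) plus the union total.

    Region keys are '&'-joined sorted group names (exclusive regions:
    a gene counts in exactly the region of groups it occurs in).
    """
    labels = sorted(set(groups.values()))
    counts: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            counts["&".join(combo)] = 0
    union = 0
    for g in matrix.genes:
        if not matrix.cyanobacterial_flag.get(g, False):
            continue
        member = sorted({groups[t] for t in matrix.taxa_with(g) if t in groups})
        if not member:
            continue
        union += 1
        counts["&".join(member)] += 1
    counts["union"] = union
    return counts


# ---------------------------------------------------------------------------
# Parsimony event mapping


@dataclass
class EventMap:
    """Per-branch loss/gain events and per-node ancestral gene sets.

    Branches are addressed by the key of their child node: the
    ','-joined sorted list of descendant leaf names.  ``ambiguous``
    lists genes whose optimal event placement is not unique (possible
    only on unary chains; on strictly bifurcating trees the minimal
    placement is unique).
    """

    losses: dict[str, list[str]]
    gains: dict[str, list[str]]
    ancestral: dict[str, set[str]]
    ambiguous: set[str] = field(default_factory=set)

    def loss_count(self) -> int:
        return sum(len(v) for v in self.losses.values())

    def gain_count(self) -> int:
        return sum(len(v) for v in self.gains.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "losses": self.losses,
                "gains": self.gains,
                "ancestral": {k: sorted(v) for k, v in self.ancestral.items()},
                "ambiguous": sorted(self.ambiguous),
            },
            indent=1,
            sort_keys=True,
        )


def load_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree (path or literal newick string)."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def default_tree() -> dendropy.Tree:
    """The fixed red algal species tree used for event mapping:
    Cyanidiales sister to everything, Porphyridium sister to
    (Bangiales, florideophytes)."""
    text = (
        resources.files("rhodoplast.data").joinpath("red_algal_plastids.nwk").read_text()
    )
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _node_key(node: dendropy.Node) -> str:
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return ",".join(leaves)


def map_events(
    matrix: PresenceMatrix,
    tree: dendropy.Tree,
    modes: Mapping[str, str] | None = None,
    placement: str = "earliest",
) -> EventMap:
    """Map gene losses and gains onto *tree* by maximum parsimony.

    Cyanobacterial-flagged genes use Dollo parsimony (present at the
    root, minimum losses below); other genes get a single gain at the
    most recent common ancestor of their carriers plus minimal
    subsequent losses.  *modes* overrides per gene ('dollo'/'fitch').

    *placement* selects the rootward-most ('earliest', default) or
    leafward-most ('latest') edge when a loss can sit anywhere on a
    unary chain; such genes are flagged ambiguous.

    Raises if a matrix taxon is missing from the tree.  The event map
    replays exactly to the leaf occupancies (asserted internally).
    """
    if placement not in ("earliest", "latest"):
        raise ValueError("placement must be 'earliest' or 'latest'")
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = set(matrix.taxa) - leaf_labels
    if missing:
        raise GeneContentError(f"taxa absent from tree: {sorted(missing)}")

    nodes = list(tree.preorder_node_iter())
    keys = {id(n): _node_key(n) for n in nodes}
    losses: dict[str, list[str]] = {}
    gains: dict[str, list[str]] = {}
    ancestral: dict[str, set[str]] = {keys[id(n)]: set() for n in nodes}
    ambiguous: set[str] = set()

    for gene in matrix.genes:
        carriers = matrix.taxa_with(gene)
        mode = (modes or {}).get(
            gene, "dollo" if matrix.cyanobacterial_flag.get(gene, False) else "fitch"
        )
        if mode not in ("dollo", "fitch"):
            raise ValueError(f"unknown mode {mode!r} for gene {gene}")
        # presence-below: node has a carrier leaf among its descendants
        below: dict[int, bool] = {}
        for n in tree.postorder_node_iter():
            if n.is_leaf():
                below[id(n)] = n.taxon.label in carriers
            else:
                below[id(n)] = any(below[id(c)] for c in n.child_nodes())
        if mode == "dollo":
            origin = tree.seed_node
        else:
            origin = tree.mrca(taxon_labels=sorted(carriers)) if carriers else None
            if origin is not None and origin is not tree.seed_node:
                gains.setdefault(keys[id(origin)], []).append(gene)
            elif origin is tree.seed_node:
                gains.setdefault(keys[id(origin)], []).append(gene)
        if origin is None:
            continue
        # ancestral states: present on every node of origin's subtree
        # that still has a carrier below
        in_scope = set()
        for n in origin.preorder_iter():
            in_scope.add(id(n))
            if below[id(n)]:
                ancestral[keys[id(n)]].add(gene)
        # losses: edges from a present parent to a presence-free child
        for n in origin.preorder_iter():
            if n is origin:
                continue
            p = n.parent_node
            if below[id(p)] and not below[id(n)]:
                edge_node = n
                # a unary chain below makes the placement ambiguous
                chain_nodes = [n]
                walk = n
                while len(walk.child_nodes()) == 1:
                    walk = walk.child_nodes()[0]
                    chain_nodes.append(walk)
                if len(chain_nodes) > 1:
                    ambiguous.add(gene)
                    if placement == "latest":
                        edge_node = chain_nodes[-1]
                losses.setdefault(keys[id(edge_node)], []).append(gene)

    result = EventMap(losses, gains, ancestral, ambiguous)
    _assert_replay(result, matrix, tree)
    return result


def _assert_replay(events: EventMap, matrix: PresenceMatrix, tree: dendropy.Tree) -> None:
    """Replaying events from the root must reproduce leaf occupancies."""
    root_key = _node_key(tree.seed_node)
    root_set = set(events.ancestral.get(root_key, set()))

    def walk(node: dendropy.Node, state: set[str]) -> None:
        key = _node_key(node)
        state = set(state)
        state |= set(events.gains.get(key, []))
        state -= set(events.losses.get(key, []))
        if node.is_leaf():
            label = node.taxon.label
            if label in matrix.taxa:
                expected = {
                    g for g in matrix.genes if label in matrix.taxa_with(g)
                }
                # replay may carry genes for taxa outside the matrix; compare
                # on matrix genes only
                got = {g for g in state if g in matrix.genes}
                if got != expected:
                    raise AssertionError(
                        f"event replay mismatch at leaf {label}: "
                        f"{sorted(got ^ expected)}"
                    )
        for child in node.child_nodes():
            walk(child, state)

    # push gains at internal nodes during descent; start from root state
    walk(tree.seed_node, root_set)


def annotated_newick(events: EventMap, tree: dendropy.Tree) -> str:
    """Newick with branch labels '+g/-l' (gain/loss counts per branch)."""
    tree = tree.clone(depth=1)
    for node in tree.preorder_node_iter():
        key = _node_key(node)
        g = len(events.gains.get(key, []))
        l = len(events.losses.get(key, []))
        if g or l:
            label = f"+{g}/-{l}"
            if node.is_leaf():
                node.taxon.label = f"{node.taxon.label} {label}"
            else:
                node.label = label
    return tree.as_string(schema="newick").strip()


def brute_force_min_events(
    presence: Mapping[str, bool], tree: dendropy.Tree, mode: str
) -> int:
    """Exhaustive minimum event count for one gene (test oracle).

    Enumerates all binary state assignments to internal nodes (leaves
    fixed by *presence*), restricted to at most one gain edge (state
    0→1), with the root's state counting as a gain for 'fitch' mode and
    forced present for 'dollo'.  Returns min(gains + losses) excluding
    the obligatory Dollo root presence.
    """
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    best = None
    for bits in range(2 ** len(internal)):
        state = {}
        for i, n in enumerate(internal):
            state[id(n)] = (bits >> i) & 1
        ok = True
        for n in nodes:
            if n.is_leaf():
                state[id(n)] = 1 if presence[n.taxon.label] else 0
        if mode == "dollo" and state[id(tree.seed_node)] != 1:
            continue
        gains = losses = 0
        for n in nodes:
            if n is tree.seed_node:
                continue
            p = state[id(n.parent_node)]
            c = state[id(n)]
            if p == 0 and c == 1:
                gains += 1
            elif p == 1 and c == 0:
                losses += 1
        if mode == "dollo":
            if gains > 0:  # Dollo forbids regain below the root
                continue
            total = losses
        else:
            if state[id(tree.seed_node)] == 1:
                gains += 1  # the single origin happened at or above the root
            if gains > 1:
                continue
            total = gains + losses
        if mode == "fitch" and any(presence.values()) and gains == 0:
            continue  # carriers need one origin
        if best is None or total < best:
            best = total
    return best if best is not None else 0
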