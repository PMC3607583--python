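# Methods

This note documents the models, conventions and numerical choices
behind each stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Coordinates and genome statistics

GenBank's 1-based inclusive coordinates are converted to 0-based
half-open on input; all internal arithmetic is half-open, which makes a
spacer length simply `start(next) − end(prev)`.  Features spanning the
origin of a circular chromosome stay single features
(`wraps_origin=True`).

Intergenic spacers are measured between consecutive non-intron features
in circular order, including the wrap-around gap.  Overlapping or
nested annotations would produce negative gaps; these are clamped to 0
and kept in the median/mean, which keeps the statistic defined on
heavily nested annotation styles.  A gene with an intron counts as one
span from its outermost boundaries (intron features are tabulated
separately, not as spacers).  Multi-copy genes (duplicated rRNA operon
genes) appear once in the unique-gene count but per-copy in the feature
list.  All statistics are invariant under rotation of the circular
origin; species-specific ORF counts need the whole genome set (an ORF
shared by ≥ 2 taxa is not species-specific) and are filled in by the
gene-content stage.

Gene identities are unified through a raw→canonical synonym table
before any cross-genome comparison; unmapped names pass through
lower-cased with a warning, and `ORF`-style names are canonicalised to
`orfNNN` and classed as ORFs.

## Inversion distances

The gene order of a query genome over the single-copy genes it shares
with a reference (ORFs and multi-copy genes excluded — orthology of
extra copies is ambiguous) is a signed permutation; sign records
orientation relative to the reference strand.  Circular genomes are
linearised at a shared anchor gene (the first shared gene of the
reference), with the anchor oriented `+`; distances refer to that
linearisation.

Distance is the minimum number of signed interval reversals reaching
the identity, found exactly by iterative-deepening depth-first search.
The admissible bound is the breakpoint-graph cycle bound
d ≥ (n+1) − c, tightened by one when no reversal can increase the
cycle count (the hurdle case); a transposition table prunes re-visited
states.  Search order is leftmost-shortest reversal first, so the
reported optimal scenario is deterministic (lexicographically
smallest).  Exactness is verified in the test suite against
breadth-first search over the full reversal graph for n ≤ 7.  The
solver refuses inputs above 25 collapsed blocks; within the regime this
package targets (compact plastid genomes collapse to ≲ 15 blocks, and
planted-inversion structures are essentially hurdle-free) solutions
take milliseconds, but adversarial hurdle-rich permutations near the
guard can be much slower — the guard bounds the block count, not the
worst-case time.

Conserved gene clusters across a genome set are counted over genes
single-copy in *every* genome, on the common linearised frame: the
blocks remaining after collapsing adjacencies (order and relative
orientation) shared by all genomes.  Pairwise this equals the collapsed
block count; the count is non-decreasing as genomes are added.  The
circular closure adjacency is not counted, matching how linearised
genome maps are usually read.

## Parsimony mapping of gene content

Genes flagged as being of cyanobacterial descent (everything except
ORFs and a default exclusion list: `rbcL`, `rbcS`, `menA`–`menF`,
`leuC`, `leuD` — genes whose phylogenetic origin is atypical or
horizontally acquired) are treated as ancestral: Dollo parsimony with
the single origin fixed at the root and the minimal set of loss edges
below it.  Acquired genes get a single gain placed at the most recent
common ancestor of their carriers plus minimal subsequent losses.  Both
reconstructions are verified in the tests against exhaustive
enumeration of all state assignments on 4–6 leaf trees, and every event
map is replayed root-to-leaves and asserted to reproduce the observed
occupancies exactly.

On strictly bifurcating trees the minimal placement is unique.  Where a
unary chain makes a loss placement ambiguous, the rootward-most edge is
reported by default (`placement="latest"` switches to the leafward
extreme) and the gene is flagged ambiguous.

## Pairwise dN estimation

Two estimators, both reporting nonsynonymous substitutions per
nonsynonymous site so they agree at low divergence:

**Counting (NG86).**  Per codon position, the synonymous site fraction
is the synonymous share of the possible non-stop single-nucleotide
changes.  Differences on multi-hit codons are averaged over all minimal
mutational pathways avoiding stop intermediates (all pathways if none
avoids a stop).  Proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is flagged undefined — undefined is
never reported as zero.  The implementation is cross-checked in the
tests against an independent NG86 implementation.

**Maximum likelihood (GY94-style).**  Rate between sense codons
differing at one position: π_target · κ^[transition] ·
ω^[nonsynonymous], zero otherwise, scaled to one expected substitution
per codon per unit t.  The two-sequence log-likelihood
Σ log(π_i · P_ij(t)) is maximised over (log t, log κ, log ω) with
L-BFGS-B from a fixed four-point start grid
(t ∈ {0.1, 1}, κ = 2, ω ∈ {0.2, 1}), convergence tolerance 1e−8 on the
log-likelihood, bounds e^±9.2; transition probabilities come from a
symmetrised eigendecomposition of the reversible rate matrix.  Codon
frequencies are F3×4 from the concatenated pair (with a half-count
pseudocount so no sense codon has zero frequency); an equal-frequency
variant is available by flag.  dN is decomposed as
t·ρ_N / N̄, where ρ_N is the nonsynonymous fraction of the substitution
flow at the optimum and N̄ the π-averaged κ-weighted nonsynonymous
sites per codon (with S̄ = 3 − N̄ for dS).  Gap/ambiguity columns are
dropped pairwise, not listwise.  Identical sequences short-circuit to
t = dN = 0; all-gapped input yields a flagged undefined result.

Genetic codes: the standard code for plastid genes; the
'mold, protozoan, and coelenterate' mitochondrial code (NCBI table 4)
for the mitochondrial marker *cox1*.  The 5′ *cox1* barcode region
defaults to the first 664 coding nucleotides (the conventional barcode
amplicon length), trimmed to whole codons and overridable.

## Summaries, correlation and marker classes

Quantiles use linear interpolation between order statistics (the
convention where {1,2,3,4} gives Q1 = 1.75, Q3 = 3.25); median dN and
IQR = Q3 − Q1 are computed over defined pairwise values only, with the
undefined count logged.  The dN–IQR association is Pearson's
product-moment correlation, raw and after log2 transform of both axes
(non-positive values excluded from the log variant with a logged
count).

Genes are binned by median dN into left-closed bins
[0, 0.1) … [0.4, 0.5) and ≥ 0.5.  "Relative IQR" within each bin is
defined as tertiles of the IQR ranks (ties broken by gene name; bins
with < 3 genes put all members in LOW) — deterministic and scale-free.
A gene is unsuitable if median dN ≥ 0.5 (a median of exactly 0.5 falls
in the open top bin) or its relative IQR is HIGH.  Candidates are
LOW-IQR genes with median dN in [0.1, 0.4), length > 300 nt, present
in all taxa; genes passing everything but with dN < 0.1 are flagged as
the deep-phylogeny tier — slow genes resolve deep splits better than
they discriminate close species.

Gene selection takes protein-coding genes present in ≥ 3 of the target
taxa, excludes unknown ORFs, and admits *cox1*/5′*cox1* as extra
markers when provided.  Protein alignments may be supplied externally;
the bundled fallback aligner handles the indel-free case (equal-length
translations) exactly, which covers all simulated data.

## Synthetic data generator

The generator emulates the statistical structure the analyses consume:

* **Tree** — a fixed 10-taxon topology (two Cyanidiales as the earliest
  split, Porphyridium sister to Bangiales + florideophytes, five
  florideophytes) with branch lengths on a neutral per-site divergence
  scale (terminal branches 0.08–0.35).
* **Gene order** — 60 ancestral genes by default (a scale at which the
  full pipeline including per-pair ML fits runs in minutes; real
  genomes carry ~4× more), random strands; per branch,
  Poisson(0.5) uniform random reversals — calibrated so the most
  distant genome pairs differ by roughly three to six inversions, the
  rearrangement scale real red algal plastids show — and
  Bernoulli(0.02) Dollo losses per gene; three planted gains mirror the
  acquired-gene pattern of real red algal plastids (a maturase-like ORF
  in the florideophyte ancestor, a two-gene operon on one terminal
  branch).
* **Spacers** — log-normal with median 70 bp (σ_log = 0.6), matching
  the compact spacing of real red algal plastids (medians 56–85 bp).
* **Sequences** — per-gene codon evolution by Gillespie event sampling
  (not matrix exponentiation), so accepted synonymous/nonsynonymous
  event counts and time-integrated site counts are known exactly;
  mutations to stops are forbidden; per-position mutation weights are
  κ-weighted and normalised so a neutral site has unit rate.  Gene
  lengths are uniform in 90–240 codons; ω is log-normal
  (median 0.15, σ_log = 0.7) and a per-gene log-normal rate multiplier
  (σ_log = 0.35) scales branch lengths.  The multiplicative structure
  makes a gene's pairwise dN spread grow with its median, reproducing
  the positive dN–IQR correlation the rate screen quantifies.
* **Determinism** — one seeded generator; draws in documented order
  (gene parameters in sorted gene order, tree preorder, genes sorted
  within a branch, leaf assembly last).  Same seed ⇒ byte-identical
  output, asserted in tests.

Realized dN between two leaves is the count of accepted nonsynonymous
events on the connecting path divided by the time-averaged
nonsynonymous site count, the same κ-weighted site definition the ML
decomposition uses; recovery tests therefore run the ML estimator in
its equal-frequency variant, which matches the generator's
compositionally untargeted mutation process (F3×4 remains the default
for real data).

What the generator does **not** emulate: indels within genes (so the
fallback identity aligner is exact), intron evolution, nucleotide-level
spacer homology, rRNA/tRNA genes, base-compositional bias, and
among-site rate variation within a gene.  Passing tests demonstrate
correctness of the inference machinery under the generating model, not
robustness to alignment error or compositional heterogeneity in real
data.

## Problem sizes

Default analysis scale: 10 genomes × 60 genes; rate estimation over the
six Bangiales + florideophyte taxa (15 pairs per gene, ~150 s of ML
fits); estimator-recovery experiments use 200 replicate pairs of 300
codons at t = 0.3, ω = 0.3, κ = 2.  These sizes were chosen so a full
reproduction completes in a few minutes on one core while every
statistic remains well-resolved.

## Known limitations

* The inversion solver is exact but exponential in the worst case;
  see the guard discussion above.
* Pairwise ML assumes one (t, κ, ω) per pair — no branch or site
  models, matching the pairwise design of the rate screen; dS is
  reported but saturates quickly at these divergences and is not used
  for ranking.
* Dollo treats presence/absence only; it cannot distinguish outright
  gene loss from transfer to the nucleus — that distinction is
  biological, not computable from plastid annotations alone.
* Venn partitions and the cyanobacterial union depend on the curation
  of the input annotations and on the exclusion list; both are
  overridable, and sensitivity to curation should be assessed by
  re-running with a patched annotation set.
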