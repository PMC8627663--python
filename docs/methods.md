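# Methods

This note records the models, conventions and numerical choices behind
`linsynt`, and what the synthetic validation does and does not show.

## Coordinate and data conventions

Gene coordinates are 1-based inclusive (GFF3 convention); gene *ranks*
are 0-based indices from the left telomere, and all window/portion
arithmetic is done on ranks. Strand is stored but ignored by
adjacency-based synteny indexes; orientation enters only the DCJ
distance. Window sizes from percentages use round-half-up with a minimum
of one gene; incomplete windows at the chromosome edges are not emitted
(the replicon is linear — no wraparound). Undefined window values (e.g. a
GOC window without orthologues) are NA, written literally as `NA` in TSV.

## Synteny indexes

For a reference adjacency (gᵢ, gᵢ₊₁), conservation requires both genes
mapped and their images' ranks in the compared genome to differ by
exactly 1, in either orientation. GOC counts *genes* participating in at
least one conserved adjacency over the mapped genes of the window (this
makes every window value a fraction in [0,1]). A consequence worth
knowing: a single clean multi-gene inversion breaks exactly two
adjacencies but leaves every gene with one conserved neighbour, so
windowed GOC can remain 1; GOC responds to breakpoint *density*
(scattered shuffling, relocated genes), not to one isolated inversion.
The pair-counting alternative reading exists in the literature; the
gene-counting form was chosen for its bounded ratio and is what the
tests pin down. NOC restricts the denominator to "considered" genes —
mapped genes with at least one mapped rank-neighbour — and its windows
slide over those genes (default 5 % window, 0.1 % step), so it has no
physical anchoring and is reported by ordinal window number.

## DCJ distance

Markers are the shared orthologues of the pair (optionally restricted to
a category), renumbered by rank in the reference; each genome's sign is
its own strand with both chromosomes read left-telomere-first. The
distance is the adjacency-graph formula d = n − C − I/2. For two linear
chromosomes the restricted variant (circular intermediates must be
reabsorbed immediately) attains the same distance, so the formula is used
directly; the test suite proves it equal to an exhaustive breadth-first
search over all DCJ operations for every signed order with ≤5 markers
and 500 random 6-marker instances. Markers from families flagged
inconsistent (possible paralogy) should be excluded before extraction;
the orthology maps used here are one-to-one by construction.

## Orthology, families, pan-genome

Best hits are selected by bitscore (ties: higher identity, then smaller
subject id, for determinism); the identity/coverage/E-value filter is
applied to both directions, with coverage required of query and subject
alike. Families are connected components of the union of pairwise maps;
components with two genes from one genome are flagged, not split.
Rarefaction draws subsets without replacement, independently across the
100 iterations, from a seeded generator. Heap's law is fitted by least
squares on log pan vs log n. The core-region is the *minimal-span* rank
interval holding ⌈0.95·C⌉ of the genome's C core genes (ceiling
guarantees the fraction); among equal spans the interval whose midpoint
is closest to the chromosome midpoint wins, then the smaller start. An
exhaustive interval search over hundreds of random chromosomes confirms
the two-pointer implementation exactly.

## ANIb and TIRs

The query genome is cut into 1000 consecutive fragments (the trailing
`len % 1000` fragments take one extra base, keeping lengths within one
base of each other). A fragment contributes its best hit's identity when
the alignment is longer than 70 % of the fragment and at least 30 %
identical; no qualifying fragment means the one-way score is undefined
(None), never 0. The built-in aligner runs edlib in infix mode against
the target and its reverse complement, with identity taken from the
alignment CIGAR; any external aligner producing BLAST-tabular hits can be
injected instead. Species dereplication uses single-linkage components
of the ≥96 % relation, with the largest genome as representative.

TIR detection extends from the two termini simultaneously, comparing the
prefix with the reverse complement of the suffix: +1 per match, −10 per
mismatch, stop when the score drops 50 below its maximum; the repeat ends
at the score maximum, and the call must reach 50 bp at ≥99 % identity.
The heavy mismatch penalty makes over-extension past a planted repeat
into random flanking sequence astronomically unlikely while still
crossing isolated mismatches (a 99.8 %-identical repeat is recovered in
full). Trimming removes the right-hand copy; genes inside it are
dropped, a straddling gene is removed with a warning.

## The simulator

The ancestor holds `n_core` skeleton families confined to the central
`1 − 2·arm_fraction` rank span (interleaved at seeded random with
accessory families) and accessory-only arms. Per branch, event counts
are Poisson(rate × branch length × gene count at branch start); event
positions are drawn with probability ∝ g(x) = (2|x−0.5|)^β on relative
rank, so β = 0 is uniform and β = 3 (the default) concentrates events at
the telomeres. Inversions take two independently gradient-weighted
breakpoints, reverse the segment and flip strands; gains insert a fresh
family from a finite HGT pool (never reused, so every family has at most
one copy per genome and gene ids can equal family ids); losses remove a
gradient-weighted non-core gene — core families are loss-exempt, which
realizes the core-genome definition while still letting inversions
relocate core genes. Events within a branch apply sequentially; at the
small per-branch rates used, interactions are negligible. Per-branch
generators are seeded deterministically from (root seed, node label), and
the event log carries concrete positions so leaves replay exactly.

Sequences: every family gets a random ancestral CDS (900 bp default,
typical for actinobacterial genes) that accumulates substitutions at
`substitution_rate` per site per unit branch length down the tree;
genomes are TIR + (spacer + gene)×n + spacer + reverse-complement TIR,
with 100 bp random spacers per genome. The planted TIR is exact, and the
base immediately inboard of it is forced to break reverse-complement
extension — that is part of the planting contract, otherwise "the"
repeat length would genuinely be ambiguous by a few coincidental bases.

Default rates (gain 0.5, loss 0.5, inversion 0.05 per gene per unit
branch length) were chosen once so that, on coalescent trees rescaled to
height 0.25, the deepest leaf pairs turn over roughly half of the
ancestral accessory complement — echoing the orthology rates observed
between distant congeners with this chromosome architecture. They are
free parameters of the model, not fitted quantities.

### What the simulator does not emulate

No nucleotide-level indels, no selection, no rate heterogeneity among
families, no plasmid–chromosome exchange, no TIR-length evolution, and
spacers are resampled per genome (so intergenic regions are unrelated
between genomes, which depresses ANIb slightly relative to coding
regions). Passing tests therefore demonstrate correctness of the
*measurements* under a controlled gradient model — that the pipeline
recovers planted architecture and gradients — not that real genomes
evolve by this model.

## Regression choices

Cophenetic distances are patristic path sums from the tree. Portions
split ranks into k contiguous blocks, sizes within one gene (remainder
genes go to the trailing blocks). Per-portion indexes treat the portion
as a single window. Trends are ordinary least-squares polynomials
(degree 3 for portion trends, degree 2 for the DCJ categories); the
early slope α is a plain linear fit over points with distance ≤ 0.1 —
an explicit, robust estimator rather than the polynomial's derivative at
0. Note that a linear fit to a curved trend is biased by the curvature
(for c₂d² over [0,a] the bias is +c₂a); the tests freeze that expected
behaviour. Confidence bands use standard OLS prediction-interval
formulas; no bootstrap.

## Problem sizes

The shipped studies use 20-leaf clades of ~600-gene chromosomes (and a
compact 2-leaf clade for sequence-level analyses), chosen as the scale at
which every qualitative contrast of interest — terminal vs central
synteny, slope ordering, category-wise DCJ, pan-genome openness — is
statistically unambiguous with seeded reproducibility.
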