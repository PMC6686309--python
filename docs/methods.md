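# Methods

This note documents the models, algorithms and numerical choices behind
`plastcomp`, and what the simulator does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open on a fixed linearization of
the circular molecule; GFF3 and VCF are emitted 1-based per their
standards. Circularity is handled by explicit rotation to a shared anchor
gene (`rotate_to_anchor`, default anchor `psbA`), splitting features that
span the new origin, rather than by modular arithmetic inside every
algorithm: downstream stages then operate on plain linear strings. The
genic/intergenic partition merges overlapping features, so a position is
genic iff it lies inside any CDS/tRNA/rRNA feature and
genic + intergenic = genome length by construction.

## Inverted-repeat detection

Plastome IRs are kilobases long and near-exact, so detection seeds exact
25-mers between the doubled sequence (wrap-awareness) and its reverse
complement, merges co-diagonal seeds across gaps within the mismatch
budget (default ≤ 2% of the arm), verifies the merged arms by direct
comparison, and keeps the longest candidate (ties: smaller first-arm
start). Absence of any pair ≥ `ir_min_len` (default 1,000 bp) is a normal
result (`None`), not an error. Boundary gene orders take the two nearest
features outside each arm on each side, in coordinate order, wrapping
around the origin; features straddling an arm edge are excluded with a
warning. Translocation calls compare each species' gene→(arm, side)
assignments against the per-gene majority; a gene attached to the
opposite arm relative to the majority is reported as
"*gene* at other IR". With no majority configuration at all, no calls are
made.

Pseudogene assessment aligns the locus to an intact reference CDS
(local alignment, match 2 / mismatch −1 / gap −5/−1). The verdict is
`pseudogene_5prime_truncated` when the alignment covers < 80% of the
reference, starts after ≥ 20% of its 5′ end, and no in-frame start codon
appears among locus positions aligning within the first 30% of the
reference (all three thresholds configurable). This truncation test takes
precedence over `internal_stop`: a locus missing its start region is
classified by the dominant structural defect even if the remainder also
carries a nonsense change. Near-full coverage with a start codon and no
in-frame stop is `intact`; anything else `other_defect`.

## Synteny mapping

Maximal exact matches ≥ k (default k = 20) come from a k-mer index with
per-diagonal seed skipping; both strands are scanned. Chaining is a
maximum-weight increasing-subsequence dynamic programme on
(ref_start, qry_start), weighted by anchor length with a 0.05/base penalty
on diagonal shift; links whose gap exceeds `max_gap` (default 5,000 bp) on
either genome are forbidden, which is what separates chains. Chains are
extracted best-first.

Gaps between consecutive anchors are closed by affine-gap global
alignment (match 1 / mismatch −1 / open −3 / extend −1); equal-length gaps
≤ 30 bp are aligned column-wise. The affine preference means an isolated
substitution is never explained as an insertion-deletion pair, and a
contiguous indel is never split — the realistic mutational reading of a
plastome alignment. A gap whose diagonal shift exceeds `band_limit`
(default 100 bp) is treated as a structural break: the chain is split
there and the discontinuity surfaces as a breakpoint. Chains are extended
to the sequence ends when the terminal overhangs are compatible. Segment
identity = matched columns / aligned columns; segments below the identity
threshold (default 0.90) or shorter than `min_segment` are dropped, and a
segment whose reference interval is contained in a longer one is removed —
this is what removes the duplicate match of the second IR copy. Reverse-
strand segments are scored and reported (they signal inversions) but are
not used for variant calling. Breakpoints are the maximal reference
intervals not covered by retained plus-strand segments; a zero-length
breakpoint marks a pure query-side insertion.

## Variant calling

Variants are read directly off the retained plus-strand segment
alignments: mismatch columns → SNPs; gap runs (adjacent insertion and
deletion ops merged) → indels, expressed VCF-style with a left anchor base
and left-normalized against the reference. Indels longer than
`small_indel_max` (default 10 bp, the practical detection range of the
short-read approach the table semantics come from) are retained but
flagged large. Region class comes from the reference annotation. Window
densities count SNPs only, summed over species, in non-overlapping
`window_size` windows (default 1,000 bp; last window short).

When scoring calls against the simulator truth, SNPs must match exactly on
(position, ref, alt); small indels match by type and length within ±10 bp.
The tolerance exists because an indel adjacent to a SNP admits several
equal-cost alignment representations, and neither the simulator's nor the
caller's choice is privileged — distance-based matching is the standard
benchmarking remedy.

## Cross-species accounting

Sharing is exclusive: unique / exactly-two-species pairs / multi (≥ 3),
partitioning the distinct SNPs. Because calls are made against a
reference genome, a mutation on the reference's own lineage appears as a
SNP shared by all other species and lands in the multi class; pattern
compatibility checks therefore accept a pattern whose complement is a
clade. Codon effects mutate the reference codon at the SNP's in-codon
offset (strand-aware, genetic code table 11); SNPs in non-CDS features or
pseudo-flagged CDS are noncoding, and multi-SNP codons are evaluated
per-SNP against the reference codon background. "Different codon changes"
counts codons where at least two species carry nonsynonymous alleles
producing different amino acids. MNP pairs are adjacent same-species SNP
positions (a run of k adjacent SNPs gives k−1 pairs); a pair is genic only
if both positions are genic, boundary-spanning pairs count intergenic
(logged); a shared pair requires both species to carry both SNPs with
identical alternate alleles. Printed-style rates round half away from
zero to one decimal. dN/dS is Nei–Gojobori with pathway averaging over
multi-hit codons (pathways through stop codons excluded unless all are),
stop-creating changes counted nonsynonymous in the site fractions, and
Jukes–Cantor correction; the ratio is undefined at dS = 0. tRNA loci are
clustered by reference-projected start position with a ±200 bp tolerance
(single-linkage along the reference; loci falling in breakpoints form
flagged unplaced clusters).

## Phylogeny

Genes present exactly once and non-pseudo in every species are extracted
strand-corrected and aligned by reference-anchored pairwise global
alignment (match 1 / mismatch −1 / open −4 / extend −1), merged on
reference columns with insertions stacked per reference gap — adequate at
the few-percent divergences of congeneric plastomes, where a full
progressive aligner would add cost without changing columns. Genes are
concatenated in reference genome order (complete-taxa genes only) with a
partition table. Distances are TN93 with pairwise deletion of gap/N
columns and base frequencies estimated from each sequence pair; the
discrete-Γ rate correction (default shape α = 0.2099, the shape fitted in
the kelp analysis this package re-implements) replaces each −c·ln(e) term
by c·α·(e^(−1/α) − 1); a non-positive logarithm argument returns +∞
(saturation). Neighbor joining is canonical, with Q-criterion ties broken
by taxon label order and negative branch lengths clamped to zero with the
deficit moved to the sister branch. Bootstrap resamples columns with
replacement; per-pair column category codes (identical / A↔G / C↔T /
transversion / excluded) make each replicate a bincount, with base
frequencies taken from the full alignment (composition is stable under
resampling). Support = % of replicates containing each original internal
bipartition. A distance-NJ tree with bootstrap was chosen over a full
maximum-likelihood search: at ≤ 3.3% divergence and a handful of taxa the
topology and supports are insensitive to the estimator, and ML searches
are themselves seeded from NJ trees.

## The simulator

`generate_ancestor` builds the quadripartite layout explicitly: LSC genes
(anchor `psbA` at position 0) … `rpl32`, `trnL` | IRa (16S rRNA, tRNA-Ile,
tRNA-Ala, 23S, 5S on +) | `rpl21`, `rpl3`, SSC … `ycf17` | IRb (exact
reverse complement) | `ycf37`, `psaM`, remaining LSC genes. CDS are
random open reading frames (start codon, no internal stop, stop codon)
with jittered lengths rescaled to hit the genic budget; spacer lengths are
multinomial with a 30 bp floor so the genome length and intergenic
fraction are met exactly.

Evolution along the tree (preorder; events in position order; one RNG
stream per run) draws per-branch Poisson substitution counts at rate =
branch length × site weight, with IR sites down-weighted by
`ir_rate_factor` (default 0.05). Substitutions are K2P-with-frequencies:
transition with probability κ/(κ+2) (default κ = 2), otherwise a
frequency-weighted transversion. Sites mutate at most once anywhere in the
tree (infinite-sites regime): this matches the single-origin reading of
shared SNPs, makes sharing patterns exactly analysable, and is a good
approximation at ≤ 3.3% divergence where multiple hits are rare. A
fraction `mnp_fraction` (default 0.02) of events mutates two adjacent
sites. IR events are mirrored into the other arm (concerted evolution), so
arms stay exact reverse complements and the observable IR site density is
2 × `ir_rate_factor` of background. Indels (rate 0.01 events/site/branch
unit, geometric lengths capped at 10 bp) fall intergenic with probability
0.9, never inside IRs, and genic indels are codon-multiples so leaf CDS
stay in frame. A fraction `ils_fraction` of substitution events receives a
random tree-incompatible leaf pattern — reproducing the observable
(scattered sharing) of incomplete lineage sorting without simulating
heteroplasmy or recombination explicitly. Translocations excise the gene
together with its arm-side spacer and re-insert it at the equivalent flank
of the other arm (spacer staying arm-adjacent, so an untruncated move is
exactly self-inverse); a positive `truncate_fraction` deletes that share
of the 5′ end, start codon included, and flags the feature pseudo.

The default tree,
`(((L_digitata:0.014,L_solidungula:0.014):0.002,S_japonica:0.015):0.001,(C_costata:0.016,U_pinnatifida:0.017):0.001)`,
was chosen once so that realized whole-genome pairwise divergence (IRs
nearly invariant) lands in the 2.5–3.3% band reported for kelp plastome
pairs; the indel and MNP rates put indel and adjacent-pair counts at the
few-percent-of-SNPs order seen there.

What the simulator does **not** emulate: rate heterogeneity among sites
(the Γ correction in the distance stage is therefore conservative on
simulated data), selection (substitutions are neutral, so simulated n/s
ratios sit near the random expectation of ~3:1 nonsynonymous:synonymous
rather than the purifying <1:5 seen in real plastomes — the published
count tables carry that structure instead), tRNA gain/loss, IR
expansion/contraction, recombination, and sequencing error. Passing tests
on simulated data therefore demonstrate the correctness of the
bookkeeping and algorithms at realistic scale and divergence, not
robustness to assembly artifacts in real data.

## Problem sizes and determinism

The test-suite and acceptance-script simulations use the full 130 kb
geometry for variant-calling, IR, sharing and translocation checks
(3–20 replicates), and a 40 kb / 40-CDS geometry for the 30-replicate
topology-recovery sweep and unit fixtures, sizes chosen to keep the whole
suite in the tens of seconds while leaving every statistic comfortably
sized (thousands of SNPs per genome pair). All randomness flows from a
single integer seed (NumPy Generator; derived stream seeds stay below
2³¹), and identical configuration + seed reproduces byte-identical
outputs, including the order of events within a branch.

## Known limitations

Genomes with large-scale rearrangements beyond IR-flank translocations
violate the collinearity assumption of the variant caller (affected
regions surface as breakpoints and produce no calls there). The
reference-anchored gene aligner assumes genes alignable end-to-end; highly
diverged or partially deleted genes should be excluded upstream. The
exclusive sharing scheme means reference-lineage mutations appear in the
multi class rather than as a reference-species row. dN/dS is a counting
estimate, not an ML codon model, and is reported per gene pair without
multiple-testing machinery.
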