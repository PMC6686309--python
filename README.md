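# plastcomp

Comparative analysis of collinear chloroplast genomes (plastomes), built
around the questions raised by kelp (Laminariales) plastome comparisons:

* **Inverted-repeat (IR) structure** — locate the two reverse-complement
  repeat arms, read off the gene order at their boundaries, call
  IR-flank gene translocations across species by majority rule, and
  classify a translocated locus as intact or a 5′-truncated pseudogene.
* **Collinearity (synteny) mapping** — nucmer-style anchor finding,
  collinear chaining, identity-filtered segments (default threshold 90%)
  and breakpoint reporting between any two plastomes.
* **Variant extraction** — SNPs and small indels called directly from the
  segment alignments against a designated reference, classified genic /
  intergenic, with per-kilobase densities, 1 kb window counts,
  unique/shared (two-species) sharing matrices, synonymous vs
  nonsynonymous classification (plastid/bacterial code, table 11),
  adjacent-SNP (MNP) pair tables, and per-gene Nei–Gojobori dN/dS.
* **Phylogeny** — shared-CDS extraction, reference-anchored gene
  alignment, concatenation, Tamura–Nei (TN93) distances with a discrete-Γ
  rate correction (default shape α = 0.2099), neighbor joining and column
  bootstrap.
* **A plastome-evolution simulator** — generates an ancestral ~130 kb
  quadripartite genome (two ~5.4 kb IRs carrying the rRNA operon, 139
  CDS, ~17% intergenic) and evolves it along a phylogeny with concerted
  IR evolution, suppressed IR substitution rates, MNP doublets, small
  intergenically-enriched indels, optional tree-discordant ("incomplete
  lineage sorting") site patterns and IR-flank translocations — with a
  complete per-event truth log for validating every stage.

The package is aimed at organelle comparative genomics: given per-species
FASTA + GFF3 (CDS/tRNA/rRNA) annotations of collinear plastomes it
reproduces the full table set of a five-species comparison; given nothing
it simulates one with known ground truth.

## The statistics at the core

SNP identity across species is the tuple (position, reference allele,
alternate allele) on one shared reference. Sharing is *exclusive*: a SNP
is unique (one species), pairwise-shared (exactly two), or multi (three or
more, tallied separately), so the three classes partition the SNP set.
Under a single-origin interpretation of shared SNPs, every presence
pattern should be a clade of the species tree; tree-incompatible patterns
are the signature of incomplete lineage sorting, and the simulator can
inject them at a controlled rate.

Coding SNPs are classified by mutating the reference codon in place
(strand-aware). Per-gene selection is screened with the Nei–Gojobori
method: per-codon synonymous/nonsynonymous site fractions averaged over
the pair, pathway-averaged difference counts for multi-hit codons, and
the Jukes–Cantor correction, giving dN/dS (undefined when dS = 0).

Distances for the phylogeny use TN93 with the Γ-rates correction
(each −c·ln(e) term becomes c·α·(e^(−1/α) − 1)); trees come from
canonical neighbor joining with deterministic tie-breaks, supports from
resampling alignment columns.

## Worked example

```
plastcomp run --config examples/demo.yaml --out demo_out
```

simulates five 40 kb kelp-like plastomes (seed 42) and runs every stage.
`demo_out/structure.tsv` then contains one row per species:

```
species        length_bp  ir_length_bp  boundaries                                            rearrangements
C_costata      39991      2002          rpl32-trnL-IR-rpl21-rpl3 cds008-ycf17-IR-ycf37-psaM
L_digitata     40024      2002          rpl32-trnL-IR-rpl21-rpl3 cds008-ycf17-IR-ycf37-psaM
...
```

i.e. every genome kept the ancestral boundary order (add a
`translocation_events` entry to the simulate block to see a
"`ycf37 at other IR`" call appear). `demo_out/density.tsv` holds the
genic/intergenic SNP densities per species, e.g.

```
species     genic_snps  intergenic_snps  ...  snp_per_kb_genic  snp_per_kb_intergenic
C_costata   992         221                   29.9              32.5
```

— SNP rates per kb are comparable between genic and intergenic sequence,
while `window_density.tsv` shows the IR windows nearly devoid of
variation (the simulator suppresses the IR substitution rate 20-fold).
`tree.nwk` and `supports.tsv` give the bootstrapped phylogeny; on this
data both true bipartitions — the two *Laminaria* together, and
*C. costata* with *U. pinnatifida* — are recovered with 100% support.

Every stage is also available as a library function
(`plastcomp.synteny.synteny_map`, `plastcomp.variants.call_variants`,
`plastcomp.comparative.gene_dnds`, `plastcomp.phylo.nj_tree`, ...) and as
individual subcommands (`plastcomp simulate | ir | synteny | variants |
compare | phylo`).

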