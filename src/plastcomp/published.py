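"""Published summary counts from a five-species kelp plastome comparison.

These are the printed per-species / per-pair tallies of a comparative
study of the chloroplast genomes of *Saccharina japonica* (the reference),
*Costaria costata*, *Undaria pinnatifida*, *Laminaria digitata* and
*Laminaria solidungula*.  They serve as fixed inputs for the summary
arithmetic (density rates, synonymous/nonsynonymous ratios, adjacent-SNP
pair checksums) that the pipeline's reporting operations reproduce.
"""

SPECIES = [
    "S_japonica",
    "C_costata",
    "U_pinnatifida",
    "L_solidungula",
    "L_digitata",
]

#: genome length, genic/intergenic region lengths (bp) and SNP counts per
#: region, each species mapped against the S. japonica reference.
REGION_COUNTS = {
    "S_japonica": dict(genome_bp=130_584, genic_bp=108_847,
                       intergenic_bp=21_737, genic_snps=None,
                       intergenic_snps=None),
    "C_costata": dict(genome_bp=129_947, genic_bp=108_550,
                      intergenic_bp=21_397, genic_snps=3_615,
                      intergenic_snps=688),
    "U_pinnatifida": dict(genome_bp=130_383, genic_bp=108_751,
                          intergenic_bp=21_632, genic_snps=3_633,
                          intergenic_snps=626),
    "L_solidungula": dict(genome_bp=130_398, genic_bp=108_730,
                          intergenic_bp=21_668, genic_snps=2_825,
                          intergenic_snps=429),
    "L_digitata": dict(genome_bp=130_376, genic_bp=108_647,
                       intergenic_bp=21_729, genic_snps=2_961,
                       intergenic_snps=566),
}

#: coding-region SNPs per category: (category, all, synonymous,
#: nonsynonymous, printed n/s %).  Categories are species (SNPs unique to
#: that species) and species pairs (exclusively shared SNPs).
CODING_SNP_COUNTS = [
    ("S_japonica", 714, 610, 104, 17.0),
    ("C_costata", 1596, 1448, 148, 10.2),
    ("U_pinnatifida", 1602, 1352, 250, 18.5),
    ("L_solidungula", 569, 509, 60, 11.8),
    ("L_digitata", 672, 600, 72, 12.0),
    ("S_japonica and C_costata", 224, 197, 27, 13.7),
    ("S_japonica and U_pinnatifida", 404, 390, 14, 3.6),
    ("S_japonica and L_digitata", 159, 151, 8, 5.3),
    ("S_japonica and L_solidungula", 143, 142, 1, 0.7),
    ("C_costata and U_pinnatifida", 492, 448, 44, 9.8),
    ("C_costata and L_solidungula", 207, 204, 3, 1.5),
    ("C_costata and L_digitata", 177, 162, 15, 9.3),
    ("U_pinnatifida and L_digitata", 141, 127, 14, 11.0),
    ("U_pinnatifida and L_solidungula", 118, 100, 18, 18.0),
    ("L_digitata and L_solidungula", 432, 391, 41, 10.5),
]

#: printed Sum row of the coding-SNP table and the different-codon-change
#: tally (codons hit by different nonsynonymous SNPs in different species).
CODING_SNP_SUM = ("Sum", 7650, 6831, 819, 12.0)
DIFFERENT_CODON_CHANGES = 260

#: adjacent-SNP (multinucleotide polymorphism) pair counts:
#: category -> (genic pairs, intergenic pairs).
MNP_PAIR_COUNTS = {
    "S_japonica": (7, 0),
    "C_costata": (39, 42),
    "U_pinnatifida": (31, 31),
    "L_solidungula": (10, 11),
    "L_digitata": (9, 15),
    "S_japonica and C_costata": (0, 0),
    "S_japonica and U_pinnatifida": (4, 3),
    "S_japonica and L_digitata": (0, 3),
    "S_japonica and L_solidungula": (2, 0),
    "C_costata and U_pinnatifida": (5, 3),
    "C_costata and L_solidungula": (7, 1),
    "C_costata and L_digitata": (0, 2),
    "U_pinnatifida and L_digitata": (0, 0),
    "U_pinnatifida and L_solidungula": (1, 0),
    "L_digitata and L_solidungula": (2, 6),
}

#: selected printed density rates used as spot checks:
#: (species, column, value) where column is one of the rate columns.
PRINTED_DENSITY_CHECKS = [
    ("C_costata", "snp_per_kb_genic", 33.3),
    ("U_pinnatifida", "snp_per_kb_intergenic", 28.9),
    ("L_solidungula", "snp_per_kb_genic", 26.0),
]
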