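"""Cross-species SNP accounting and per-gene selection screening.

SNP identity across species is (position, ref allele, alt allele) on one
shared reference.  Sharing is exclusive: a SNP counts as unique if present
in exactly one species, toward a pair cell if present in exactly two, and
toward the multi tally when in three or more — so every SNP contributes to
exactly one cell.  Coding SNPs are classified synonymous/nonsynonymous by
mutating the reference codon (strand-aware, plastid/bacterial genetic code
by default).  dN/dS uses Nei-Gojobori site counting with pathway averaging
and the Jukes-Cantor correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Optional, Sequence

import dendropy

from .core import (
    CircularGenome,
    Feature,
    GenomeAnnotation,
    PlastcompError,
    VariantCall,
)

from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger("plastcomp")


def round_half_away(x: float, digits: int = 1) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10 ** digits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# Share matrix
# ---------------------------------------------------------------------------

@dataclass
class ShareMatrix:
    """Unique / pairwise-shared / multi-species SNP partition."""

    species: list[str]
    unique_counts: dict[str, int]
    pair_counts: dict[frozenset, int]
    multi_counts: int
    # (pos, ref, alt) -> frozenset of carrying species
    patterns: dict[tuple, frozenset] = field(default_factory=dict, repr=False)

    @property
    def total(self) -> int:
        return (sum(self.unique_counts.values())
                + sum(self.pair_counts.values()) + self.multi_counts)

    def category_of(self, key: tuple) -> Optional[object]:
        """'species', frozenset pair, or 'multi' for a SNP key."""
        pat = self.patterns.get(key)
        if pat is None:
            return None
        if len(pat) == 1:
            return next(iter(pat))
        if len(pat) == 2:
            return pat
        return "multi"


def build_share_matrix(calls: Sequence[VariantCall]) -> ShareMatrix:
    """Partition SNPs by their cross-species presence pattern."""
    refs = {c.ref_id for c in calls}
    if len(refs) > 1:
        raise PlastcompError(f"calls against mixed references: {sorted(refs)}")
    species = sorted({c.species for c in calls})
    patterns: dict[tuple, set] = {}
    for c in calls:
        if c.var_type != "SNP":
            continue
        patterns.setdefault(c.key, set()).add(c.species)
    unique = {sp: 0 for sp in species}
    pairs = {frozenset(p): 0 for p in combinations(species, 2)}
    multi = 0
    frozen: dict[tuple, frozenset] = {}
    for key, pat in patterns.items():
        fpat = frozenset(pat)
        frozen[key] = fpat
        if len(fpat) == 1:
            unique[next(iter(fpat))] += 1
        elif len(fpat) == 2:
            pairs.setdefault(fpat, 0)
            pairs[fpat] += 1
        else:
            multi += 1
    return ShareMatrix(species=species, unique_counts=unique,
                       pair_counts=pairs, multi_counts=multi, patterns=frozen)


def pattern_concordance(share: ShareMatrix, tree: dendropy.Tree
                        ) -> tuple[int, int]:
    """(concordant, total) SNP presence patterns judged against the tree.

    A pattern is concordant when it, or its complement over all leaves
    (the reference species carries the derived allele in that case), forms
    a clade — i.e. the site is compatible with the tree.
    """
    from .simulate import _compatible_patterns

    compatible = _compatible_patterns(tree)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ok = total = 0
    for pat in share.patterns.values():
        total += 1
        if pat in compatible or (leaves - pat) in compatible:
            ok += 1
    return ok, total


# ---------------------------------------------------------------------------
# Codon effects
# ---------------------------------------------------------------------------

def codon_effect(
    call: VariantCall,
    annotation: GenomeAnnotation,
    reference: CircularGenome,
    code_table: int = 11,
) -> str:
    """'synonymous' | 'nonsynonymous' | 'noncoding' for a SNP.

    The reference codon containing the SNP is mutated in place (strand-
    aware) and the translations compared.  SNPs outside CDS features, in
    non-CDS features, or in pseudo-flagged CDS are noncoding.
    """
    if call.var_type != "SNP":
        raise PlastcompError("codon_effect is defined for SNPs only")
    feat = _containing_cds(annotation, call.pos)
    if feat is None:
        return "noncoding"
    if feat.pseudo:
        logger.info("SNP at %d falls in pseudo-flagged CDS %s: noncoding",
                    call.pos, feat.gene_name)
        return "noncoding"
    table = CodonTable.unambiguous_dna_by_id[code_table]
    if feat.strand == "+":
        off = call.pos - feat.start
        codon_start = feat.start + (off // 3) * 3
        codon = reference.seq[codon_start:codon_start + 3]
        in_codon = off % 3
        ref_base, alt_base = call.ref_allele, call.alt_allele
    else:
        off = feat.end - 1 - call.pos  # distance from the 5' end on '-'
        codon_index = off // 3
        in_codon = off % 3
        codon_end = feat.end - codon_index * 3
        codon = str(Seq(reference.seq[codon_end - 3:codon_end]).reverse_complement())
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        ref_base, alt_base = comp[call.ref_allele], comp[call.alt_allele]
    if len(codon) < 3:
        return "noncoding"  # SNP in a codon clipped by a feature split
    if codon[in_codon] != ref_base:
        logger.warning("reference codon mismatch at %d (gene %s)",
                       call.pos, feat.gene_name)
    mutated = codon[:in_codon] + alt_base + codon[in_codon + 1:]

    def aa(c: str) -> str:
        return "*" if c in table.stop_codons else table.forward_table[c]

    return "synonymous" if aa(codon) == aa(mutated) else "nonsynonymous"


def _containing_cds(annotation: GenomeAnnotation, pos: int) -> Optional[Feature]:
    for f in annotation.features:
        if f.kind == "CDS" and f.start <= pos < f.end:
            return f
    return None


# ---------------------------------------------------------------------------
# Synonymous / nonsynonymous summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NsRow:
    category: str
    all: int
    synonymous: int
    nonsynonymous: int
    ratio_percent: float


@dataclass
class NsSummary:
    rows: list[NsRow]
    sum_row: NsRow
    different_codon_changes: int


def ns_row(category: str, synonymous: int, nonsynonymous: int) -> NsRow:
    ratio = (round_half_away(100.0 * nonsynonymous / synonymous, 1)
             if synonymous else float("nan"))
    return NsRow(category=category, all=synonymous + nonsynonymous,
                 synonymous=synonymous, nonsynonymous=nonsynonymous,
                 ratio_percent=ratio)


def summarize_ns_rows(rows: Sequence[tuple[str, int, int]],
                      different_codon_changes: int = 0) -> NsSummary:
    """Assemble per-category rows plus the Sum row from (category, syn,
    nonsyn) counts, applying the one-decimal rounding rule."""
    out = [ns_row(cat, s, n) for cat, s, n in rows]
    tot_s = sum(r.synonymous for r in out)
    tot_n = sum(r.nonsynonymous for r in out)
    return NsSummary(rows=out, sum_row=ns_row("Sum", tot_s, tot_n),
                     different_codon_changes=different_codon_changes)


def ns_summary(
    calls: Sequence[VariantCall],
    share: ShareMatrix,
    annotation: GenomeAnnotation,
    reference: CircularGenome,
    code_table: int = 11,
) -> NsSummary:
    """Coding-SNP synonymous/nonsynonymous table with one row per species
    (unique SNPs) and per species pair (exclusively shared SNPs)."""
    effect: dict[tuple, str] = {}
    codon_hits: dict[tuple[str, int], list[tuple[str, str]]] = {}
    table = CodonTable.unambiguous_dna_by_id[code_table]
    seen: set[tuple] = set()
    for c in calls:
        if c.var_type != "SNP" or c.key in seen:
            continue
        seen.add(c.key)
        eff = codon_effect(c, annotation, reference, code_table)
        effect[c.key] = eff
        if eff == "nonsynonymous":
            feat = _containing_cds(annotation, c.pos)
            if feat.strand == "+":
                codon_index = (c.pos - feat.start) // 3
            else:
                codon_index = (feat.end - 1 - c.pos) // 3
            alt_aa = _mutated_aa(c, feat, reference, table)
            for sp in share.patterns.get(c.key, frozenset()):
                codon_hits.setdefault((feat.gene_name, codon_index), []) \
                    .append((sp, alt_aa))

    def counts_for(keys) -> tuple[int, int]:
        s = sum(1 for k in keys if effect.get(k) == "synonymous")
        n = sum(1 for k in keys if effect.get(k) == "nonsynonymous")
        return s, n

    by_cat: dict[object, list[tuple]] = {}
    for key in effect:
        cat = share.category_of(key)
        by_cat.setdefault(cat, []).append(key)

    rows: list[tuple[str, int, int]] = []
    for sp in share.species:
        s, n = counts_for(by_cat.get(sp, []))
        rows.append((sp, s, n))
    for pair in sorted(share.pair_counts, key=lambda p: tuple(sorted(p))):
        s, n = counts_for(by_cat.get(pair, []))
        rows.append((" and ".join(sorted(pair)), s, n))

    different = 0
    for hits in codon_hits.values():
        aa_by_species: dict[str, set[str]] = {}
        for sp, aa in hits:
            aa_by_species.setdefault(sp, set()).add(aa)
        aas = set()
        for sp, aa_set in aa_by_species.items():
            aas |= {(sp, a) for a in aa_set}
        distinct_aas = {a for _sp, a in aas}
        if len(distinct_aas) >= 2 and len(aa_by_species) >= 2:
            different += 1
    return summarize_ns_rows(rows, different_codon_changes=different)


def _mutated_aa(call: VariantCall, feat: Feature, reference: CircularGenome,
                table) -> str:
    if feat.strand == "+":
        off = call.pos - feat.start
        codon_start = feat.start + (off // 3) * 3
        codon = reference.seq[codon_start:codon_start + 3]
        in_codon = off % 3
        alt = call.alt_allele
    else:
        off = feat.end - 1 - call.pos
        codon_index = off // 3
        in_codon = off % 3
        codon_end = feat.end - codon_index * 3
        codon = str(Seq(reference.seq[codon_end - 3:codon_end]).reverse_complement())
        alt = {"A": "T", "T": "A", "C": "G", "G": "C"}[call.alt_allele]
    mutated = codon[:in_codon] + alt + codon[in_codon + 1:]
    return "*" if mutated in table.stop_codons else table.forward_table[mutated]


# ---------------------------------------------------------------------------
# Multinucleotide (adjacent SNP) pairs
# ---------------------------------------------------------------------------

@dataclass
class MnpTable:
    """Genic/intergenic adjacent-SNP-pair counts per category (species or
    exclusively-sharing species pair)."""

    rows: dict[object, tuple[int, int]]  # category -> (genic, intergenic)

    @property
    def genic_total(self) -> int:
        return sum(g for g, _ in self.rows.values())

    @property
    def intergenic_total(self) -> int:
        return sum(i for _, i in self.rows.values())


def find_mnp_pairs(
    calls: Sequence[VariantCall],
    annotation: GenomeAnnotation,
) -> MnpTable:
    """Adjacent-SNP pairs per species, categorized by the exclusive sharing
    scheme.

    Within one species, a pair is two SNPs at adjacent reference positions;
    a run of k adjacent SNPs yields k-1 pairs.  A pair is genic only if
    both positions are genic; mixed pairs count as intergenic (logged).  A
    pair shared between two species requires both species to carry both
    SNPs with identical alt alleles; pairs carried by three or more
    species are tallied under 'multi'.
    """
    by_species: dict[str, dict[int, VariantCall]] = {}
    for c in calls:
        if c.var_type != "SNP":
            continue
        by_species.setdefault(c.species, {})[c.pos] = c
    # collect every pair with its carrying species
    pair_species: dict[tuple, set[str]] = {}
    for sp, posmap in by_species.items():
        for pos in sorted(posmap):
            if pos + 1 in posmap:
                key = (pos, posmap[pos].alt_allele, posmap[pos + 1].alt_allele)
                pair_species.setdefault(key, set()).add(sp)
    genic = annotation.genic_mask()
    rows: dict[object, list[int]] = {}
    for (pos, _a1, _a2), carriers in pair_species.items():
        both_genic = bool(genic[pos] and genic[pos + 1])
        if genic[pos] != genic[pos + 1]:
            logger.info("MNP pair at %d spans a genic/intergenic boundary; "
                        "counted intergenic", pos)
        if len(carriers) == 1:
            cat: object = next(iter(carriers))
        elif len(carriers) == 2:
            cat = frozenset(carriers)
        else:
            cat = "multi"
        row = rows.setdefault(cat, [0, 0])
        row[0 if both_genic else 1] += 1
    return MnpTable(rows={k: (v[0], v[1]) for k, v in rows.items()})


# ---------------------------------------------------------------------------
# Density table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityRow:
    species: str
    genic_snps: int
    intergenic_snps: int
    genic_bp: int
    intergenic_bp: int
    intergenic_genic_ratio: Optional[float]
    snp_per_kb_genic: Optional[float]
    snp_per_kb_intergenic: Optional[float]


def density_rates(species: str, genic_snps: int, intergenic_snps: int,
                  genic_bp: int, intergenic_bp: int) -> DensityRow:
    """Per-species SNP density rates, one decimal (kb = bp/1000); undefined
    rates (zero-length region) are reported as None."""
    ratio = (round_half_away(intergenic_snps / genic_snps, 1)
             if genic_snps else None)
    per_kb_g = (round_half_away(1000.0 * genic_snps / genic_bp, 1)
                if genic_bp else None)
    per_kb_i = (round_half_away(1000.0 * intergenic_snps / intergenic_bp, 1)
                if intergenic_bp else None)
    return DensityRow(species=species, genic_snps=genic_snps,
                      intergenic_snps=intergenic_snps, genic_bp=genic_bp,
                      intergenic_bp=intergenic_bp,
                      intergenic_genic_ratio=ratio,
                      snp_per_kb_genic=per_kb_g,
                      snp_per_kb_intergenic=per_kb_i)


def density_table(
    calls: Sequence[VariantCall],
    annotations: dict[str, GenomeAnnotation],
) -> list[DensityRow]:
    """Genic/intergenic SNP counts and rates per species.  Region lengths
    are taken from each species' own annotation; counts are against the
    shared reference."""
    by_species: dict[str, list[VariantCall]] = {}
    for c in calls:
        if c.var_type == "SNP":
            by_species.setdefault(c.species, []).append(c)
    rows = []
    for sp in sorted(by_species):
        ann = annotations[sp]
        genic = sum(1 for c in by_species[sp] if c.region == "genic")
        inter = len(by_species[sp]) - genic
        rows.append(density_rates(sp, genic, inter,
                                  ann.genic_length, ann.intergenic_length))
    return rows


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS
# ---------------------------------------------------------------------------

def _codon_site_fractions(codon: str, table) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon: at each
    position, the fraction of the three possible changes preserving the
    amino acid (changes creating a stop count as nonsynonymous)."""
    def aa(c):
        return "*" if c in table.stop_codons else table.forward_table[c]

    ref_aa = aa(codon)
    syn = 0.0
    for i in range(3):
        s = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            if aa(codon[:i] + b + codon[i + 1:]) == ref_aa:
                s += 1
        syn += s / 3.0
    return syn, 3.0 - syn


def _pathway_diffs(c1: str, c2: str, table) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts
    between two codons; pathways through stop codons are excluded unless
    all pass through one."""
    def aa(c):
        return "*" if c in table.stop_codons else table.forward_table[c]

    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = c1
        syn = non = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if aa(nxt) == "*" and nxt != c2:
                through_stop = True
            if aa(nxt) == aa(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        results.append((syn, non, through_stop))
    valid = [(s, n) for s, n, t in results if not t]
    if not valid:
        valid = [(s, n) for s, n, _t in results]
    syn = sum(s for s, _ in valid) / len(valid)
    non = sum(n for _, n in valid) / len(valid)
    return syn, non


@dataclass(frozen=True)
class DnDsResult:
    gene: str
    dn: float
    ds: float
    ratio: Optional[float]  # None when dS == 0 (undefined)
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def gene_dnds(ref_cds: str, qry_cds: str, code_table: int = 11,
              gene: str = "") -> DnDsResult:
    """Nei-Gojobori dN/dS between two aligned CDS of equal length.

    Site counts are averaged over the pair, differences are pathway-
    averaged per codon, and both proportions receive the Jukes-Cantor
    correction.  The ratio is undefined (None) when dS = 0.
    """
    if len(ref_cds) != len(qry_cds) or len(ref_cds) % 3:
        raise PlastcompError("CDS pair must be aligned with length divisible by 3")
    table = CodonTable.unambiguous_dna_by_id[code_table]
    n_codons = len(ref_cds) // 3
    S = N = sd = nd = 0.0
    for i in range(n_codons):
        c1 = ref_cds[3 * i:3 * i + 3]
        c2 = qry_cds[3 * i:3 * i + 3]
        for j, c in ((i, c1), (i, c2)):
            if c in table.stop_codons and j < n_codons - 1:
                raise PlastcompError(f"internal stop codon at codon {i}")
        if "-" in c1 or "-" in c2:
            continue  # gapped codons are skipped
        s1, n1 = _codon_site_fractions(c1, table)
        s2, n2 = _codon_site_fractions(c2, table)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        psd, pnd = _pathway_diffs(c1, c2, table)
        sd += psd
        nd += pnd

    def jc(p: float) -> float:
        if p <= 0:
            return 0.0
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            return float("inf")
        return -0.75 * math.log(arg)

    ds = jc(sd / S) if S else 0.0
    dn = jc(nd / N) if N else 0.0
    ratio = (dn / ds) if ds > 0 else None
    return DnDsResult(gene=gene, dn=dn, ds=ds, ratio=ratio,
                      syn_sites=S, nonsyn_sites=N, syn_diffs=sd,
                      nonsyn_diffs=nd)


# ---------------------------------------------------------------------------
# tRNA position comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrnaCluster:
    ref_position: int
    members: dict  # species -> (gene_name, position on that species)
    orphan: bool
    unplaced: bool = False


def compare_trna_positions(
    annotations: dict[str, GenomeAnnotation],
    position_maps: dict[str, object],
    reference_species: str,
    tolerance: int = 200,
) -> list[TrnaCluster]:
    """Cluster tRNA loci by reference-projected position.

    ``position_maps[sp]`` maps a position on species sp to the reference
    coordinate (a callable returning None when the locus is unmappable, for
    example inside a breakpoint); the reference species maps identically.
    Loci within ``tolerance`` bases collapse into one cluster; clusters
    present in a single species are flagged orphans.
    """
    loci: list[tuple[Optional[int], str, str, int]] = []
    for sp, ann in annotations.items():
        mapper = position_maps.get(sp)
        for f in ann.features:
            if f.kind != "tRNA":
                continue
            pos = f.start
            if sp == reference_species:
                ref_pos: Optional[int] = pos
            else:
                ref_pos = mapper(pos) if mapper else None
            loci.append((ref_pos, sp, f.gene_name, pos))
    clusters: list[TrnaCluster] = []
    placed = sorted((l for l in loci if l[0] is not None),
                    key=lambda l: l[0])
    group: list[tuple[int, str, str, int]] = []
    for locus in placed:
        if group and locus[0] - group[-1][0] > tolerance:
            clusters.append(_mk_cluster(group))
            group = []
        group.append(locus)  # type: ignore
    if group:
        clusters.append(_mk_cluster(group))
    for ref_pos, sp, name, pos in loci:
        if ref_pos is None:
            clusters.append(TrnaCluster(ref_position=-1,
                                        members={sp: (name, pos)},
                                        orphan=True, unplaced=True))
    return clusters


def _mk_cluster(group) -> TrnaCluster:
    members: dict[str, tuple[str, int]] = {}
    for ref_pos, sp, name, pos in group:
        members.setdefault(sp, (name, pos))
    return TrnaCluster(ref_position=group[0][0], members=members,
                       orphan=len(members) == 1)


def segment_position_mapper(segments):
    """A qry->ref coordinate mapper from plus-strand synteny segments
    (anchor-linear interpolation is enough at plastome divergences)."""
    plus = sorted((s for s in segments if s.strand == "+"),
                  key=lambda s: s.qry_start)

    def mapper(qpos: int) -> Optional[int]:
        for s in plus:
            if s.qry_start <= qpos < s.qry_end:
                frac = (qpos - s.qry_start) / max(1, s.qry_end - s.qry_start)
                return int(s.ref_start + frac * (s.ref_end - s.ref_start))
        return None

    return mapper
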