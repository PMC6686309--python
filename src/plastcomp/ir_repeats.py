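"""Inverted-repeat structure, boundary gene orders, and gene integrity.

Plastome IRs are long (kilobases) and near-exact, so detection seeds exact
k-mer matches between the forward strand and its reverse complement and
merges/extends them, allowing a small mismatch fraction.  Boundary gene
orders (the two nearest genes on each side of each arm) are compared
across species by majority rule to call translocations of IR-flank genes,
and a local-alignment check classifies a translocated locus as intact,
5'-truncated pseudogene, or carrying an internal stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .core import CircularGenome, Feature, GenomeAnnotation, PlastcompError, revcomp
from .synteny import _mems

logger = logging.getLogger("plastcomp")


@dataclass(frozen=True)
class IRStructure:
    """The detected inverted-repeat pair (0-based half-open intervals,
    arm_a before arm_b on the linearization)."""

    arm_a: tuple[int, int]
    arm_b: tuple[int, int]
    arm_length: int
    mismatches: int


@dataclass(frozen=True)
class BoundaryOrder:
    """Gene order at the IR boundaries of one species.

    Each flank tuple holds up to two gene names in genome coordinate
    order: ``forward_flanks = (upstream pair, downstream pair)`` for
    arm_a, ``reverse_flanks`` likewise for arm_b.
    """

    species: str
    forward_flanks: tuple[tuple[str, ...], tuple[str, ...]]
    reverse_flanks: tuple[tuple[str, ...], tuple[str, ...]]

    def as_string(self) -> str:
        fa = "-".join(self.forward_flanks[0]) + "-IR-" + "-".join(self.forward_flanks[1])
        fb = "-".join(self.reverse_flanks[0]) + "-IR-" + "-".join(self.reverse_flanks[1])
        return f"{fa} {fb}"

    def slots(self) -> dict[str, tuple[str, str]]:
        """gene -> (arm, side) for the genes in the flanks."""
        out = {}
        for arm, (left, right) in (("A", self.forward_flanks),
                                   ("B", self.reverse_flanks)):
            for g in left:
                out[g] = (arm, "left")
            for g in right:
                out[g] = (arm, "right")
        return out


@dataclass(frozen=True)
class TranslocationReport:
    species: str
    gene: str
    description: str  # "<gene> at other IR"


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------

def _count_mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def find_inverted_repeats(
    genome: CircularGenome,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.02,
    k: int = 25,
) -> Optional[IRStructure]:
    """Locate the highest-scoring inverted-repeat pair, or None if no pair
    of length >= ``min_len`` exists within the mismatch tolerance.

    Exact matches between the doubled sequence and its reverse complement
    seed the search (doubling makes detection wrap-aware; positions are
    reported mod length), co-antidiagonal seeds separated by mismatches are
    merged, and the longest surviving candidate wins (ties broken by the
    smaller arm_a start).
    """
    n = genome.length
    if n <= 2 * min_len:
        raise PlastcompError("sequence shorter than twice min_len")
    doubled = genome.seq + genome.seq
    rc = revcomp(doubled)
    mems = _mems(doubled, rc, k)

    # A match of `doubled` at position r against rc at position q means
    # doubled[r:r+L] == revcomp(doubled)[q:q+L], i.e. the partner interval
    # in doubled coordinates starts at len(doubled) - q - L.  Pieces of one
    # interrupted repeat share the diagonal d = r - q; merge across small
    # gaps within the mismatch budget.
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for r, q, ln in mems:
        if ln < k:
            continue
        by_diag.setdefault(r - q, []).append((r, ln))

    scored: list[IRStructure] = []
    for diag, hits in by_diag.items():
        hits.sort()
        i = 0
        while i < len(hits):
            start, ln = hits[i]
            end = start + ln
            mism = 0
            j = i + 1
            while j < len(hits):
                nxt_s, nxt_l = hits[j]
                gap = nxt_s - end
                if gap < 0 or gap > 200:
                    break
                cand_len = nxt_s + nxt_l - start
                if mism + gap > max_mismatch_frac * cand_len:
                    break
                mism += gap
                end = nxt_s + nxt_l
                j += 1
            i = j
            length = end - start
            if length < min_len:
                continue
            q = start - diag
            partner = 2 * n - q - length  # start of partner in doubled coords
            a0, b0 = start % n, partner % n
            if a0 == b0:
                continue
            if a0 > b0:
                a0, b0 = b0, a0
            # arms must not overlap on the circle
            if a0 + length > b0 or b0 + length > a0 + n:
                continue
            arm_a = doubled[a0:a0 + length]
            arm_b = doubled[b0:b0 + length]
            m = _count_mismatches(arm_a, revcomp(arm_b))
            if m > max_mismatch_frac * length:
                continue
            scored.append(IRStructure(arm_a=(a0, a0 + length),
                                      arm_b=(b0, b0 + length),
                                      arm_length=length, mismatches=m))
        # end while
    if not scored:
        return None
    scored.sort(key=lambda s: (-s.arm_length, s.arm_a[0]))
    # deduplicate symmetric reports
    return scored[0]


# ---------------------------------------------------------------------------
# Boundary gene order
# ---------------------------------------------------------------------------

def ir_boundary_gene_order(ir: IRStructure, annotation: GenomeAnnotation,
                           n_flank: int = 2, species: Optional[str] = None
                           ) -> BoundaryOrder:
    """The two nearest non-IR genes on each side of each arm, in genome
    coordinate order (circular; features spanning an arm boundary are
    excluded with a warning)."""
    arms = [ir.arm_a, ir.arm_b]
    feats: list[Feature] = []
    for f in annotation.features:
        inside = any(f.start >= s and f.end <= e for s, e in arms)
        spans = any((f.start < s < f.end) or (f.start < e < f.end)
                    for s, e in arms)
        if spans:
            logger.warning("feature %s spans an IR boundary; excluded from "
                           "flank order", f.gene_name)
            continue
        if not inside:
            feats.append(f)
    feats.sort(key=lambda f: f.start)
    n = annotation.genome_length

    def flanks(arm: tuple[int, int]) -> tuple[tuple[str, ...], tuple[str, ...]]:
        s, e = arm
        upstream = [f for f in feats if f.end <= s]
        downstream = [f for f in feats if f.start >= e % n or f.start >= e]
        # circular wrap: if fewer than n_flank on one side, borrow from the
        # other end of the linearization
        up = upstream[-n_flank:]
        if len(up) < n_flank:
            wrap = [f for f in feats if f.start >= e][-(n_flank - len(up)):]
            up = wrap + up if wrap else up
        down = [f for f in feats if f.start >= e][:n_flank]
        if len(down) < n_flank:
            wrap = [f for f in feats if f.end <= s][:n_flank - len(down)]
            down = down + wrap
        return (tuple(f.gene_name for f in up),
                tuple(f.gene_name for f in down))

    fa = flanks(ir.arm_a)
    fb = flanks(ir.arm_b)
    if any(len(side) < n_flank for side in (*fa, *fb)):
        logger.warning("degenerate annotation: fewer than %d flanking genes",
                       n_flank)
    return BoundaryOrder(species=species or annotation.genome_id,
                         forward_flanks=fa, reverse_flanks=fb)


def compare_ir_boundaries(orders: Sequence[BoundaryOrder]
                          ) -> list[TranslocationReport]:
    """Call IR-flank translocations against the majority configuration.

    For every gene seen in any species' flanks, the majority (arm, side)
    slot is determined; a species whose slot for that gene sits at the
    other arm is reported as "<gene> at other IR".  If no gene has a
    majority configuration, no calls are made.
    """
    if len(orders) < 2:
        raise PlastcompError("need at least two species to compare boundaries")
    slot_by_species = {o.species: o.slots() for o in orders}
    genes = sorted({g for slots in slot_by_species.values() for g in slots})
    reports: list[TranslocationReport] = []
    any_majority = False
    for gene in genes:
        votes: dict[tuple[str, str], int] = {}
        for slots in slot_by_species.values():
            if gene in slots:
                votes[slots[gene]] = votes.get(slots[gene], 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue  # tie: no majority for this gene
        majority_slot, nvotes = ranked[0]
        if nvotes < 2:
            continue
        any_majority = True
        for order in orders:
            slot = slot_by_species[order.species].get(gene)
            if slot is None or slot == majority_slot:
                continue
            if slot[0] != majority_slot[0]:  # attached to the other arm
                reports.append(TranslocationReport(
                    species=order.species, gene=gene,
                    description=f"{gene} at other IR",
                ))
    if not any_majority:
        logger.warning("no consensus boundary configuration; no calls made")
        return []
    return sorted(reports, key=lambda r: (r.species, r.gene))


# ---------------------------------------------------------------------------
# Gene integrity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrityVerdict:
    verdict: str  # intact | pseudogene_5prime_truncated | internal_stop | other_defect
    ref_coverage: float
    ref_start_offset: float  # fraction of the reference 5' end missing
    has_internal_stop: bool


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


def assess_gene_integrity(
    locus_seq: str,
    reference_cds: str,
    genetic_code_table: int = 11,
    coverage_threshold: float = 0.8,
    loss_threshold: float = 0.2,
    start_window: float = 0.3,
) -> IntegrityVerdict:
    """Classify a gene locus against an intact reference CDS.

    A 5'-truncated pseudogene call requires (a) the best local alignment to
    cover < ``coverage_threshold`` of the reference, starting only after
    >= ``loss_threshold`` of its 5' end is lost, and (b) no in-frame start
    codon among the locus positions aligning within the first
    ``start_window`` fraction of the reference (no alternative start).
    An intact-length locus whose aligned frame contains a stop codon is
    reported as ``internal_stop``.
    """
    if not locus_seq or not reference_cds:
        raise PlastcompError("empty sequence passed to assess_gene_integrity")
    if len(reference_cds) % 3:
        raise PlastcompError("reference CDS length not divisible by 3")
    table = CodonTable.unambiguous_dna_by_id[genetic_code_table]
    aln = _local_aligner().align(reference_cds, locus_seq)[0]
    ref_blocks, loc_blocks = aln.aligned
    ref_cov_start = int(ref_blocks[0][0])
    ref_cov_end = int(ref_blocks[-1][1])
    coverage = (ref_cov_end - ref_cov_start) / len(reference_cds)
    start_offset = ref_cov_start / len(reference_cds)

    # scan the aligned locus region for in-frame internal stops
    has_stop = False
    for (rs, re_), (ls, le_) in zip(ref_blocks, loc_blocks):
        phase = (3 - rs % 3) % 3
        block = locus_seq[ls + phase: le_]
        block = block[: len(block) - len(block) % 3]
        # exclude the reference's own terminal stop codon
        for i in range(0, len(block) - 2, 3):
            ref_codon_index = (rs + phase + i) // 3
            if ref_codon_index >= len(reference_cds) // 3 - 1:
                break
            if block[i:i + 3] in table.stop_codons:
                has_stop = True
                break
        if has_stop:
            break

    # alternative start search: locus positions aligned within the first
    # `start_window` fraction of the reference, in frame
    window_end = start_window * len(reference_cds)
    alt_start = False
    for (rs, re_), (ls, le_) in zip(ref_blocks, loc_blocks):
        for off in range(0, re_ - rs - 2):
            rpos = rs + off
            if rpos >= window_end:
                break
            if rpos % 3 == 0 and locus_seq[ls + off: ls + off + 3] in \
                    table.start_codons:
                alt_start = True
                break
        if alt_start or rs >= window_end:
            break

    if start_offset >= loss_threshold and coverage < coverage_threshold \
            and not alt_start:
        verdict = "pseudogene_5prime_truncated"
    elif has_stop:
        verdict = "internal_stop"
    elif coverage >= 0.99 and start_offset < 0.01 \
            and locus_seq[int(loc_blocks[0][0]):int(loc_blocks[0][0]) + 3] \
            in table.start_codons:
        verdict = "intact"
    else:
        verdict = "other_defect"
    return IntegrityVerdict(verdict=verdict, ref_coverage=coverage,
                            ref_start_offset=start_offset,
                            has_internal_stop=has_stop)


def extract_cds(genome: CircularGenome, feature: Feature) -> str:
    """Strand-corrected nucleotide sequence of a feature."""
    s = genome.seq[feature.start:feature.end]
    return s if feature.strand == "+" else revcomp(s)


def ir_report_rows(species: str, genome: CircularGenome,
                   ir: Optional[IRStructure],
                   order: Optional[BoundaryOrder]) -> dict:
    """One row of the per-species structural report (length, IR length,
    boundary strings)."""
    return {
        "species": species,
        "length_bp": genome.length,
        "ir_length_bp": ir.arm_length if ir else 0,
        "boundaries": order.as_string() if order else "no IR found",
    }
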