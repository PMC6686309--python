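"""Core domain types and file I/O shared by every analysis stage.

All coordinates are 0-based half-open internally.  Files are written in
their formats' native conventions (GFF3 and VCF are 1-based).  Genomes are
circular molecules; they are stored linearized at a canonical origin and
rotated explicitly (``rotate_to_anchor``) before any positional comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("plastcomp")

VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = ("CDS", "tRNA", "rRNA")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


class PlastcompError(Exception):
    """Base class for user-facing errors raised by this package."""


@dataclass(frozen=True)
class CircularGenome:
    """A named circular nucleotide sequence stored at a fixed linearization.

    ``origin_offset`` records the rotation (in bases) that was applied to
    the original deposition to obtain this linearization; rotating by the
    full length is the identity.
    """

    id: str
    seq: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if not self.seq:
            raise PlastcompError(f"genome {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise PlastcompError(
                f"genome {self.id!r}: non-nucleotide character "
                f"{self.seq[pos]!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def rotate(self, offset: int) -> "CircularGenome":
        """Rotate the linearization left by ``offset`` bases (mod length)."""
        n = self.length
        offset %= n
        return CircularGenome(
            id=self.id,
            seq=self.seq[offset:] + self.seq[:offset],
            origin_offset=(self.origin_offset + offset) % n,
        )

    def reverse_complement(self) -> "CircularGenome":
        return CircularGenome(id=self.id, seq=revcomp(self.seq),
                              origin_offset=self.origin_offset)


@dataclass(frozen=True)
class Feature:
    """An annotated CDS/tRNA/rRNA interval on a linearized genome."""

    gene_name: str
    kind: str  # one of FEATURE_KINDS
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise PlastcompError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise PlastcompError(
                f"feature {self.gene_name}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in "+-":
            raise PlastcompError(f"feature {self.gene_name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, merged and sorted."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class GenomeAnnotation:
    """Ordered feature set of one genome plus the genic/intergenic partition.

    A position is genic if it lies inside any feature; overlapping features
    are merged for the partition so genic + intergenic always equals the
    genome length.  ``ir_intervals`` optionally records the two inverted
    repeat arms ``((a_start, a_end), (b_start, b_end))`` when known.
    """

    genome_id: str
    genome_length: int
    features: list[Feature] = field(default_factory=list)
    ir_intervals: Optional[tuple[tuple[int, int], tuple[int, int]]] = None

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > self.genome_length:
                raise PlastcompError(
                    f"feature {f.gene_name} exceeds genome length "
                    f"({f.end} > {self.genome_length})"
                )

    @property
    def genic_intervals(self) -> list[tuple[int, int]]:
        return merge_intervals((f.start, f.end) for f in self.features)

    @property
    def genic_length(self) -> int:
        return sum(e - s for s, e in self.genic_intervals)

    @property
    def intergenic_length(self) -> int:
        return self.genome_length - self.genic_length

    def is_genic(self, pos: int) -> bool:
        import bisect

        ivs = self.genic_intervals
        i = bisect.bisect_right(ivs, (pos, self.genome_length + 1)) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    def genic_mask(self):
        """Boolean numpy array: True where genic."""
        import numpy as np

        mask = np.zeros(self.genome_length, dtype=bool)
        for s, e in self.genic_intervals:
            mask[s:e] = True
        return mask

    def by_name(self, gene_name: str) -> list[Feature]:
        return [f for f in self.features if f.gene_name == gene_name]


@dataclass(frozen=True)
class VariantCall:
    """A SNP or small indel on reference coordinates.

    For indels ``ref_allele``/``alt_allele`` follow the VCF convention of a
    shared left anchor base; ``pos`` is the 0-based position of that anchor
    (or of the substituted base for SNPs).
    """

    ref_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    var_type: str  # SNP | insertion | deletion
    species: str
    region: str = "intergenic"  # genic | intergenic
    effect: Optional[str] = None  # synonymous | nonsynonymous | noncoding
    gene: Optional[str] = None
    large: bool = False  # indel longer than the small-indel limit

    def __post_init__(self) -> None:
        if self.var_type == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise PlastcompError("SNP alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise PlastcompError("SNP ref and alt alleles are identical")
        elif self.var_type in ("insertion", "deletion"):
            if abs(len(self.ref_allele) - len(self.alt_allele)) < 1:
                raise PlastcompError("indel alleles must differ in length")
        else:
            raise PlastcompError(f"unknown variant type {self.var_type!r}")

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def key(self) -> tuple:
        """Allele identity used when matching calls across species."""
        return (self.pos, self.ref_allele, self.alt_allele)


@dataclass
class AnalysisConfig:
    """Tunable parameters shared across the pipeline stages."""

    window_size: int = 1000
    identity_threshold: float = 0.90
    min_segment: int = 200
    small_indel_max: int = 10
    bootstrap_reps: int = 1000
    gamma_shape: float = 0.2099
    genetic_code_table: int = 11
    ir_min_len: int = 1000
    ir_max_mismatch_frac: float = 0.02
    anchor_k: int = 20
    max_gap: int = 5000
    band_limit: int = 100  # max diagonal shift closed by alignment inside a segment
    trna_cluster_tolerance: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise PlastcompError("identity_threshold must be in (0, 1]")
        for name in ("window_size", "min_segment", "small_indel_max",
                     "bootstrap_reps", "gamma_shape", "genetic_code_table",
                     "ir_min_len", "anchor_k", "max_gap", "band_limit"):
            if getattr(self, name) <= 0:
                raise PlastcompError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[CircularGenome]:
    """Read a (multi-record) FASTA file into CircularGenome objects.

    Sequences are upper-cased; only A/C/G/T/N are accepted.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PlastcompError(f"{path}: no FASTA records found")
    genomes = []
    for rec in records:
        genomes.append(CircularGenome(id=rec.id, seq=str(rec.seq).upper()))
    return genomes


def write_fasta(genomes: Sequence[CircularGenome], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path, genome: CircularGenome) -> GenomeAnnotation:
    """Read CDS/tRNA/rRNA rows of a GFF3 file for one genome.

    GFF3 coordinates (1-based, closed) are converted to 0-based half-open.
    Rows of other feature types are skipped with a log entry.
    """
    features: list[Feature] = []
    skipped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise PlastcompError(f"{path}:{lineno}: malformed GFF3 row")
            seqid, _src, kind, start, end, _score, strand, _phase, attrs = cols[:9]
            if seqid != genome.id:
                continue
            if kind not in FEATURE_KINDS:
                skipped.add(kind)
                continue
            a = _parse_gff_attributes(attrs)
            name = a.get("gene") or a.get("Name") or a.get("ID") or f"feat{lineno}"
            s, e = int(start) - 1, int(end)
            if e > genome.length:
                raise PlastcompError(
                    f"{path}:{lineno}: feature {name} exceeds genome length"
                )
            features.append(Feature(
                gene_name=name, kind=kind, start=s, end=e, strand=strand,
                pseudo=a.get("pseudo", "").lower() == "true",
            ))
    if skipped:
        logger.info("read_gff3(%s): skipped feature kinds %s", path, sorted(skipped))
    return GenomeAnnotation(genome_id=genome.id, genome_length=genome.length,
                            features=features)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.genome_id} 1 "
                 f"{annotation.genome_length}\n")
        for f in annotation.features:
            attrs = f"gene={f.gene_name}"
            if f.pseudo:
                attrs += ";pseudo=true"
            phase = "0" if f.kind == "CDS" else "."
            fh.write("\t".join([
                annotation.genome_id, "plastcomp", f.kind,
                str(f.start + 1), str(f.end), ".", f.strand, phase, attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Rotation to a shared origin
# ---------------------------------------------------------------------------

def rotate_to_anchor(
    genome: CircularGenome,
    annotation: GenomeAnnotation,
    anchor_gene: str,
) -> tuple[CircularGenome, GenomeAnnotation]:
    """Rotate a circular genome so that ``anchor_gene`` starts at position 0
    on the + strand, remapping all features.

    The anchor must occur exactly once and lie outside the inverted repeats
    (a gene duplicated in the IRs cannot define a unique origin).  Features
    that span the new origin are split into two parts sharing the gene name.
    """
    hits = annotation.by_name(anchor_gene)
    if not hits:
        raise PlastcompError(f"anchor gene {anchor_gene!r} not found")
    if len(hits) > 1:
        raise PlastcompError(f"anchor gene {anchor_gene!r} occurs {len(hits)} times")
    anchor = hits[0]
    if annotation.ir_intervals:
        for (s, e) in annotation.ir_intervals:
            if anchor.start < e and anchor.end > s:
                raise PlastcompError(
                    f"anchor gene {anchor_gene!r} lies inside an inverted repeat"
                )
    n = genome.length
    if anchor.strand == "-":
        # Flip the molecule so the anchor reads on '+', then rotate.
        genome = genome.reverse_complement()
        flipped = [
            replace(f, start=n - f.end, end=n - f.start,
                    strand="+" if f.strand == "-" else "-")
            for f in annotation.features
        ]
        ir = annotation.ir_intervals
        if ir:
            ir = tuple(sorted(((n - e, n - s) for s, e in ir)))  # type: ignore
        annotation = GenomeAnnotation(genome_id=annotation.genome_id,
                                      genome_length=n, features=flipped,
                                      ir_intervals=ir)
        anchor = annotation.by_name(anchor_gene)[0]
    offset = anchor.start
    rotated = genome.rotate(offset)
    new_features: list[Feature] = []
    for f in annotation.features:
        s = (f.start - offset) % n
        e = s + f.length
        if e <= n:
            new_features.append(replace(f, start=s, end=e))
        else:  # wraps the new origin: split in two parts
            new_features.append(replace(f, start=s, end=n))
            new_features.append(replace(f, start=0, end=e - n))
    ir = annotation.ir_intervals
    new_ir = None
    if ir:
        arms = []
        for s, e in ir:
            s2 = (s - offset) % n
            arms.append((s2, s2 + (e - s)))  # may exceed n if the arm wraps
        new_ir = tuple(sorted(arms))  # type: ignore
    return rotated, GenomeAnnotation(
        genome_id=annotation.genome_id, genome_length=n,
        features=new_features, ir_intervals=new_ir,
    )


# ---------------------------------------------------------------------------
# Indel normalization and VCF output
# ---------------------------------------------------------------------------

def left_normalize(ref_seq: str, pos: int, ref_allele: str, alt_allele: str
                   ) -> tuple[int, str, str]:
    """Left-normalize an indel against the reference sequence.

    Follows the usual VCF normalization: shift left while the rightmost
    bases of both alleles agree, keeping a single shared anchor base.
    """
    ref, alt = ref_allele, alt_allele
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if ref and alt:
                continue
        if not ref or not alt:
            if pos == 0:
                raise PlastcompError("cannot left-normalize indel at position 0")
            pos -= 1
            base = ref_seq[pos]
            ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def write_vcf(
    calls: Sequence[VariantCall],
    reference: CircularGenome,
    path: str | Path,
    species_order: Optional[Sequence[str]] = None,
) -> None:
    """Write a minimal VCF 4.2 with one presence-genotype column per species.

    Calls must be sorted by position.  Calls sharing (pos, ref, alt) across
    species are emitted as one row.
    """
    positions = [c.pos for c in calls]
    if positions != sorted(positions):
        raise PlastcompError("write_vcf requires calls sorted by position")
    if species_order is None:
        species_order = sorted({c.species for c in calls})
    grouped: dict[tuple, list[VariantCall]] = {}
    order: list[tuple] = []
    for c in calls:
        if c.key not in grouped:
            grouped[c.key] = []
            order.append(c.key)
        grouped[c.key].append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.id},length={reference.length}>\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="genic or intergenic">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Presence genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(species_order) + "\n")
        for key in order:
            group = grouped[key]
            c0 = group[0]
            present = {c.species for c in group}
            gts = ["1" if sp in present else "0" for sp in species_order]
            info = f"TYPE={c0.var_type};REGION={c0.region}"
            fh.write("\t".join([
                reference.id, str(c0.pos + 1), ".", c0.ref_allele,
                c0.alt_allele, ".", "PASS", info, "GT", *gts,
            ]) + "\n")
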