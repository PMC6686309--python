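"""Reference-based SNP/indel extraction from synteny segments.

Variants are read directly off the segment alignments produced by the
synteny stage: mismatch columns become SNPs, gap runs become indels
(left-normalized, with indels longer than the small-indel limit retained
but flagged large).  Windowed SNP densities summarize the distribution of
variation along the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    AnalysisConfig,
    CircularGenome,
    GenomeAnnotation,
    PlastcompError,
    VariantCall,
    left_normalize,
)
from .synteny import SyntenySegment, synteny_map

logger = logging.getLogger("plastcomp")


@dataclass(frozen=True)
class WindowDensity:
    window_start: int
    count: int


def call_variants(
    ref: CircularGenome,
    qry: CircularGenome,
    segments: Sequence[SyntenySegment],
    config: Optional[AnalysisConfig] = None,
    annotation: Optional[GenomeAnnotation] = None,
    species: Optional[str] = None,
) -> list[VariantCall]:
    """Call SNPs and indels for one query against the reference.

    Only plus-strand segments are used; they must be non-overlapping on the
    reference (run containment filtering first).  Region class (genic /
    intergenic) is assigned from the reference annotation when provided.
    """
    config = config or AnalysisConfig()
    species = species or qry.id
    plus = sorted((s for s in segments if s.strand == "+"),
                  key=lambda s: s.ref_start)
    for a, b in zip(plus, plus[1:]):
        if b.ref_start < a.ref_end:
            raise PlastcompError(
                "overlapping segments passed to call_variants; "
                "containment filtering must run first"
            )
    genic = annotation.genic_mask() if annotation is not None else None
    calls: list[VariantCall] = []
    for seg in plus:
        i = 0
        ops = seg.ops
        while i < len(ops):
            kind, rp, qp, ln = ops[i]
            if kind == "eq":
                i += 1
                continue
            if kind == "x":
                for j in range(ln):
                    pos = rp + j
                    calls.append(VariantCall(
                        ref_id=ref.id, pos=pos, ref_allele=ref.seq[pos],
                        alt_allele=qry.seq[qp + j], var_type="SNP",
                        species=species,
                        region=_region(genic, pos),
                    ))
                i += 1
                continue
            # merge adjacent ins/del runs into one indel event
            del_len = ins_len = 0
            r0, q0 = rp, qp
            while i < len(ops) and ops[i][0] in ("ins", "del"):
                k2, _rp, _qp, l2 = ops[i]
                if k2 == "del":
                    del_len += l2
                else:
                    ins_len += l2
                i += 1
            if rp == 0:
                # an indel at the very start of the reference has no left
                # anchor; skip (cannot be represented in VCF form)
                logger.warning("indel at reference position 0 skipped")
                continue
            anchor = r0 - 1
            ref_allele = ref.seq[anchor:r0 + del_len]
            alt_allele = ref.seq[anchor] + qry.seq[q0:q0 + ins_len]
            if ref_allele == alt_allele:
                continue
            pos, ref_allele, alt_allele = left_normalize(
                ref.seq, anchor, ref_allele, alt_allele)
            vtype = "deletion" if len(ref_allele) > len(alt_allele) else "insertion"
            length = abs(len(ref_allele) - len(alt_allele))
            calls.append(VariantCall(
                ref_id=ref.id, pos=pos, ref_allele=ref_allele,
                alt_allele=alt_allele, var_type=vtype, species=species,
                region=_region(genic, pos),
                large=length > config.small_indel_max,
            ))
    calls.sort(key=lambda c: (c.pos, c.ref_allele, c.alt_allele))
    return calls


def _region(genic, pos: int) -> str:
    if genic is None:
        return "intergenic"
    return "genic" if genic[pos] else "intergenic"


def window_density(
    calls: Sequence[VariantCall],
    reference_length: int,
    window_size: int = 1000,
) -> list[WindowDensity]:
    """SNP counts (summed over species) in non-overlapping windows tiling
    the reference; indels are excluded, the last window may be short."""
    n_windows = (reference_length + window_size - 1) // window_size
    counts = np.zeros(n_windows, dtype=int)
    for c in calls:
        if c.var_type == "SNP":
            counts[c.pos // window_size] += 1
    return [WindowDensity(window_start=i * window_size, count=int(v))
            for i, v in enumerate(counts)]


def pairwise_genome_diff(
    g1: CircularGenome,
    g2: CircularGenome,
    config: Optional[AnalysisConfig] = None,
) -> tuple[int, int, int]:
    """(snp_count, small_indel_count, large_indel_count) between two
    collinear genomes, with ``g1`` as the reference."""
    config = config or AnalysisConfig()
    segments, _bps = synteny_map(g1, g2, config)
    calls = call_variants(g1, g2, segments, config)
    snps = sum(1 for c in calls if c.var_type == "SNP")
    small = sum(1 for c in calls if c.var_type != "SNP" and not c.large)
    large = sum(1 for c in calls if c.var_type != "SNP" and c.large)
    return snps, small, large


def write_window_tsv(densities: Sequence[WindowDensity], path) -> None:
    with open(path, "w") as fh:
        fh.write("window_start\tsnp_count\n")
        for w in densities:
            fh.write(f"{w.window_start}\t{w.count}\n")
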