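"""Anchor-and-chain collinearity mapping between two plastomes.

The three stages re-implement a nucmer-style workflow: maximal exact
matches from a k-mer index (``find_anchors``), maximum-weight collinear
chaining (``chain_anchors``), and identity-scored segments with the gaps
between anchors closed by edit-distance alignment (``score_segments``).
Segments below the identity threshold are dropped, and segments fully
contained in a longer segment's reference interval are removed — this is
what removes the duplicate hit of the second inverted-repeat copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .core import AnalysisConfig, CircularGenome, PlastcompError, revcomp

logger = logging.getLogger("plastcomp")


class Anchor(NamedTuple):
    """A maximal exact match.  ``qry_start`` is in original query
    coordinates; for '-' anchors the reverse complement of the query
    interval equals the reference interval."""

    ref_start: int
    qry_start: int
    length: int
    strand: str


@dataclass
class SyntenySegment:
    """A chained, identity-scored collinear block."""

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str
    identity: float
    aligned_length: int
    # alignment ops on the + strand: (kind, ref_pos, qry_pos, length)
    # kinds: 'eq' exact block, 'x' mismatch run, 'ins' qry-only, 'del' ref-only
    ops: list[tuple] = field(default_factory=list, repr=False)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class Breakpoint:
    """A maximal reference interval not covered by any retained segment
    (zero-length for pure query-side insertions), with flanking segments."""

    ref_start: int
    ref_end: int
    left_segment: Optional[int]
    right_segment: Optional[int]


# ---------------------------------------------------------------------------
# Maximal exact matches
# ---------------------------------------------------------------------------

def _mems(ref: str, qry: str, k: int) -> list[tuple[int, int, int]]:
    """All maximal exact matches of length >= k as (ref_start, qry_start, len).

    Seeds come from a k-mer index of the reference; each seed is extended
    maximally in both directions, and seeds falling inside an already
    reported match on the same diagonal are skipped.
    """
    index: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i:i + k], []).append(i)
    out = []
    diag_end: dict[int, int] = {}
    nq, nr = len(qry), len(ref)
    for q in range(nq - k + 1):
        hits = index.get(qry[q:q + k])
        if not hits:
            continue
        for r in hits:
            d = r - q
            if diag_end.get(d, -1) >= q:
                continue
            lo = 0
            while r - lo - 1 >= 0 and q - lo - 1 >= 0 \
                    and ref[r - lo - 1] == qry[q - lo - 1]:
                lo += 1
            hi = k
            while r + hi < nr and q + hi < nq and ref[r + hi] == qry[q + hi]:
                hi += 1
            out.append((r - lo, q - lo, lo + hi))
            diag_end[d] = q + hi - 1
    return out


def find_anchors(ref: CircularGenome, qry: CircularGenome, k: int = 20
                 ) -> list[Anchor]:
    """All maximal exact matches >= k between the two genomes, both strands."""
    if k < 12:
        raise PlastcompError("anchor k must be >= 12")
    anchors = [Anchor(r, q, ln, "+") for r, q, ln in _mems(ref.seq, qry.seq, k)]
    rc = revcomp(qry.seq)
    n = qry.length
    for r, q, ln in _mems(ref.seq, rc, k):
        anchors.append(Anchor(r, n - q - ln, ln, "-"))
    anchors.sort(key=lambda a: (a.ref_start, a.qry_start, a.strand))
    return anchors


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def chain_anchors(anchors: Sequence[Anchor], max_gap: int = 5000,
                  diag_penalty: float = 0.05) -> list[list[Anchor]]:
    """Maximum-weight collinear chains per strand.

    Longest-increasing-subsequence style dynamic programme on
    (ref_start, qry_start) weighted by anchor length, with a per-base
    penalty on diagonal shift; links with a gap beyond ``max_gap`` on
    either genome are forbidden, which is what separates chains.  Chains
    are extracted best-first from unused anchors.
    """
    chains: list[list[Anchor]] = []
    for strand in "+-":
        sub = [a for a in anchors if a.strand == strand]
        if not sub:
            continue
        if strand == "-":
            # anti-diagonal coordinates: use the query interval end so that
            # collinear reverse matches become increasing pairs
            sub.sort(key=lambda a: (a.ref_start, -a.qry_start))
            qpos = np.array([-(a.qry_start + a.length) for a in sub], dtype=float)
        else:
            sub.sort(key=lambda a: (a.ref_start, a.qry_start))
            qpos = np.array([a.qry_start for a in sub], dtype=float)
        rs = np.array([a.ref_start for a in sub], dtype=float)
        ln = np.array([a.length for a in sub], dtype=float)
        re_ = rs + ln
        qe = qpos + ln
        n = len(sub)
        score = ln.copy()
        parent = np.full(n, -1, dtype=int)
        for i in range(1, n):
            rgap = rs[i] - re_[:i]
            qgap = qpos[i] - qe[:i]
            ok = (rs[i] > rs[:i]) & (qpos[i] > qpos[:i]) \
                & (rgap <= max_gap) & (qgap <= max_gap)
            if not ok.any():
                continue
            cand = score[:i] - diag_penalty * np.abs(rgap - qgap)
            cand[~ok] = -np.inf
            j = int(np.argmax(cand))
            if cand[j] > 0:
                score[i] = ln[i] + cand[j]
                parent[i] = j
        used = np.zeros(n, dtype=bool)
        order = np.argsort(-score, kind="stable")
        for start in order:
            if used[start]:
                continue
            chain_idx = []
            i = int(start)
            while i != -1 and not used[i]:
                chain_idx.append(i)
                used[i] = True
                i = int(parent[i])
            chain_idx.reverse()
            chains.append([sub[i] for i in chain_idx])
    chains.sort(key=lambda c: (c[0].ref_start, c[0].qry_start))
    return chains


# ---------------------------------------------------------------------------
# Segment scoring
# ---------------------------------------------------------------------------

def _gap_aligner() -> "object":
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -3
    a.extend_gap_score = -1
    return a


_GAP_ALIGNER = None


def _close_gap(ops: list, stats: list, ref_seq: str, qry_seq: str,
               r0: int, r1: int, q0: int, q1: int) -> None:
    """Append alignment ops covering ref[r0:r1] vs qry[q0:q1].

    Short equal-length gaps are aligned column-wise; everything else goes
    through affine-gap global alignment, which prefers substitutions and
    contiguous indels over equal-cost split gaps (the realistic mutational
    interpretation).  ``stats`` accumulates [matches, columns].
    """
    r, q = r1 - r0, q1 - q0
    if r == 0 and q == 0:
        return
    if r == q and r <= 30:
        i = 0
        while i < r:
            if ref_seq[r0 + i] == qry_seq[q0 + i]:
                j = i
                while j < r and ref_seq[r0 + j] == qry_seq[q0 + j]:
                    j += 1
                ops.append(("eq", r0 + i, q0 + i, j - i))
                stats[0] += j - i
            else:
                j = i
                while j < r and ref_seq[r0 + j] != qry_seq[q0 + j]:
                    j += 1
                ops.append(("x", r0 + i, q0 + i, j - i))
            stats[1] += j - i
            i = j
        return
    if r == 0:
        ops.append(("ins", r0, q0, q))
        stats[1] += q
        return
    if q == 0:
        ops.append(("del", r0, q0, r))
        stats[1] += r
        return
    global _GAP_ALIGNER
    if _GAP_ALIGNER is None:
        _GAP_ALIGNER = _gap_aligner()
    aln = _GAP_ALIGNER.align(ref_seq[r0:r1], qry_seq[q0:q1])[0]
    ref_blocks, qry_blocks = aln.aligned
    prev_r, prev_q = 0, 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, qry_blocks):
        if rs > prev_r:
            ops.append(("del", r0 + prev_r, q0 + prev_q, rs - prev_r))
            stats[1] += rs - prev_r
        if qs > prev_q:
            ops.append(("ins", r0 + rs, q0 + prev_q, qs - prev_q))
            stats[1] += qs - prev_q
        # aligned block: split into eq/x runs column-wise
        i = rs
        while i < re_:
            qi = qs + (i - rs)
            same = ref_seq[r0 + i] == qry_seq[q0 + qi]
            j = i
            while j < re_ and (ref_seq[r0 + j] == qry_seq[q0 + qs + (j - rs)]) == same:
                j += 1
            ops.append(("eq" if same else "x", r0 + i, q0 + qi, j - i))
            if same:
                stats[0] += j - i
            stats[1] += j - i
            i = j
        prev_r, prev_q = re_, qe
    if r > prev_r:
        ops.append(("del", r0 + prev_r, q0 + prev_q, r - prev_r))
        stats[1] += r - prev_r
    if q > prev_q:
        ops.append(("ins", r0 + r, q0 + prev_q, q - prev_q))
        stats[1] += q - prev_q


def score_segments(chains: Sequence[Sequence[Anchor]], ref: CircularGenome,
                   qry: CircularGenome, config: Optional[AnalysisConfig] = None
                   ) -> list[SyntenySegment]:
    """Turn chains into identity-scored segments.

    Plus-strand chains are extended to the sequence ends where possible,
    inter-anchor gaps are closed by alignment, and a chain is split at any
    gap whose diagonal shift exceeds ``config.band_limit`` (such shifts
    signal structural differences, not alignable indels).  Segments below
    the identity threshold or minimum length are dropped, then segments
    whose reference interval is contained in a longer retained segment are
    removed (this discards the second IR copy's duplicate match).
    """
    config = config or AnalysisConfig()
    segments: list[SyntenySegment] = []
    for chain in chains:
        strand = chain[0].strand
        if strand == "-":
            seg = _score_minus_chain(chain, ref, qry, config)
            if seg is not None:
                segments.append(seg)
            continue
        # head/tail extension: cover the sequence ends when the overhangs
        # on both genomes are comparable
        first, last = chain[0], chain[-1]
        pieces: list[tuple[int, int, int, int]] = []  # (r0, r1, q0, q1) gaps
        head_r, head_q = first.ref_start, first.qry_start
        ext_head = (0 < max(head_r, head_q) <= config.max_gap
                    and abs(head_r - head_q) <= config.band_limit)
        tail_r0, tail_q0 = last.ref_start + last.length, last.qry_start + last.length
        tail_r, tail_q = ref.length - tail_r0, qry.length - tail_q0
        ext_tail = (0 < max(tail_r, tail_q) <= config.max_gap
                    and abs(tail_r - tail_q) <= config.band_limit)

        ops: list[tuple] = []
        stats = [0, 0]  # matches, columns
        seg_start: Optional[tuple[int, int]] = None

        def flush(r_end: int, q_end: int) -> None:
            nonlocal ops, stats, seg_start
            if seg_start is None or not ops:
                ops, stats, seg_start = [], [0, 0], None
                return
            ident = stats[0] / stats[1] if stats[1] else 0.0
            segments.append(SyntenySegment(
                ref_start=seg_start[0], ref_end=r_end,
                qry_start=seg_start[1], qry_end=q_end, strand="+",
                identity=ident, aligned_length=stats[1], ops=ops,
            ))
            ops, stats, seg_start = [], [0, 0], None

        cur_r, cur_q = first.ref_start, first.qry_start
        if ext_head:
            seg_start = (0, 0)
            _close_gap(ops, stats, ref.seq, qry.seq, 0, cur_r, 0, cur_q)
        else:
            seg_start = (cur_r, cur_q)
        for a in chain:
            r, q, ln = a.ref_start, a.qry_start, a.length
            clip = max(cur_r - r, cur_q - q, 0)
            r, q, ln = r + clip, q + clip, ln - clip
            if ln <= 0:
                continue
            rgap, qgap = r - cur_r, q - cur_q
            if abs(rgap - qgap) > config.band_limit:
                flush(cur_r, cur_q)  # structural break inside the chain
                seg_start = (r, q)
            else:
                _close_gap(ops, stats, ref.seq, qry.seq, cur_r, r, cur_q, q)
            ops.append(("eq", r, q, ln))
            stats[0] += ln
            stats[1] += ln
            cur_r, cur_q = r + ln, q + ln
        if ext_tail:
            _close_gap(ops, stats, ref.seq, qry.seq,
                       cur_r, ref.length, cur_q, qry.length)
            flush(ref.length, qry.length)
        else:
            flush(cur_r, cur_q)

    kept = [s for s in segments
            if s.identity >= config.identity_threshold
            and s.ref_span >= config.min_segment]
    # containment filtering on reference coordinates
    kept.sort(key=lambda s: -s.ref_span)
    filtered: list[SyntenySegment] = []
    for s in kept:
        if any(o.ref_start <= s.ref_start and s.ref_end <= o.ref_end
               for o in filtered):
            continue
        filtered.append(s)
    filtered.sort(key=lambda s: s.ref_start)
    return filtered


def _score_minus_chain(chain, ref: CircularGenome, qry: CircularGenome,
                       config: AnalysisConfig) -> Optional[SyntenySegment]:
    """Identity for a reverse-strand chain (anchors only plus gap closure on
    the reverse-complemented query); ops are not retained for calling."""
    n = qry.length
    rc = revcomp(qry.seq)
    # anchor coordinates on the reverse-complemented query
    conv = sorted(((a.ref_start, n - a.qry_start - a.length, a.length)
                   for a in chain))
    ops: list[tuple] = []
    stats = [0, 0]
    cur_r, cur_q = conv[0][0], conv[0][1]
    for r, q, ln in conv:
        clip = max(cur_r - r, cur_q - q, 0)
        r, q, ln = r + clip, q + clip, ln - clip
        if ln <= 0:
            continue
        if abs((r - cur_r) - (q - cur_q)) <= config.band_limit:
            _close_gap(ops, stats, ref.seq, rc, cur_r, r, cur_q, q)
        stats[0] += ln
        stats[1] += ln
        cur_r, cur_q = r + ln, q + ln
    if stats[1] == 0:
        return None
    first_r, first_q = conv[0][0], conv[0][1]
    return SyntenySegment(
        ref_start=first_r, ref_end=cur_r,
        qry_start=n - cur_q, qry_end=n - first_q, strand="-",
        identity=stats[0] / stats[1], aligned_length=stats[1], ops=[],
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def synteny_map(ref: CircularGenome, qry: CircularGenome,
                config: Optional[AnalysisConfig] = None
                ) -> tuple[list[SyntenySegment], list[Breakpoint]]:
    """Full collinearity map: anchors -> chains -> scored segments plus the
    uncovered reference intervals (breakpoints)."""
    config = config or AnalysisConfig()
    anchors = find_anchors(ref, qry, k=config.anchor_k)
    chains = chain_anchors(anchors, max_gap=config.max_gap)
    segments = score_segments(chains, ref, qry, config)
    plus = sorted((s for s in segments if s.strand == "+"),
                  key=lambda s: s.ref_start)
    breakpoints: list[Breakpoint] = []
    cursor = 0
    prev_idx: Optional[int] = None
    for i, s in enumerate(plus):
        if s.ref_start > cursor:
            breakpoints.append(Breakpoint(cursor, s.ref_start, prev_idx, i))
        elif prev_idx is not None and s.ref_start == cursor:
            prev = plus[prev_idx]
            if s.qry_start != prev.qry_end:  # query-side discontinuity
                breakpoints.append(Breakpoint(cursor, cursor, prev_idx, i))
        cursor = max(cursor, s.ref_end)
        prev_idx = i
    if cursor < ref.length:
        breakpoints.append(Breakpoint(cursor, ref.length, prev_idx, None))
    return segments, breakpoints


def write_segments_tsv(segments: Sequence[SyntenySegment],
                       breakpoints: Sequence[Breakpoint],
                       path) -> None:
    """TSV export (1-based inclusive intervals, as in the usual nucmer-style
    coordinate reports)."""
    with open(path, "w") as fh:
        fh.write("record\tref_start\tref_end\tqry_start\tqry_end\t"
                 "strand\tidentity\taligned_length\n")
        for s in segments:
            fh.write(f"segment\t{s.ref_start + 1}\t{s.ref_end}\t"
                     f"{s.qry_start + 1}\t{s.qry_end}\t{s.strand}\t"
                     f"{s.identity:.4f}\t{s.aligned_length}\n")
        for b in breakpoints:
            fh.write(f"breakpoint\t{b.ref_start + 1}\t{b.ref_end}\t.\t.\t.\t"
                     f".\t.\n")
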