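"""Concatenated-gene distance phylogeny with bootstrap support.

Shared, non-pseudo CDS are extracted by gene name, each gene is aligned by
reference-anchored pairwise global alignment merged on reference columns,
genes are concatenated in reference genome order, and a neighbor-joining
tree is estimated from Tamura-Nei (1993) distances with an optional
discrete-gamma rate correction.  Support values come from column
bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from Bio import Align

from .core import CircularGenome, GenomeAnnotation, PlastcompError, revcomp

logger = logging.getLogger("plastcomp")


# ---------------------------------------------------------------------------
# Shared CDS extraction
# ---------------------------------------------------------------------------

def extract_shared_cds(
    annotations: dict[str, GenomeAnnotation],
    genomes: dict[str, CircularGenome],
) -> dict[str, dict[str, str]]:
    """gene -> species -> strand-corrected CDS, for genes present (once,
    non-pseudo) in every species.  Genes duplicated within a genome are
    excluded with a log entry."""
    species = sorted(annotations)
    per_species: dict[str, dict[str, str]] = {}
    order_ref: dict[str, int] = {}
    for sp in species:
        ann, genome = annotations[sp], genomes[sp]
        genes: dict[str, str] = {}
        dupes: set[str] = set()
        for f in ann.features:
            if f.kind != "CDS":
                continue
            if f.gene_name in genes or f.gene_name in dupes:
                dupes.add(f.gene_name)
                genes.pop(f.gene_name, None)
                logger.info("gene %s duplicated in %s; excluded", f.gene_name, sp)
                continue
            if f.pseudo:
                dupes.add(f.gene_name)  # pseudo in one species drops the gene
                continue
            seq = genome.seq[f.start:f.end]
            genes[f.gene_name] = seq if f.strand == "+" else revcomp(seq)
            if sp == species[0]:
                order_ref[f.gene_name] = f.start
        per_species[sp] = genes
    shared = set(per_species[species[0]])
    for sp in species[1:]:
        shared &= set(per_species[sp])
    out = {g: {sp: per_species[sp][g] for sp in species}
           for g in shared}
    return dict(sorted(out.items(),
                       key=lambda kv: order_ref.get(kv[0], 1 << 30)))


# ---------------------------------------------------------------------------
# Gene alignment (reference-anchored)
# ---------------------------------------------------------------------------

def _pairwise_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -4
    a.extend_gap_score = -1
    return a


def align_gene(sequences: dict[str, str], reference: str) -> dict[str, str]:
    """Multiple alignment of one gene by merging pairwise global alignments
    on reference coordinates.

    Every non-reference sequence is aligned to the reference; insertions
    relative to the reference are stacked per reference gap, padded with
    gap characters.  Returns species -> aligned row (equal lengths).
    """
    if any(not s for s in sequences.values()):
        raise PlastcompError("empty sequence passed to align_gene")
    ref_seq = sequences[reference]
    n = len(ref_seq)
    aligner = _pairwise_aligner()
    # per species: per reference position the aligned char, plus insertions
    # keyed by the reference position they follow (-1 = before the start)
    cols: dict[str, list[str]] = {}
    inserts: dict[str, dict[int, str]] = {}
    for sp, seq in sequences.items():
        if sp == reference:
            cols[sp] = list(ref_seq)
            inserts[sp] = {}
            continue
        aln = aligner.align(ref_seq, seq)[0]
        ref_blocks, qry_blocks = aln.aligned
        col = ["-"] * n
        ins: dict[int, str] = {}
        prev_r = prev_q = 0
        for (rs, re_), (qs, qe) in zip(ref_blocks, qry_blocks):
            if qs > prev_q:  # unaligned query bases = insertion after prev_r-1
                ins[prev_r - 1] = ins.get(prev_r - 1, "") + seq[prev_q:qs]
            for k in range(re_ - rs):
                col[rs + k] = seq[qs + k]
            prev_r, prev_q = re_, qe
        if prev_q < len(seq):
            ins[prev_r - 1] = ins.get(prev_r - 1, "") + seq[prev_q:]
        cols[sp] = col
        inserts[sp] = ins
    ins_len = {}
    for sp in sequences:
        for pos, s in inserts[sp].items():
            ins_len[pos] = max(ins_len.get(pos, 0), len(s))
    rows: dict[str, str] = {}
    for sp in sequences:
        parts: list[str] = []
        if -1 in ins_len:
            s = inserts[sp].get(-1, "")
            parts.append(s.ljust(ins_len[-1], "-"))
        for i in range(n):
            parts.append(cols[sp][i])
            if i in ins_len:
                s = inserts[sp].get(i, "")
                parts.append(s.ljust(ins_len[i], "-"))
        rows[sp] = "".join(parts)
    lengths = {len(r) for r in rows.values()}
    assert len(lengths) == 1, "aligned rows differ in length"
    return rows


@dataclass
class ConcatAlignment:
    taxa: list[str]
    rows: dict[str, str]
    gene_partitions: dict[str, tuple[int, int]]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def matrix(self) -> np.ndarray:
        """(taxa x columns) byte matrix in taxa order."""
        return np.vstack([
            np.frombuffer(self.rows[t].encode(), dtype="S1")
            for t in self.taxa
        ])


def concatenate(gene_alignments: dict[str, dict[str, str]]) -> ConcatAlignment:
    """Concatenate per-gene alignments (in the given gene order) into one
    matrix with a partition table.  Genes missing a taxon are excluded
    (complete-only policy)."""
    if not gene_alignments:
        raise PlastcompError("no gene alignments to concatenate")
    taxa = sorted(next(iter(gene_alignments.values())))
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for gene, rows in gene_alignments.items():
        if set(rows) != set(taxa):
            logger.info("gene %s missing some taxa; excluded", gene)
            continue
        width = len(next(iter(rows.values())))
        for t in taxa:
            parts[t].append(rows[t])
        partitions[gene] = (col, col + width)
        col += width
    if not partitions:
        raise PlastcompError("no gene shared by all taxa")
    return ConcatAlignment(taxa=taxa,
                           rows={t: "".join(parts[t]) for t in taxa},
                           gene_partitions=partitions)


# ---------------------------------------------------------------------------
# Tamura-Nei 1993 distance (with optional gamma rate correction)
# ---------------------------------------------------------------------------

def _pair_counts(row_i: np.ndarray, row_j: np.ndarray):
    """(valid, P1, P2, Q, freqs) for two byte rows with pairwise deletion."""
    a, c, g, t = (np.uint8(ord(x)) for x in "ACGT")
    vi = np.isin(row_i.view(np.uint8), [a, c, g, t])
    vj = np.isin(row_j.view(np.uint8), [a, c, g, t])
    ok = vi & vj
    x = row_i.view(np.uint8)[ok]
    y = row_j.view(np.uint8)[ok]
    n = x.size
    if n == 0:
        raise PlastcompError("no comparable columns between rows")
    diff = x != y
    purine_x = (x == a) | (x == g)
    purine_y = (y == a) | (y == g)
    p1 = int((diff & purine_x & purine_y).sum())  # A<->G
    pyr_x = (x == c) | (x == t)
    pyr_y = (y == c) | (y == t)
    p2 = int((diff & pyr_x & pyr_y).sum())  # C<->T
    q = int(diff.sum()) - p1 - p2
    both = np.concatenate([x, y])
    freqs = np.array([(both == b).sum() for b in (a, c, g, t)], dtype=float)
    freqs /= freqs.sum()
    return n, p1, p2, q, freqs


def tn93_distance(row_i: str | np.ndarray, row_j: str | np.ndarray,
                  gamma_shape: Optional[float] = None) -> float:
    """Tamura-Nei 1993 distance between two aligned rows.

    Gap/ambiguous columns are pairwise-deleted.  With ``gamma_shape`` set,
    the gamma-rates version is used (each -c*ln(e) term becomes
    c*a*(e^(-1/a) - 1)).  Returns ``inf`` when a logarithm argument is
    non-positive (saturation).
    """
    if isinstance(row_i, str):
        row_i = np.frombuffer(row_i.encode(), dtype="S1")
    if isinstance(row_j, str):
        row_j = np.frombuffer(row_j.encode(), dtype="S1")
    if row_i.size != row_j.size:
        raise PlastcompError("rows must have equal length")
    n, p1_n, p2_n, q_n, freqs = _pair_counts(row_i, row_j)
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1_n / n, p2_n / n, q_n / n
    if min(gA, gC, gG, gT) <= 0:
        # degenerate composition: fall back to a JC-style distance
        p = P1 + P2 + Q
        arg = 1 - 4 * p / 3
        return float("inf") if arg <= 0 else -0.75 * math.log(arg)
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    e1 = 1 - P1 / k1 - Q / (2 * gR)
    e2 = 1 - P2 / k2 - Q / (2 * gY)
    e3 = 1 - Q / (2 * gR * gY)
    if min(e1, e2, e3) <= 0:
        return float("inf")

    def term(c: float, e: float) -> float:
        if gamma_shape is None or math.isinf(gamma_shape):
            return -c * math.log(e)
        a = gamma_shape
        return c * a * (e ** (-1.0 / a) - 1.0)

    return term(k1, e1) + term(k2, e2) + term(k3, e3)


def distance_matrix(alignment: ConcatAlignment,
                    gamma_shape: Optional[float] = None) -> np.ndarray:
    m = alignment.matrix()
    k = len(alignment.taxa)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = tn93_distance(m[i], m[j], gamma_shape)
    return D


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and optional bootstrap supports,
    stored as newick plus a dendropy handle."""

    newick: str
    tree: dendropy.Tree = field(repr=False, default=None)  # type: ignore
    degenerate: bool = False

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as frozensets (smaller-or-lexicographic
        side of each internal edge)."""
        taxa = frozenset(l.taxon.label for l in self.tree.leaf_node_iter())
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(clade) < len(taxa) - 1:
                out.add(min(clade, taxa - clade,
                            key=lambda s: (len(s), sorted(s))))
        return out


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Canonical neighbor joining with deterministic tie-breaks.

    Ties in the Q criterion are broken by label order.  Negative branch
    lengths are clamped to zero with the deficit moved to the sister
    branch, the standard remedy for slightly non-additive matrices.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise PlastcompError("distance matrix must be square and symmetric")
    k = len(labels)
    if k < 3:
        raise PlastcompError("neighbor joining needs at least 3 taxa")
    nodes = [f"{l}" for l in labels]  # newick fragments
    active = list(range(k))
    dist = {(i, j): D[i, j] for i in range(k) for j in range(k) if i != j}
    next_id = k
    labels_by_id = {i: labels[i] for i in range(k)}

    def d(i, j):
        return dist[(i, j)] if i != j else 0.0

    frag = {i: nodes[i] for i in range(k)}
    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * d(i, j) - r[i] - r[j]
                key = (qv, min(labels_by_id.get(i, ""), labels_by_id.get(j, "")),
                       max(labels_by_id.get(i, ""), labels_by_id.get(j, "")))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        if li < 0:
            lj += li  # move the deficit to the sister branch
            li = 0.0
        if lj < 0:
            li += lj
            li = max(li, 0.0)
            lj = 0.0
        new = next_id
        next_id += 1
        for x in active:
            if x in (i, j):
                continue
            dist[(new, x)] = dist[(x, new)] = 0.5 * (d(i, x) + d(j, x) - d(i, j))
        frag[new] = f"({frag[i]}:{li:.10f},{frag[j]}:{lj:.10f})"
        labels_by_id[new] = min(labels_by_id.get(i, ""), labels_by_id.get(j, ""))
        active = [x for x in active if x not in (i, j)] + [new]
    i, j = active
    lij = max(d(i, j), 0.0)
    newick = f"({frag[i]}:{lij / 2:.10f},{frag[j]}:{lij / 2:.10f});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return PhyloTree(newick=newick, tree=tree)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _pair_codes(m: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Per-pair per-column category codes for fast bootstrap tallies:
    0 identical, 1 A<->G, 2 C<->T, 3 transversion, 4 excluded."""
    a, c, g, t = (np.uint8(ord(x)) for x in "ACGT")
    k = m.shape[0]
    u = m.view(np.uint8)
    valid = np.isin(u, [a, c, g, t])
    codes = {}
    for i in range(k):
        for j in range(i + 1, k):
            x, y = u[i], u[j]
            code = np.full(m.shape[1], 4, dtype=np.uint8)
            ok = valid[i] & valid[j]
            same = ok & (x == y)
            code[same] = 0
            diff = ok & ~same
            pur = ((x == a) | (x == g)) & ((y == a) | (y == g))
            pyr = ((x == c) | (x == t)) & ((y == c) | (y == t))
            code[diff & pur] = 1
            code[diff & pyr] = 2
            code[diff & ~pur & ~pyr] = 3
            codes[(i, j)] = code
    return codes


def _tn93_from_counts(n, p1, p2, q, freqs, gamma_shape):
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / n, p2 / n, q / n
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    e1 = 1 - P1 / k1 - Q / (2 * gR)
    e2 = 1 - P2 / k2 - Q / (2 * gY)
    e3 = 1 - Q / (2 * gR * gY)
    if min(e1, e2, e3) <= 0:
        return float("inf")

    def term(cc, e):
        if gamma_shape is None or math.isinf(gamma_shape):
            return -cc * math.log(e)
        return cc * gamma_shape * (e ** (-1.0 / gamma_shape) - 1.0)

    return term(k1, e1) + term(k2, e2) + term(k3, e3)


def bootstrap_support(
    alignment: ConcatAlignment,
    reps: int = 100,
    seed: int = 0,
    gamma_shape: Optional[float] = None,
) -> tuple[PhyloTree, dict[frozenset, float]]:
    """NJ tree plus bootstrap support (%) for each of its bipartitions.

    Columns are resampled with replacement; base frequencies are taken
    from the full alignment (they are composition parameters, stable under
    resampling).  A degenerate alignment (all rows identical) yields a
    star tree flagged as such.
    """
    if reps < 1:
        raise PlastcompError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    m = alignment.matrix()
    taxa = alignment.taxa
    D0 = distance_matrix(alignment, gamma_shape)
    if np.allclose(D0, 0):
        star = "(" + ",".join(f"{t}:0" for t in taxa) + ");"
        tree = PhyloTree(newick=star,
                         tree=dendropy.Tree.get(data=star, schema="newick", preserve_underscores=True),
                         degenerate=True)
        logger.warning("all rows identical: star tree, supports undefined")
        return tree, {}
    main = nj_tree(D0, taxa)
    target = main.bipartitions()
    codes = _pair_codes(m)
    # full-alignment base frequencies per pair
    freqs_pair = {}
    a, c, g, t = (np.uint8(ord(x)) for x in "ACGT")
    u = m.view(np.uint8)
    for (i, j) in codes:
        both = np.concatenate([u[i], u[j]])
        f = np.array([(both == b).sum() for b in (a, c, g, t)], dtype=float)
        freqs_pair[(i, j)] = f / f.sum()
    ncol = m.shape[1]
    hits = {bp: 0 for bp in target}
    k = len(taxa)
    for _ in range(reps):
        idx = rng.integers(0, ncol, size=ncol)
        D = np.zeros((k, k))
        for (i, j), code in codes.items():
            counts = np.bincount(code[idx], minlength=5)
            n = int(counts[:4].sum())
            if n == 0:
                D[i, j] = D[j, i] = 0.0
                continue
            D[i, j] = D[j, i] = _tn93_from_counts(
                n, int(counts[1]), int(counts[2]), int(counts[3]),
                freqs_pair[(i, j)], gamma_shape)
        rep_tree = nj_tree(D, taxa)
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
    supports = {bp: 100.0 * h / reps for bp, h in hits.items()}
    return main, supports
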