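"""Synthetic plastome evolution with complete ground truth.

The generator builds an ancestral ~130 kb circular chloroplast genome with
the quadripartite layout typical of kelp plastomes (large and small single
copy regions separated by two exact reverse-complement inverted repeats
carrying the rRNA operon), then evolves it along a user-supplied rooted
phylogeny.  Every mutation event is recorded in a :class:`TruthLog`, which
can be projected against any leaf chosen as reference to yield the exact
set of expected variant calls.

The mutational model is deliberately simple and observation-oriented:

* substitutions follow a K2P-with-frequencies scheme (transition bias
  ``kappa``, stationary base frequencies) and are placed under an
  infinite-sites regime — each ancestral site mutates at most once anywhere
  in the tree.  This mirrors the interpretive assumption that a SNP shared
  by two species has a single origin, and makes sharing patterns exactly
  analysable;
* the two IR arms evolve in concert: a substitution in one arm is mirrored
  into the other, so arms stay exact reverse complements, and the
  substitution rate inside the IRs is multiplied by ``ir_rate_factor``;
* indels have geometric lengths capped at ``indel_len_cap``, fall in
  intergenic sequence with probability ``1 - genic_indel_fraction``, never
  inside the IRs, and genic indels are codon-length so reading frames stay
  intact;
* a fraction ``mnp_fraction`` of substitution events mutates two adjacent
  sites (multinucleotide polymorphisms);
* a fraction ``ils_fraction`` of substitution events is assigned a leaf
  presence pattern drawn from tree-discordant subsets, emulating the
  scattered sharing produced by incomplete lineage sorting;
* IR-flank gene translocations (optionally 5'-truncating, i.e.
  pseudogenizing, the moved gene) can be injected on chosen leaves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .core import (
    CircularGenome,
    Feature,
    GenomeAnnotation,
    PlastcompError,
    VariantCall,
    left_normalize,
    revcomp,
)

logger = logging.getLogger("plastcomp")

#: Five-taxon kelp topology with branch lengths (substitutions/site) chosen
#: so whole-genome pairwise divergence lands in the 2.5-3.3% band observed
#: between kelp plastomes (the IRs contribute almost no variation).
DEFAULT_TREE = (
    "(((L_digitata:0.014,L_solidungula:0.014):0.002,S_japonica:0.015):0.001,"
    "(C_costata:0.016,U_pinnatifida:0.017):0.001);"
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimParams:
    """Parameters of the plastome-evolution simulator.

    Defaults emulate the structure of kelp chloroplast genomes: ~130 kb,
    139 CDS, ~5.4 kb IRs with the rRNA operon, 17% intergenic sequence,
    rare small indels enriched intergenically, a small fraction of
    adjacent-doublet substitution events, and a strongly suppressed
    substitution rate inside the IRs.
    """

    tree: str = DEFAULT_TREE  # newick with branch lengths (subs/site)
    genome_length: int = 130_000
    n_cds: int = 139
    n_trna: int = 29
    ir_length: int = 5_400
    intergenic_fraction: float = 0.17
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.31, 0.19, 0.19, 0.31)
    mnp_fraction: float = 0.02
    indel_rate: float = 0.01  # events per site per unit branch length
    indel_len_p: float = 0.35  # geometric length parameter
    indel_len_cap: int = 10
    genic_indel_fraction: float = 0.1
    ir_rate_factor: float = 0.05
    ils_fraction: float = 0.0
    translocation_events: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intergenic_fraction", "mnp_fraction", "indel_len_p",
                     "genic_indel_fraction", "ir_rate_factor", "ils_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise PlastcompError(f"{name} must lie in [0, 1]")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise PlastcompError("base_freqs must sum to 1")


@dataclass(frozen=True)
class MutationEvent:
    """One mutation event in ancestral coordinates.

    ``sites`` holds one or more (position, old, new) substitution triples
    (two for MNP doublets; IR-mirrored changes add their mirror triples).
    Indel events use ``positions``/``inserted`` instead.
    """

    branch: str
    kind: str  # substitution | insertion | deletion
    leaves: frozenset
    region: str
    sites: tuple = ()  # substitutions: ((pos, old, new), ...)
    positions: tuple = ()  # deletions: deleted ancestral positions
    anchor: int = -1  # insertions: insert after this ancestral position
    inserted: str = ""
    mnp: bool = False
    discordant: bool = False


@dataclass(frozen=True)
class TranslocationRecord:
    species: str
    gene: str
    truncate_fraction: float
    pseudogenized: bool


class TruthLog:
    """Complete per-branch mutation record of one simulation.

    Holds the ancestor, the event list, per-leaf pre-translocation sequences
    and ancestral->leaf coordinate maps, so leaf sequences can be reproduced
    and expected variant calls projected against any reference leaf.
    """

    def __init__(self, params: SimParams, tree: dendropy.Tree,
                 ancestor: CircularGenome, annotation: GenomeAnnotation,
                 events: list[MutationEvent], leaf_names: list[str]):
        self.params = params
        self.tree = tree
        self.ancestor = ancestor
        self.annotation = annotation
        self.events = events
        self.leaf_names = leaf_names
        self.translocations: list[TranslocationRecord] = []
        self._leaf_seq: dict[str, str] = {}
        self._leaf_cum: dict[str, np.ndarray] = {}
        self._genic = annotation.genic_mask()

    # -- construction helpers (used by evolve) -----------------------------
    def _register_leaf(self, name: str, seq: str, cum: np.ndarray) -> None:
        self._leaf_seq[name] = seq
        self._leaf_cum[name] = cum

    # -- public API ---------------------------------------------------------
    def leaf_sequence(self, name: str) -> str:
        """Leaf sequence before any injected translocation."""
        return self._leaf_seq[name]

    def leaf_position(self, name: str, ancestral_pos: int) -> int:
        return int(self._leaf_cum[name][ancestral_pos])

    def substitution_events(self) -> list[MutationEvent]:
        return [e for e in self.events if e.kind == "substitution"]

    def discordant_fraction(self) -> float:
        subs = self.substitution_events()
        if not subs:
            return 0.0
        return sum(e.discordant for e in subs) / len(subs)

    def project(self, ref_leaf: str) -> dict[str, list[VariantCall]]:
        """Expected variant calls of every other leaf against ``ref_leaf``.

        SNP/indel alleles are expressed on the reference leaf's sequence and
        indels are left-normalized, matching what an exact variant caller
        should report.
        """
        if ref_leaf not in self._leaf_seq:
            raise PlastcompError(f"unknown reference leaf {ref_leaf!r}")
        rseq = self._leaf_seq[ref_leaf]
        rcum = self._leaf_cum[ref_leaf]
        anc = self.ancestor.seq
        out: dict[str, list[VariantCall]] = {
            n: [] for n in self.leaf_names if n != ref_leaf
        }
        for ev in self.events:
            in_ref = ref_leaf in ev.leaves
            for sp in out:
                in_sp = sp in ev.leaves
                if in_sp == in_ref:
                    continue
                calls = out[sp]
                if ev.kind == "substitution":
                    for (p, old, new) in ev.sites:
                        ref_b, alt_b = (new, old) if in_ref else (old, new)
                        pos = int(rcum[p])
                        calls.append(VariantCall(
                            ref_id=ref_leaf, pos=pos, ref_allele=ref_b,
                            alt_allele=alt_b, var_type="SNP", species=sp,
                            region="genic" if self._genic[p] else "intergenic",
                        ))
                elif ev.kind == "deletion":
                    ps = ev.positions
                    a = ps[0] - 1
                    pos = int(rcum[a])
                    anchor_frag = rseq[int(rcum[a]):int(rcum[a + 1])]
                    block = anc[ps[0]:ps[-1] + 1]
                    if in_sp:  # species lacks the bases present in reference
                        ref_al = rseq[int(rcum[a]):int(rcum[ps[-1] + 1])]
                        alt_al = anchor_frag
                        vtype = "deletion"
                    else:  # reference lacks them: insertion relative to ref
                        ref_al = anchor_frag
                        alt_al = anchor_frag + block
                        vtype = "insertion"
                    pos, ref_al, alt_al = left_normalize(rseq, pos, ref_al, alt_al)
                    calls.append(VariantCall(
                        ref_id=ref_leaf, pos=pos, ref_allele=ref_al,
                        alt_allele=alt_al, var_type=vtype, species=sp,
                        region=ev.region, large=len(block) >
                        10))
                elif ev.kind == "insertion":
                    a = ev.anchor
                    pos = int(rcum[a])
                    anchor_frag = rseq[int(rcum[a]):int(rcum[a + 1])]
                    if in_sp:  # species carries extra bases
                        ref_al = anchor_frag
                        alt_al = anchor_frag + ev.inserted
                        vtype = "insertion"
                    else:  # reference carries them: deletion relative to ref
                        ref_al = anchor_frag
                        alt_al = anchor_frag[0]
                        vtype = "deletion"
                    pos, ref_al, alt_al = left_normalize(rseq, pos, ref_al, alt_al)
                    calls.append(VariantCall(
                        ref_id=ref_leaf, pos=pos, ref_allele=ref_al,
                        alt_allele=alt_al, var_type=vtype, species=sp,
                        region=ev.region, large=len(ev.inserted) > 10))
        for sp in out:
            out[sp].sort(key=lambda c: (c.pos, c.ref_allele, c.alt_allele))
        return out


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, freqs) -> str:
    return "".join(np.char.decode(rng.choice(BASES, size=n, p=freqs)))


def _random_cds(rng: np.random.Generator, n_codons: int, freqs) -> str:
    """A CDS of ``n_codons`` codons: ATG start, TAA stop, no internal stop."""
    codons = []
    while len(codons) < n_codons - 2:
        block = rng.choice(BASES, size=(n_codons, 3), p=freqs)
        for row in block:
            codon = b"".join(row).decode()
            if codon not in STOP_CODONS:
                codons.append(codon)
                if len(codons) == n_codons - 2:
                    break
    return "ATG" + "".join(codons) + "TAA"


def generate_ancestor(params: SimParams, seed: Optional[int] = None
                      ) -> tuple[CircularGenome, GenomeAnnotation]:
    """Construct the ancestral quadripartite plastome and its annotation.

    Layout (linearized at the LSC start, the anchor gene psbA at position 0):
    LSC genes ... rpl32, trnL | IRa (rRNA operon, +) | rpl21, rpl3,
    SSC genes ... ycf17 | IRb (exact revcomp of IRa) | ycf37, psaM,
    remaining LSC genes ... wrap to origin.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    L = params.genome_length
    freqs = np.asarray(params.base_freqs)
    ir_len = params.ir_length

    # --- IR arm: spacer/rRNA operon layout ---------------------------------
    rrn16_len = round(0.28 * ir_len)
    rrn23_len = round(0.54 * ir_len)
    trn_lens = {"trnI": 74, "trnA": 73}
    rrn5_len = 119
    arm_genic = rrn16_len + rrn23_len + rrn5_len + sum(trn_lens.values())
    arm_spacer_total = ir_len - arm_genic
    if arm_spacer_total < 6:
        raise PlastcompError("ir_length too small for the rRNA operon")
    sp = [arm_spacer_total // 6] * 6
    sp[-1] += arm_spacer_total - sum(sp)
    arm_parts = [
        ("", sp[0]), ("rrn16", rrn16_len), ("", sp[1]), ("trnI", 74),
        ("", sp[2]), ("trnA", 73), ("", sp[3]), ("rrn23", rrn23_len),
        ("", sp[4]), ("rrn5", rrn5_len), ("", sp[5]),
    ]
    arm_seq_parts = []
    arm_features = []  # (name, kind, offset_in_arm, length)
    off = 0
    for name, ln in arm_parts:
        arm_seq_parts.append(_random_seq(rng, ln, freqs))
        if name:
            kind = "rRNA" if name.startswith("rrn") else "tRNA"
            arm_features.append((name, kind, off, ln))
        off += ln
    arm_seq = "".join(arm_seq_parts)
    assert len(arm_seq) == ir_len

    # --- budgets ------------------------------------------------------------
    genic_target = round(L * (1 - params.intergenic_fraction))
    non_ir_trna = params.n_trna - 2  # trnI/trnA live in the IRs
    if non_ir_trna < 1:
        raise PlastcompError("n_trna must be at least 3")
    trna_len = 74
    cds_budget = genic_target - 2 * arm_genic - non_ir_trna * trna_len
    if cds_budget < params.n_cds * 150:
        raise PlastcompError("geometry infeasible: genome too small for n_cds")
    budget_codons = cds_budget // 3
    mean_codons = budget_codons // params.n_cds
    jitter = rng.uniform(0.6, 1.4, size=params.n_cds)
    codons = np.maximum(40, (mean_codons * jitter).astype(int))
    codons = np.maximum(40, np.round(
        codons * budget_codons / codons.sum()).astype(int))
    residual = budget_codons - int(codons.sum())
    step = 1 if residual > 0 else -1
    i = 0
    while residual != 0 and i < 10 * params.n_cds:
        j = i % params.n_cds
        if step > 0 or codons[j] > 40:
            codons[j] += step
            residual -= step
        i += 1
    if residual != 0 or codons.min() < 40:
        raise PlastcompError("geometry infeasible: CDS budget too tight")

    # --- gene roster and ordering -------------------------------------------
    special = ["psbA", "rpl32", "rpl21", "rpl3", "ycf17", "ycf37", "psaM"]
    n_generic_cds = params.n_cds - len(special)
    generic_cds = [f"cds{i:03d}" for i in range(1, n_generic_cds + 1)]
    generic_trna = [f"trn{i:02d}" for i in range(1, non_ir_trna)]  # trnL is special

    n_ssc = min(12, n_generic_cds // 4)
    n_tail = min(18, n_generic_cds // 3)
    ssc_cds = generic_cds[:n_ssc]
    tail_cds = generic_cds[n_ssc:n_ssc + n_tail]
    lsc_cds = generic_cds[n_ssc + n_tail:]
    third = max(1, len(generic_trna) // 3)
    lsc_trna, ssc_trna, tail_trna = (generic_trna[: len(generic_trna) - 2 * third],
                                     generic_trna[len(generic_trna) - 2 * third:
                                                  len(generic_trna) - third],
                                     generic_trna[len(generic_trna) - third:])

    def interleave(cds_names, trna_names):
        out = [(n, "CDS") for n in cds_names]
        for i, t in enumerate(trna_names):
            out.insert((i * 5 + 2) % (len(out) + 1), (t, "tRNA"))
        return out

    order: list[tuple[str, str]] = []
    order.append(("psbA", "CDS"))
    order += interleave(lsc_cds, lsc_trna)
    order += [("rpl32", "CDS"), ("trnL", "tRNA")]
    order.append(("__IRA__", "IR"))
    order += [("rpl21", "CDS"), ("rpl3", "CDS")]
    order += interleave(ssc_cds, ssc_trna)
    order.append(("ycf17", "CDS"))
    order.append(("__IRB__", "IR"))
    order += [("ycf37", "CDS"), ("psaM", "CDS")]
    order += interleave(tail_cds, tail_trna)

    # --- sequences per gene --------------------------------------------------
    codon_iter = iter(codons.tolist())
    gene_seqs: dict[str, str] = {}
    gene_kind: dict[str, str] = {}
    for name, kind in order:
        if kind == "IR":
            continue
        if kind == "CDS":
            gene_seqs[name] = _random_cds(rng, next(codon_iter), freqs)
        else:
            gene_seqs[name] = _random_seq(rng, trna_len, freqs)
        gene_kind[name] = kind

    # --- spacers --------------------------------------------------------------
    n_slots = len(order) + 1  # gap before every element plus the final wrap gap
    spacer_total = L - 2 * ir_len - sum(len(s) for s in gene_seqs.values())
    min_spacer = 30
    if spacer_total < n_slots * min_spacer:
        raise PlastcompError("geometry infeasible: not enough intergenic budget")
    extra = rng.multinomial(spacer_total - n_slots * min_spacer,
                            np.full(n_slots, 1.0 / n_slots))
    spacers = (extra + min_spacer).tolist()

    # --- assembly --------------------------------------------------------------
    parts: list[str] = []
    features: list[Feature] = []
    ir_intervals: list[tuple[int, int]] = []
    pos = 0

    def emit(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    special_strand = {n: "+" for n in special + ["trnL"]}
    for i, (name, kind) in enumerate(order):
        emit(_random_seq(rng, spacers[i], freqs))
        if kind == "IR":
            start = pos
            if name == "__IRA__":
                emit(arm_seq)
                for gname, gkind, goff, glen in arm_features:
                    features.append(Feature(gname, gkind, start + goff,
                                            start + goff + glen, "+"))
            else:
                emit(revcomp(arm_seq))
                for gname, gkind, goff, glen in arm_features:
                    s = start + ir_len - (goff + glen)
                    features.append(Feature(gname, gkind, s, s + glen, "-"))
            ir_intervals.append((start, start + ir_len))
        else:
            strand = special_strand.get(
                name, "+" if rng.random() < 0.5 else "-")
            seq = gene_seqs[name]
            emit(seq if strand == "+" else revcomp(seq))
            features.append(Feature(name, kind, pos - len(seq), pos, strand))
    emit(_random_seq(rng, spacers[-1], freqs))
    seq = "".join(parts)
    assert len(seq) == L, (len(seq), L)

    genome = CircularGenome(id="ancestor", seq=seq)
    annotation = GenomeAnnotation(
        genome_id="ancestor", genome_length=L, features=features,
        ir_intervals=(ir_intervals[0], ir_intervals[1]),
    )
    return genome, annotation


# ---------------------------------------------------------------------------
# Evolution along the tree
# ---------------------------------------------------------------------------

def _weighted_sample(rng: np.random.Generator, weights: np.ndarray, n: int
                     ) -> np.ndarray:
    """Sample ``n`` distinct indices with probability proportional to weights
    (Gumbel top-k; positions with zero weight are never drawn)."""
    n = min(n, int((weights > 0).sum()))
    if n == 0:
        return np.empty(0, dtype=int)
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.size)
    idx = np.argpartition(-keys, n - 1)[:n]
    return np.sort(idx)


def _tree_clades(tree: dendropy.Tree) -> set[frozenset]:
    clades = set()
    for node in tree.preorder_node_iter():
        clades.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    return clades


def _compatible_patterns(tree: dendropy.Tree) -> set[frozenset]:
    """Leaf subsets compatible with the unrooted tree (subset or complement
    is a clade), plus singletons and trivial sets."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    clades = _tree_clades(tree)
    out = set()
    for c in clades:
        out.add(c)
        out.add(leaves - c)
    for l in leaves:
        out.add(frozenset([l]))
        out.add(leaves - {l})
    return out


def pattern_is_concordant(pattern: frozenset, tree: dendropy.Tree) -> bool:
    """True if a leaf presence pattern is compatible with the tree
    (the pattern or its complement forms a clade)."""
    return frozenset(pattern) in _compatible_patterns(tree)


def _discordant_pattern(rng: np.random.Generator, leaves: list[str],
                        compatible: set[frozenset]) -> frozenset:
    n = len(leaves)
    while True:
        size = int(rng.integers(2, n))  # 2 .. n-1
        idx = rng.choice(n, size=size, replace=False)
        pat = frozenset(leaves[i] for i in idx)
        if pat not in compatible:
            return pat


def _substitute(rng: np.random.Generator, old: str, kappa: float,
                freqs) -> str:
    """Draw a new base: transition with probability kappa/(kappa+2),
    otherwise one of the two transversions weighted by base frequency."""
    if rng.random() < kappa / (kappa + 2.0):
        return TRANSITION[old]
    tv = [b for b in "ACGT" if b != old and b != TRANSITION[old]]
    w = np.array([freqs[BASE_INDEX[b]] for b in tv])
    return tv[int(rng.choice(2, p=w / w.sum()))]


def evolve(
    ancestor: CircularGenome,
    annotation: GenomeAnnotation,
    params: SimParams,
) -> tuple[dict[str, tuple[CircularGenome, GenomeAnnotation]], TruthLog]:
    """Evolve the ancestor along ``params.tree``.

    Returns per-leaf (genome, annotation) pairs and the complete TruthLog.
    Branches are processed in preorder and events in position order, so a
    given seed always yields byte-identical output.
    """
    tree = dendropy.Tree.get(data=params.tree, schema="newick", preserve_underscores=True)
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise PlastcompError("tree must have at least two leaves")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    L = ancestor.length
    anc = ancestor.seq
    freqs = np.asarray(params.base_freqs)
    genic = annotation.genic_mask()

    ir = annotation.ir_intervals
    in_ir = np.zeros(L, dtype=bool)
    mirror = np.full(L, -1, dtype=int)
    if ir:
        (a_s, a_e), (b_s, b_e) = ir
        in_ir[a_s:a_e] = True
        in_ir[b_s:b_e] = True
        arm = a_e - a_s
        idx = np.arange(arm)
        mirror[a_s + idx] = b_e - 1 - idx
        mirror[b_s + idx] = a_e - 1 - idx

    weights = np.ones(L)
    weights[in_ir] = params.ir_rate_factor
    compatible = _compatible_patterns(tree) if len(leaves) >= 4 else set()

    events: list[MutationEvent] = []
    node_id = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        node_id[node] = node.taxon.label if node.is_leaf() else f"node{i}"

    comp = str.maketrans("ACGT", "TGCA")
    for node in tree.preorder_node_iter():
        t = node.edge.length or 0.0
        if node.parent_node is None or t <= 0:
            continue
        branch = node_id[node]
        clade = frozenset(l.taxon.label for l in node.leaf_iter())

        # --- substitutions -------------------------------------------------
        n_sub = rng.poisson(t * weights.sum())
        chosen = _weighted_sample(rng, weights, n_sub)
        chosen_set = set(chosen.tolist())
        for p in chosen.tolist():
            if weights[p] == 0:  # consumed as an MNP partner earlier this branch
                continue
            sites = []
            old = anc[p]
            new = _substitute(rng, old, params.kappa, freqs)
            sites.append((p, old, new))
            is_mnp = False
            if rng.random() < params.mnp_fraction:
                q = p + 1
                if q < L and weights[q] > 0 and q not in chosen_set \
                        and in_ir[q] == in_ir[p]:
                    old2 = anc[q]
                    sites.append((q, old2, _substitute(rng, old2,
                                                       params.kappa, freqs)))
                    is_mnp = True
            consumed = [s[0] for s in sites]
            if in_ir[p]:
                for (sp_, o_, n_) in list(sites):
                    m = int(mirror[sp_])
                    sites.append((m, o_.translate(comp), n_.translate(comp)))
                    consumed.append(m)
            pattern = clade
            discordant = False
            if compatible and params.ils_fraction > 0 \
                    and rng.random() < params.ils_fraction:
                pattern = _discordant_pattern(rng, leaves, compatible)
                discordant = True
            events.append(MutationEvent(
                branch=branch, kind="substitution", leaves=pattern,
                region="genic" if genic[p] else "intergenic",
                sites=tuple(sites), mnp=is_mnp, discordant=discordant,
            ))
            weights[consumed] = 0.0

        # --- indels ---------------------------------------------------------
        n_ind = rng.poisson(t * params.indel_rate * L)
        for _ in range(n_ind):
            want_genic = rng.random() < params.genic_indel_fraction
            length = min(int(rng.geometric(params.indel_len_p)),
                         params.indel_len_cap)
            if want_genic:
                length = min(((length + 2) // 3) * 3, 9)  # keep frames intact
            is_del = rng.random() < 0.5
            placed = False
            for _attempt in range(30):
                p = int(rng.integers(1, L - params.indel_len_cap - 1))
                if in_ir[p] or genic[p] != want_genic or weights[p] == 0:
                    continue
                if is_del:
                    span = slice(p, p + length)
                    if in_ir[span].any() or (genic[span] != want_genic).any() \
                            or (weights[span] == 0).any() or weights[p - 1] == 0:
                        continue
                    positions = tuple(range(p, p + length))
                    events.append(MutationEvent(
                        branch=branch, kind="deletion", leaves=clade,
                        region="genic" if want_genic else "intergenic",
                        positions=positions,
                    ))
                    weights[p - 1:p + length] = 0.0
                else:
                    if weights[p] == 0:
                        continue
                    ins = _random_seq(rng, length, freqs)
                    events.append(MutationEvent(
                        branch=branch, kind="insertion", leaves=clade,
                        region="genic" if want_genic else "intergenic",
                        anchor=p, inserted=ins,
                    ))
                    weights[p] = 0.0
                placed = True
                break
            if not placed:
                logger.debug("could not place an indel on branch %s", branch)

    truth = TruthLog(params, tree, ancestor, annotation, events, leaves)

    # --- build leaf sequences and annotations ------------------------------
    out: dict[str, tuple[CircularGenome, GenomeAnnotation]] = {}
    for leaf in leaves:
        frags = list(anc)
        for ev in events:
            if leaf not in ev.leaves:
                continue
            if ev.kind == "substitution":
                for (p, _old, new) in ev.sites:
                    frags[p] = new
            elif ev.kind == "deletion":
                for p in ev.positions:
                    frags[p] = ""
            else:
                frags[ev.anchor] = frags[ev.anchor] + ev.inserted
        lens = np.fromiter((len(f) for f in frags), dtype=np.int64, count=L)
        cum = np.concatenate(([0], np.cumsum(lens)))
        seq = "".join(frags)
        truth._register_leaf(leaf, seq, cum)
        feats = [replace(f, start=int(cum[f.start]), end=int(cum[f.end]))
                 for f in annotation.features]
        ir_iv = None
        if annotation.ir_intervals:
            ir_iv = tuple((int(cum[s]), int(cum[e]))
                          for s, e in annotation.ir_intervals)
        genome = CircularGenome(id=leaf, seq=seq)
        ann = GenomeAnnotation(genome_id=leaf, genome_length=len(seq),
                               features=feats, ir_intervals=ir_iv)  # type: ignore
        out[leaf] = (genome, ann)

    # --- injected translocations --------------------------------------------
    clade_of = {node_id[n]: frozenset(l.taxon.label for l in n.leaf_iter())
                for n in tree.preorder_node_iter()}
    for (branch, gene, frac) in params.translocation_events:
        targets = clade_of.get(branch)
        if targets is None:
            raise PlastcompError(f"translocation branch {branch!r} not in tree")
        for leaf in sorted(targets):
            g, a = out[leaf]
            g, a = inject_ir_translocation(g, a, gene, frac)
            out[leaf] = (g, a)
            truth.translocations.append(TranslocationRecord(
                species=leaf, gene=gene, truncate_fraction=frac,
                pseudogenized=frac > 0,
            ))
    return out, truth


# ---------------------------------------------------------------------------
# IR-flank translocation
# ---------------------------------------------------------------------------

def inject_ir_translocation(
    genome: CircularGenome,
    annotation: GenomeAnnotation,
    gene: str,
    truncate_fraction: float = 0.0,
) -> tuple[CircularGenome, GenomeAnnotation]:
    """Move a gene directly flanking one IR arm to the equivalent flank of
    the other arm, optionally deleting ``truncate_fraction`` of its 5' end
    (start codon included), which flags the moved copy as a pseudogene.

    The gene travels together with the spacer separating it from its arm;
    at the destination the spacer stays arm-adjacent, so a translocation
    with ``truncate_fraction == 0`` is exactly reversed by applying the
    operation again to the moved gene.
    """
    if annotation.ir_intervals is None:
        raise PlastcompError("annotation lacks IR intervals")
    hits = [f for f in annotation.features if f.gene_name == gene]
    if len(hits) != 1:
        raise PlastcompError(f"gene {gene!r} absent or duplicated")
    feat = hits[0]
    (a_s, a_e), (b_s, b_e) = sorted(annotation.ir_intervals)
    seq = genome.seq

    others = [f for f in annotation.features
              if f is not feat and not (f.start >= a_s and f.end <= a_e)
              and not (f.start >= b_s and f.end <= b_e)]

    def adjacent(side_start: int, side_end: int, before: bool) -> bool:
        """True if no other feature lies between the gene and the arm."""
        if before:  # gene upstream of arm at side_start
            if feat.end > side_start:
                return False
            return not any(f.start >= feat.end and f.end <= side_start
                           for f in others)
        if feat.start < side_end:
            return False
        return not any(f.start >= side_end and f.end <= feat.start
                       for f in others)

    # locate the gene relative to the two arms
    if feat.end <= a_s and adjacent(a_s, a_e, before=True):
        blk_s, blk_e = feat.start, a_s  # gene + spacer upstream of arm A
        target, gene_first = b_e, False  # destination: downstream of arm B
    elif feat.start >= a_e and feat.end <= b_s and adjacent(a_s, a_e, before=False):
        blk_s, blk_e = a_e, feat.end  # spacer + gene downstream of arm A
        target, gene_first = b_s, True  # destination: upstream of arm B
    elif feat.end <= b_s and feat.start >= a_e and adjacent(b_s, b_e, before=True):
        blk_s, blk_e = feat.start, b_s
        target, gene_first = a_e, False
    elif feat.start >= b_e and adjacent(b_s, b_e, before=False):
        blk_s, blk_e = b_e, feat.end
        target, gene_first = a_s, True
    else:
        raise PlastcompError(f"gene {gene!r} is not directly adjacent to an IR arm")

    gene_seq = seq[feat.start:feat.end]
    spacer = seq[blk_s:feat.start] if blk_s < feat.start else seq[feat.end:blk_e]

    cut = 0
    pseudo = feat.pseudo
    if truncate_fraction > 0:
        cut = int(round(truncate_fraction * len(gene_seq)))
        gene_seq = gene_seq[cut:] if feat.strand == "+" else gene_seq[:-cut]
        pseudo = True

    # content placed at the destination; the spacer stays arm-adjacent
    if gene_first:  # inserted upstream of the destination arm
        content = gene_seq + spacer
        gene_off = 0
    else:
        content = spacer + gene_seq
        gene_off = len(spacer)

    blk_len = blk_e - blk_s
    without = seq[:blk_s] + seq[blk_e:]
    tgt = target - blk_len if blk_s < target else target
    new_seq = without[:tgt] + content + without[tgt:]

    def remap(x: int) -> int:
        x2 = x - blk_len if x >= blk_e else x
        return x2 + len(content) if x2 >= tgt else x2

    new_features = []
    for f in annotation.features:
        if f is feat:
            continue
        new_features.append(replace(f, start=remap(f.start), end=remap(f.end)))
    g_start = tgt + gene_off
    new_features.append(replace(feat, start=g_start,
                                end=g_start + len(gene_seq), pseudo=pseudo))
    new_ir = tuple(sorted((remap(s), remap(e)) for s, e in ((a_s, a_e), (b_s, b_e))))
    new_genome = CircularGenome(id=genome.id, seq=new_seq,
                                origin_offset=genome.origin_offset)
    new_ann = GenomeAnnotation(genome_id=annotation.genome_id,
                               genome_length=len(new_seq),
                               features=new_features, ir_intervals=new_ir)  # type: ignore
    return new_genome, new_ann


# ---------------------------------------------------------------------------
# Truth output
# ---------------------------------------------------------------------------

def write_truth(truth: TruthLog, path_prefix: str | Path,
                reference_leaf: Optional[str] = None) -> None:
    """Write the mutation log as TSV plus a truth VCF against a reference leaf."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.events.tsv", "w") as fh:
        fh.write("branch\tkind\tregion\tleaves\tpositions\talleles\t"
                 "mnp\tdiscordant\n")
        for ev in truth.events:
            if ev.kind == "substitution":
                poss = ",".join(str(p) for p, _o, _n in ev.sites)
                alleles = ",".join(f"{o}>{n}" for _p, o, n in ev.sites)
            elif ev.kind == "deletion":
                poss = ",".join(map(str, ev.positions))
                alleles = "del"
            else:
                poss = str(ev.anchor)
                alleles = f"ins:{ev.inserted}"
            fh.write("\t".join([
                ev.branch, ev.kind, ev.region,
                ",".join(sorted(ev.leaves)), poss, alleles,
                str(int(ev.mnp)), str(int(ev.discordant)),
            ]) + "\n")
    if reference_leaf is not None:
        from .core import write_vcf

        projected = truth.project(reference_leaf)
        calls = sorted((c for calls in projected.values() for c in calls),
                       key=lambda c: c.pos)
        ref_genome = CircularGenome(id=reference_leaf,
                                    seq=truth.leaf_sequence(reference_leaf))
        write_vcf(calls, ref_genome, f"{prefix}.truth.vcf",
                  species_order=[n for n in truth.leaf_names
                                 if n != reference_leaf])


# ---------------------------------------------------------------------------
# Call-set evaluation against the truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CallSetScore:
    snp_recall: float
    snp_precision: float
    indel_recall: float
    indel_precision: float
    n_true_snps: int
    n_called_snps: int
    n_true_indels: int
    n_called_indels: int


def _match_indels(queries: list[VariantCall], targets: list[VariantCall],
                  tolerance: int) -> int:
    """Count queries with a one-to-one target match of identical type and
    length within ``tolerance`` bases.  An indel next to a SNP admits
    several equal-cost alignment representations, so exact allele matching
    would under-count genuinely detected events; distance-based matching is
    the usual benchmarking remedy."""
    used = [False] * len(targets)
    matched = 0
    for q in queries:
        best = None
        for i, t in enumerate(targets):
            if used[i] or t.var_type != q.var_type \
                    or t.indel_length != q.indel_length:
                continue
            dist = abs(t.pos - q.pos)
            if dist <= tolerance and (best is None or dist < best[0]):
                best = (dist, i)
        if best is not None:
            used[best[1]] = True
            matched += 1
    return matched


def score_calls(called: Sequence[VariantCall],
                truth_calls: Sequence[VariantCall],
                small_indel_max: int = 10,
                indel_tolerance: int = 10) -> CallSetScore:
    """Recall/precision of a call set for one species against the projected
    truth.  SNPs match exactly on (pos, ref, alt); small indels match by
    type and length within ``indel_tolerance`` bases (see _match_indels)."""
    def split(calls):
        snps = {c.key for c in calls if c.var_type == "SNP"}
        indels = [c for c in calls
                  if c.var_type != "SNP" and c.indel_length <= small_indel_max]
        return snps, indels

    t_snp, t_ind = split(truth_calls)
    c_snp, c_ind = split(called)

    matched = _match_indels(c_ind, t_ind, indel_tolerance)
    return CallSetScore(
        snp_recall=(len(c_snp & t_snp) / len(t_snp)) if t_snp else 1.0,
        snp_precision=(len(c_snp & t_snp) / len(c_snp)) if c_snp else 1.0,
        indel_recall=(matched / len(t_ind)) if t_ind else 1.0,
        indel_precision=(matched / len(c_ind)) if c_ind else 1.0,
        n_true_snps=len(t_snp), n_called_snps=len(c_snp),
        n_true_indels=len(t_ind), n_called_indels=len(c_ind),
    )
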