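"""Gene alignment, concatenation, TN93 distances, neighbor joining and
bootstrap, with independent oracles (ape's dist.dna via Rscript, additive
matrices, exhaustive least-squares topology search)."""

import itertools
import subprocess
import textwrap

import numpy as np
import pytest

from plastcomp.core import PlastcompError
from plastcomp.phylo import (
    ConcatAlignment,
    align_gene,
    bootstrap_support,
    concatenate,
    distance_matrix,
    extract_shared_cds,
    nj_tree,
    tn93_distance,
)


class TestAlignGene:
    def test_identical_sequences_no_gaps(self):
        rows = align_gene({"a": "ATGGCTTAA", "b": "ATGGCTTAA"}, "a")
        assert rows["a"] == rows["b"] == "ATGGCTTAA"

    def test_three_base_deletion_single_gap(self):
        ref = "ATGGCTGCAGCTTAA"
        qry = ref[:6] + ref[9:]
        rows = align_gene({"r": ref, "q": qry}, "r")
        assert rows["r"] == ref
        assert rows["q"].count("-") == 3
        gap = rows["q"].find("-")
        assert rows["q"][gap:gap + 3] == "---"

    def test_insertion_stacked_on_reference_gap(self):
        ref = "ATGGCTGCTTAA"
        qry = ref[:6] + "AAA" + ref[6:]
        rows = align_gene({"r": ref, "q": qry}, "r")
        assert rows["r"].count("-") == 3
        assert len(rows["r"]) == len(rows["q"]) == 15

    def test_empty_sequence_rejected(self):
        with pytest.raises(PlastcompError):
            align_gene({"r": "ATG", "q": ""}, "r")

    def test_simulated_gene_alignment_accuracy(self, small_sim):
        """At plastome divergences the merged alignment recovers the true
        homology columns almost perfectly (checked per shared gene)."""
        _p, _anc, _ann, leaves, _t = small_sim
        genomes = {n: g for n, (g, _a) in leaves.items()}
        annotations = {n: a for n, (_g, a) in leaves.items()}
        shared = extract_shared_cds(annotations, genomes)
        gene, seqs = next(iter(shared.items()))
        rows = align_gene(seqs, "S_japonica")
        # ungapped rows: per-column identity to the reference row is high
        ref_row = rows["S_japonica"]
        for sp, row in rows.items():
            ident = sum(a == b for a, b in zip(row, ref_row)) / len(ref_row)
            assert ident > 0.9


class TestExtractConcat:
    def test_all_genes_retained_without_loss(self, small_sim):
        _p, _anc, _ann, leaves, _t = small_sim
        genomes = {n: g for n, (g, _a) in leaves.items()}
        annotations = {n: a for n, (_g, a) in leaves.items()}
        shared = extract_shared_cds(annotations, genomes)
        n_cds = sum(1 for f in annotations["S_japonica"].features
                    if f.kind == "CDS")
        assert len(shared) == n_cds

    def test_pseudo_gene_dropped(self, small_sim):
        from plastcomp.simulate import inject_ir_translocation

        _p, _anc, _ann, leaves, _t = small_sim
        genomes = {n: g for n, (g, _a) in leaves.items()}
        annotations = {n: a for n, (_g, a) in leaves.items()}
        g2, a2 = inject_ir_translocation(*leaves["C_costata"], "ycf37", 0.3)
        genomes["C_costata"], annotations["C_costata"] = g2, a2
        shared = extract_shared_cds(annotations, genomes)
        assert "ycf37" not in shared

    def test_concatenate_partitions(self):
        g1 = {"a": "AAA", "b": "AAC"}
        g2 = {"a": "GGGGGG", "b": "GGGGGG"}
        concat = concatenate({"x": g1, "y": g2})
        assert concat.gene_partitions == {"x": (0, 3), "y": (3, 9)}
        assert concat.rows["a"] == "AAAGGGGGG"

    def test_concatenate_empty_rejected(self):
        with pytest.raises(PlastcompError):
            concatenate({})

    def test_total_columns_near_total_cds_length(self, small_sim):
        _p, _anc, ann, leaves, _t = small_sim
        genomes = {n: g for n, (g, _a) in leaves.items()}
        annotations = {n: a for n, (_g, a) in leaves.items()}
        shared = extract_shared_cds(annotations, genomes)
        alignments = {g: align_gene(s, "S_japonica")
                      for g, s in shared.items()}
        concat = concatenate(alignments)
        cds_len = sum(f.length for f in annotations["S_japonica"].features
                      if f.kind == "CDS")
        assert abs(concat.n_columns - cds_len) / cds_len < 0.01


class TestTn93:
    def test_identical_rows_zero(self):
        assert tn93_distance("ACGT" * 100, "ACGT" * 100) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), size=400))
        b = list(a)
        for p in rng.choice(400, size=12, replace=False):
            b[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[p]]
        b = "".join(b)
        assert tn93_distance(a, b) == pytest.approx(tn93_distance(b, a))

    def test_matches_ape_oracle(self, tmp_path):
        """Plain TN93 distance agrees with ape::dist.dna on a small pair."""
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), size=600))
        b = list(a)
        for p in rng.choice(600, size=30, replace=False):
            b[p] = {"A": "G", "G": "T", "C": "A", "T": "C"}[b[p]]
        b = "".join(b)
        fasta = tmp_path / "pair.fasta"
        fasta.write_text(f">a\n{a}\n>b\n{b}\n")
        script = textwrap.dedent(f"""
            suppressMessages(library(ape))
            aln <- read.dna("{fasta}", format="fasta")
            d <- dist.dna(aln, model="TN93")
            cat(sprintf("%.10f", as.numeric(d)))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        want = float(out.stdout.strip())
        got = tn93_distance(a, b, gamma_shape=None)
        assert got == pytest.approx(want, abs=1e-6)

    def test_gap_columns_pairwise_deleted(self):
        a = "ACGTACGTAC"
        b = "ACGTACGT-C"
        assert tn93_distance(a, b) == 0.0

    def test_monotone_in_substitutions(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), size=2000))
        b = list(a)
        prev = 0.0
        order = rng.permutation(2000)
        for step in range(20):
            for p in order[step * 5:(step + 1) * 5]:
                b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
            d = tn93_distance(a, "".join(b))
            assert d >= prev
            prev = d

    def test_gamma_correction_inflates(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), size=1000))
        b = list(a)
        for p in rng.choice(1000, size=30, replace=False):
            b[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[p]]
        b = "".join(b)
        assert tn93_distance(a, b, gamma_shape=0.2099) > tn93_distance(a, b)


def _additive_matrix(tree_dists, taxa):
    k = len(taxa)
    D = np.zeros((k, k))
    for (i, j), d in tree_dists.items():
        D[i, j] = D[j, i] = d
    return D


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree: ((A:2,B:3):1,(C:4,D:5)); path distances are additive
        taxa = ["A", "B", "C", "D"]
        paths = {(0, 1): 5, (0, 2): 7, (0, 3): 8, (1, 2): 8, (1, 3): 9,
                 (2, 3): 9}
        D = _additive_matrix(paths, taxa)
        tree = nj_tree(D, taxa)
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        # branch lengths recovered: check a leaf edge
        pdm = tree.tree.phylogenetic_distance_matrix()
        t = {x.label: x for x in tree.tree.taxon_namespace}
        for (i, j), d in paths.items():
            assert pdm.distance(t[taxa[i]], t[taxa[j]]) == pytest.approx(d)

    def test_three_taxa_closed_form(self):
        taxa = ["A", "B", "C"]
        D = _additive_matrix({(0, 1): 3, (0, 2): 4, (1, 2): 5}, taxa)
        tree = nj_tree(D, taxa)
        pdm = tree.tree.phylogenetic_distance_matrix()
        t = {x.label: x for x in tree.tree.taxon_namespace}
        assert pdm.distance(t["A"], t["B"]) == pytest.approx(3)
        assert pdm.distance(t["A"], t["C"]) == pytest.approx(4)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(PlastcompError, match="symmetric"):
            nj_tree(D, ["a", "b", "c"])

    def test_five_taxon_exhaustive_least_squares_oracle(self):
        """NJ on an additive 5-taxon matrix agrees with the best of all 15
        unrooted topologies under ordinary least squares."""
        taxa = list("ABCDE")
        # tree ((A:1,B:2):1,(C:1.5,D:1):2,E:3)
        paths = {(0, 1): 3, (0, 2): 5.5, (0, 3): 5, (0, 4): 5,
                 (1, 2): 6.5, (1, 3): 6, (1, 4): 6,
                 (2, 3): 2.5, (2, 4): 6.5, (3, 4): 6}
        D = _additive_matrix(paths, taxa)

        def topology_sse(split_pairs):
            """Least-squares fit of branch lengths for an unrooted topology
            given as its two non-trivial splits; returns SSE."""
            # edges: 5 leaf edges + 2 internal edges (defined by splits)
            edges = [frozenset([t]) for t in taxa] + \
                [frozenset(s) for s in split_pairs]
            rows, y = [], []
            for i, j in itertools.combinations(range(5), 2):
                row = []
                for e in edges:
                    sep = (taxa[i] in e) != (taxa[j] in e)
                    row.append(1.0 if sep else 0.0)
                rows.append(row)
                y.append(D[i, j])
            coef, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y),
                                            rcond=None)
            pred = np.array(rows) @ coef
            return float(((pred - np.array(y)) ** 2).sum())

        best = None
        for splits in itertools.combinations(
                [s for s in itertools.combinations(taxa, 2)], 2):
            s1, s2 = frozenset(splits[0]), frozenset(splits[1])
            if s1 & s2:
                continue  # incompatible pair of cherries
            sse = topology_sse([s1, s2])
            if best is None or sse < best[0] - 1e-12:
                best = (sse, {s1, s2})
        tree = nj_tree(D, taxa)
        assert tree.bipartitions() == best[1]

    def test_simulated_topology_recovery(self, small_sim):
        _p, _anc, _ann, leaves, _t = small_sim
        rows = {n: g.seq for n, (g, _a) in leaves.items()}
        # equalize row lengths by truncation (indels shift ends slightly)
        m = min(len(s) for s in rows.values())
        taxa = sorted(rows)
        concat = ConcatAlignment(taxa=taxa,
                                 rows={t: rows[t][:m] for t in taxa},
                                 gene_partitions={"all": (0, m)})
        D = distance_matrix(concat)
        tree = nj_tree(D, taxa)
        assert tree.bipartitions() == {
            frozenset({"L_digitata", "L_solidungula"}),
            frozenset({"C_costata", "U_pinnatifida"}),
        }


class TestBootstrap:
    def _alignment(self, small_sim):
        _p, _anc, _ann, leaves, _t = small_sim
        rows = {n: g.seq for n, (g, _a) in leaves.items()}
        m = min(len(s) for s in rows.values())
        taxa = sorted(rows)
        return ConcatAlignment(taxa=taxa,
                               rows={t: rows[t][:m] for t in taxa},
                               gene_partitions={"all": (0, m)})

    def test_same_seed_same_supports(self, small_sim):
        aln = self._alignment(small_sim)
        _t1, s1 = bootstrap_support(aln, reps=25, seed=7)
        _t2, s2 = bootstrap_support(aln, reps=25, seed=7)
        assert s1 == s2

    def test_identical_rows_degenerate_star(self):
        aln = ConcatAlignment(taxa=["a", "b", "c", "d"],
                              rows={t: "ACGT" * 50 for t in "abcd"},
                              gene_partitions={"g": (0, 200)})
        tree, supports = bootstrap_support(aln, reps=5, seed=1)
        assert tree.degenerate and supports == {}

    def test_taxon_order_invariance(self, small_sim):
        aln = self._alignment(small_sim)
        reordered = ConcatAlignment(taxa=list(reversed(aln.taxa)),
                                    rows=aln.rows,
                                    gene_partitions=aln.gene_partitions)
        _t1, s1 = bootstrap_support(aln, reps=25, seed=3)
        _t2, s2 = bootstrap_support(reordered, reps=25, seed=3)
        assert set(s1) == set(s2)

    def test_clean_data_high_support(self, small_sim):
        aln = self._alignment(small_sim)
        tree, supports = bootstrap_support(aln, reps=50, seed=5)
        assert supports
        assert min(supports.values()) >= 95.0
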