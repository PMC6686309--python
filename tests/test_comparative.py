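"""Cross-species SNP accounting: sharing, codon effects, N/S summary,
MNP pairs, density rates, Nei-Gojobori dN/dS, tRNA clustering."""

import math
from itertools import permutations

import numpy as np
import pytest
from Bio.Data import CodonTable

from plastcomp.core import (
    CircularGenome,
    Feature,
    GenomeAnnotation,
    PlastcompError,
    VariantCall,
)
from plastcomp.comparative import (
    build_share_matrix,
    codon_effect,
    compare_trna_positions,
    density_rates,
    find_mnp_pairs,
    gene_dnds,
    ns_summary,
    pattern_concordance,
    round_half_away,
    summarize_ns_rows,
)

TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def _snp(pos, alt, sp, ref="A"):
    return VariantCall("ref", pos, ref, alt, "SNP", sp)


class TestShareMatrix:
    def test_brute_force_example(self):
        calls = [_snp(5, "T", "A"), _snp(9, "G", "A"), _snp(5, "T", "B")]
        share = build_share_matrix(calls)
        assert share.unique_counts == {"A": 1, "B": 0}
        assert share.pair_counts[frozenset({"A", "B"})] == 1
        assert share.multi_counts == 0

    def test_identical_sets_in_three_species(self):
        calls = [_snp(p, "C", sp) for p in (3, 7, 11)
                 for sp in ("A", "B", "C")]
        share = build_share_matrix(calls)
        assert all(v == 0 for v in share.unique_counts.values())
        assert all(v == 0 for v in share.pair_counts.values())
        assert share.multi_counts == 3

    def test_partition_property(self, small_sim):
        """unique + pairwise + multi equals the number of distinct SNPs."""
        _p, _anc, _ann, _leaves, truth = small_sim
        calls = [c for cs in truth.project("S_japonica").values() for c in cs
                 if c.var_type == "SNP"]
        share = build_share_matrix(calls)
        distinct = len({c.key for c in calls})
        assert share.total == distinct

    def test_mixed_references_rejected(self):
        calls = [_snp(1, "C", "A"),
                 VariantCall("other", 2, "A", "C", "SNP", "B")]
        with pytest.raises(PlastcompError, match="mixed"):
            build_share_matrix(calls)

    def test_clade_patterns_without_ils(self, small_sim):
        _p, _anc, _ann, _leaves, truth = small_sim
        calls = [c for cs in truth.project("S_japonica").values() for c in cs]
        share = build_share_matrix(calls)
        ok, total = pattern_concordance(share, truth.tree)
        assert ok == total > 0


def _one_cds_setup(codon, strand="+"):
    """A genome whose single CDS is exactly one codon (plus enough context)."""
    if strand == "+":
        seq = "GGGG" + codon + "GGGG"
    else:
        from plastcomp.core import revcomp

        seq = "GGGG" + revcomp(codon) + "GGGG"
    genome = CircularGenome("ref", seq)
    ann = GenomeAnnotation("ref", len(seq),
                           [Feature("g", "CDS", 4, 7, strand)])
    return genome, ann


class TestCodonEffect:
    def test_exhaustive_code_table_oracle(self):
        """codon_effect vs direct translation-table lookup over all 64
        codons x 9 single-base changes (576 cases)."""
        def aa(c):
            return "*" if c in TABLE11.stop_codons else TABLE11.forward_table[c]

        mismatches = 0
        for c1 in ("".join(t) for t in __import__("itertools")
                   .product("ACGT", repeat=3)):
            genome, ann = _one_cds_setup(c1)
            for i in range(3):
                for b in "ACGT":
                    if b == c1[i]:
                        continue
                    call = VariantCall("ref", 4 + i, c1[i], b, "SNP", "s")
                    got = codon_effect(call, ann, genome)
                    c2 = c1[:i] + b + c1[i + 1:]
                    want = ("synonymous" if aa(c1) == aa(c2)
                            else "nonsynonymous")
                    if got != want:
                        mismatches += 1
        assert mismatches == 0

    def test_known_examples(self):
        genome, ann = _one_cds_setup("TTT")
        call = VariantCall("ref", 6, "T", "C", "SNP", "s")
        assert codon_effect(call, ann, genome) == "synonymous"  # Phe
        genome, ann = _one_cds_setup("ATG")
        call = VariantCall("ref", 6, "G", "A", "SNP", "s")
        assert codon_effect(call, ann, genome) == "nonsynonymous"  # Met->Ile

    def test_minus_strand_symmetry(self):
        """Effect on a '-' strand CDS equals the '+' strand computation on
        the reverse complement."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for codon in ("ATG", "TTT", "GGA", "CTC"):
            for i in range(3):
                for b in "ACGT":
                    if b == codon[i]:
                        continue
                    g_plus, a_plus = _one_cds_setup(codon, "+")
                    eff_plus = codon_effect(
                        VariantCall("ref", 4 + i, codon[i], b, "SNP", "s"),
                        a_plus, g_plus)
                    g_min, a_min = _one_cds_setup(codon, "-")
                    # position of codon base i on the '-' strand genome
                    pos = 4 + (2 - i)
                    eff_min = codon_effect(
                        VariantCall("ref", pos, comp[codon[i]], comp[b],
                                    "SNP", "s"), a_min, g_min)
                    assert eff_plus == eff_min

    def test_noncoding_cases(self):
        genome, ann = _one_cds_setup("ATG")
        call = VariantCall("ref", 0, "G", "A", "SNP", "s")
        assert codon_effect(call, ann, genome) == "noncoding"
        ann_pseudo = GenomeAnnotation("ref", genome.length,
                                      [Feature("g", "CDS", 4, 7, "+",
                                               pseudo=True)])
        call = VariantCall("ref", 5, "T", "C", "SNP", "s")
        assert codon_effect(call, ann_pseudo, genome) == "noncoding"


class TestNsSummary:
    def test_row_arithmetic(self):
        ns = summarize_ns_rows([("sp1", 2, 1)])
        row = ns.rows[0]
        assert (row.all, row.synonymous, row.nonsynonymous,
                row.ratio_percent) == (3, 2, 1, 50.0)

    def test_rounding_half_away(self):
        assert round_half_away(11.75, 1) == 11.8
        assert round_half_away(11.849, 1) == 11.8
        assert round_half_away(-2.25, 1) == -2.3
        assert round_half_away(0.05, 1) == 0.1

    def test_different_codon_changes_counted(self):
        # one codon, two species with different nonsynonymous alleles that
        # encode different amino acids
        genome, ann = _one_cds_setup("GGG")  # Gly
        calls = [VariantCall("ref", 4, "G", "A", "SNP", "s1"),  # AGG = Arg
                 VariantCall("ref", 4, "G", "T", "SNP", "s2")]  # TGG = Trp
        share = build_share_matrix(calls)
        ns = ns_summary(calls, share, ann, genome)
        assert ns.different_codon_changes == 1
        total = sum(r.all for r in ns.rows)
        assert total == 2

    def test_simulated_counts_consistent(self, small_sim):
        _p, _anc, _ann, leaves, truth = small_sim
        ref_a = leaves["S_japonica"][1]
        ref_g = leaves["S_japonica"][0]
        calls = [c for cs in truth.project("S_japonica").values() for c in cs
                 if c.var_type == "SNP"]
        share = build_share_matrix(calls)
        ns = ns_summary(calls, share, ref_a, ref_g)
        for row in ns.rows:
            assert row.all == row.synonymous + row.nonsynonymous
        assert ns.sum_row.all == sum(r.all for r in ns.rows)
        # purifying-free simulation: nonsynonymous >> 0 but bounded
        assert ns.sum_row.nonsynonymous > 0


class TestMnpPairs:
    def _ann(self, n=200, genic_until=100):
        return GenomeAnnotation("ref", n,
                                [Feature("g", "CDS", 0, genic_until, "+")])

    def test_run_rule(self):
        ann = self._ann()
        calls = [_snp(100, "C", "A"), _snp(101, "C", "A"), _snp(102, "C", "A")]
        mnp = find_mnp_pairs(calls, ann)
        assert sum(g + i for g, i in mnp.rows.values()) == 2

    def test_non_adjacent_no_pair(self):
        ann = self._ann()
        calls = [_snp(100, "C", "A"), _snp(102, "C", "A")]
        mnp = find_mnp_pairs(calls, ann)
        assert mnp.rows == {}

    def test_shared_pair_requires_identical_alts(self):
        ann = self._ann()
        calls = [_snp(10, "C", "A"), _snp(11, "C", "A"),
                 _snp(10, "C", "B"), _snp(11, "T", "B")]
        mnp = find_mnp_pairs(calls, ann)
        # different alt at the second position: two distinct single-species
        # pairs, no shared pair
        assert set(mnp.rows) == {"A", "B"}

    def test_mixed_pair_counted_intergenic(self):
        ann = self._ann(genic_until=100)
        calls = [_snp(99, "C", "A"), _snp(100, "C", "A")]
        mnp = find_mnp_pairs(calls, ann)
        assert mnp.rows["A"] == (0, 1)

    def test_genic_and_intergenic_classification(self):
        ann = self._ann(genic_until=100)
        calls = [_snp(10, "C", "A"), _snp(11, "C", "A"),
                 _snp(150, "C", "A"), _snp(151, "C", "A")]
        mnp = find_mnp_pairs(calls, ann)
        assert mnp.rows["A"] == (1, 1)


class TestDensity:
    def test_printed_style_rates(self):
        row = density_rates("x", 3615, 688, 108550, 21397)
        assert row.snp_per_kb_genic == 33.3
        assert row.snp_per_kb_intergenic == 32.2
        assert row.intergenic_genic_ratio == 0.2

    def test_zero_counts(self):
        row = density_rates("x", 0, 0, 1000, 1000)
        assert row.snp_per_kb_genic == 0.0
        assert row.snp_per_kb_intergenic == 0.0

    def test_zero_length_region_undefined(self):
        row = density_rates("x", 5, 5, 0, 1000)
        assert row.snp_per_kb_genic is None


class TestGeneDnds:
    def _oracle(self, c1, c2):
        """Independent exhaustive-pathway Nei-Gojobori for one codon pair."""
        def aa(c):
            return "*" if c in TABLE11.stop_codons else TABLE11.forward_table[c]

        diff = [i for i in range(3) if c1[i] != c2[i]]
        res = []
        for order in permutations(diff):
            cur, s, n, stop = c1, 0, 0, False
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1:]
                if aa(nxt) == "*" and nxt != c2:
                    stop = True
                if aa(nxt) == aa(cur):
                    s += 1
                else:
                    n += 1
                cur = nxt
            res.append((s, n, stop))
        valid = [(s, n) for s, n, t in res if not t] or \
            [(s, n) for s, n, _ in res]
        return (sum(s for s, _ in valid) / len(valid),
                sum(n for _, n in valid) / len(valid))

    def _sites_oracle(self, codon):
        def aa(c):
            return "*" if c in TABLE11.stop_codons else TABLE11.forward_table[c]

        s = 0.0
        for i in range(3):
            syn = sum(1 for b in "ACGT" if b != codon[i]
                      and aa(codon[:i] + b + codon[i + 1:]) == aa(codon))
            s += syn / 3
        return s, 3 - s

    def test_identical_cds(self):
        cds = "ATGGCTGCTTAA"
        r = gene_dnds(cds, cds)
        assert r.dn == r.ds == 0.0 and r.ratio is None

    def test_single_synonymous_difference(self):
        ref = "ATG" + "GCT" * 298 + "TAA"
        qry = "ATG" + "GCC" + "GCT" * 297 + "TAA"
        r = gene_dnds(ref, qry)
        assert r.dn == 0.0 and r.ds > 0 and r.ratio == 0.0

    def test_ten_codon_toy_matches_pathway_oracle(self):
        """Full NG computation on a 10-codon pair with multi-hit codons
        agrees with the independent exhaustive-pathway oracle to 1e-9."""
        ref = "ATG GCT TGT CAA GAA TTC GGA CAT ATT TAA".replace(" ", "")
        qry = "ATG GTT TGC CGA GAA TTA GGA CAC ATT TAA".replace(" ", "")
        S = N = sd = nd = 0.0
        for i in range(10):
            c1, c2 = ref[3 * i:3 * i + 3], qry[3 * i:3 * i + 3]
            s1, n1 = self._sites_oracle(c1)
            s2, n2 = self._sites_oracle(c2)
            S += (s1 + s2) / 2
            N += (n1 + n2) / 2
            ps, pn = self._oracle(c1, c2)
            sd += ps
            nd += pn

        def jc(p):
            return -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0

        want_ds, want_dn = jc(sd / S), jc(nd / N)
        r = gene_dnds(ref, qry)
        assert abs(r.ds - want_ds) < 1e-9
        assert abs(r.dn - want_dn) < 1e-9

    def test_internal_stop_rejected(self):
        ref = "ATGTAAGCTTAA"
        with pytest.raises(PlastcompError, match="stop"):
            gene_dnds(ref, ref)

    def test_neutral_simulation_ratio_near_one(self):
        """Uniform substitutions over sites give dN/dS well inside
        [0.2, 1.5] for genes of several hundred codons, and no systematic
        positive-selection signal appears; checked over 10 seeds."""
        non_stop = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                    if a + b + c not in ("TAA", "TAG", "TGA")]
        flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            body = list("".join(rng.choice(non_stop, size=600)))
            ref = "ATG" + "".join(body) + "TAA"
            qry = list(ref)
            k = 0
            while k < 110:  # ~6% neutral divergence
                p = int(rng.integers(3, len(ref) - 3))
                new = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}[qry[p]]
                cand = qry[:]
                cand[p] = new[int(rng.integers(3))]
                codon_i = p // 3
                codon = "".join(cand[3 * codon_i:3 * codon_i + 3])
                if codon in ("TAA", "TAG", "TGA"):
                    continue  # keep the frame stop-free
                qry = cand
                k += 1
            r = gene_dnds(ref, "".join(qry))
            assert 0.2 <= r.ratio <= 1.5
            if r.ratio > 1:
                flagged += 1
        assert flagged <= 5  # no systematic positive-selection signal


class TestTrnaPositions:
    def test_identical_annotations_cluster_completely(self):
        feats = [Feature(f"trn{i}", "tRNA", 300 * i, 300 * i + 70, "+")
                 for i in range(1, 4)]
        anns = {sp: GenomeAnnotation(sp, 1000, list(feats))
                for sp in ("a", "b", "c")}
        maps = {sp: (lambda p: p) for sp in anns}
        clusters = compare_trna_positions(anns, maps, "a")
        assert len(clusters) == 3
        assert all(not c.orphan and len(c.members) == 3 for c in clusters)

    def test_extra_trna_is_orphan(self):
        base = [Feature("trn1", "tRNA", 100, 170, "+")]
        extra = base + [Feature("trnX", "tRNA", 600, 670, "+")]
        anns = {"a": GenomeAnnotation("a", 1000, base),
                "b": GenomeAnnotation("b", 1000, extra)}
        maps = {sp: (lambda p: p) for sp in anns}
        clusters = compare_trna_positions(anns, maps, "a")
        orphans = [c for c in clusters if c.orphan]
        assert len(orphans) == 1 and "b" in orphans[0].members

    def test_zero_tolerance_splits_jittered_loci(self):
        anns = {"a": GenomeAnnotation("a", 1000,
                                      [Feature("t", "tRNA", 100, 170, "+")]),
                "b": GenomeAnnotation("b", 1000,
                                      [Feature("t", "tRNA", 105, 175, "+")])}
        maps = {sp: (lambda p: p) for sp in anns}
        loose = compare_trna_positions(anns, maps, "a", tolerance=200)
        tight = compare_trna_positions(anns, maps, "a", tolerance=0)
        assert len(loose) == 1 and len(tight) == 2

    def test_unmappable_locus_flagged(self):
        anns = {"a": GenomeAnnotation("a", 1000,
                                      [Feature("t", "tRNA", 100, 170, "+")]),
                "b": GenomeAnnotation("b", 1000,
                                      [Feature("t", "tRNA", 100, 170, "+")])}
        maps = {"b": (lambda p: None)}
        clusters = compare_trna_positions(anns, maps, "a")
        assert any(c.unplaced for c in clusters)
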