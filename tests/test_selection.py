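"""Selection scan: Fitch ancestral codons, NG-style counting, permutation
null, LRT and BH machinery."""

import itertools

import numpy as np
import pytest

import diveconv as dc
from diveconv._codon import CODON_INDEX, SENSE_CODONS, STOP_CODONS
from diveconv.io_model import NUCLEOTIDE, GeneAlignment


def _aln(taxa_rows):
    return GeneAlignment("g", list(taxa_rows), list(taxa_rows.values()),
                         NUCLEOTIDE, codon_aligned=True)


def exhaustive_parsimony_changes(tree, tip_codons):
    """Minimum number of codon changes over all internal labelings —
    independent oracle for the Fitch assignment's total change count."""
    internal = [i for i, tip in enumerate(tree.is_tip) if not tip]
    tips = {i: CODON_INDEX[tip_codons[tree.labels[i]]]
            for i, tip in enumerate(tree.is_tip) if tip}
    observed = sorted(set(tips.values()))
    best = None
    for labels in itertools.product(observed, repeat=len(internal)):
        assign = dict(zip(internal, labels))
        assign.update(tips)
        changes = sum(assign[i] != assign[tree.parent[i]]
                      for i in range(1, len(tree.labels)))
        best = changes if best is None else min(best, changes)
    return best


class TestFitchAncestralCodons:
    def test_identical_tips_propagate_to_root(self, toy_tree):
        aln = _aln({t: "ATGAAA" for t in "abcd"})
        anc = dc.fitch_ancestral_codons(aln, toy_tree)
        assert all(seq == "ATGAAA" for seq in anc.values())

    def test_two_tip_tie_breaks_lexicographically(self):
        tree = dc.read_tree_newick("(a:0.1,b:0.1);")
        anc = dc.fitch_ancestral_codons(_aln({"a": "AAA", "b": "AAG"}), tree)
        root_label = tree.labels[0]
        assert anc[root_label] == "AAA"

    def test_three_against_one_costs_one_change(self, toy_tree):
        aln = _aln({"a": "AAA", "b": "AAA", "c": "AAA", "d": "AAG"})
        anc = dc.fitch_ancestral_codons(aln, toy_tree)
        changes = sum(anc[toy_tree.labels[i]] != anc[toy_tree.labels[toy_tree.parent[i]]]
                      for i in range(1, len(toy_tree.labels)))
        assert changes == 1
        assert changes == exhaustive_parsimony_changes(
            toy_tree, {t: r for t, r in zip(aln.taxa, aln.rows)})

    @pytest.mark.parametrize("tips", [
        {"a": "AAA", "b": "AAG", "c": "AAT", "d": "AAT"},
        {"a": "TTT", "b": "TTC", "c": "TTA", "d": "CTA"},
        {"a": "GGG", "b": "CCC", "c": "GGG", "d": "CCC"},
    ])
    def test_change_count_matches_exhaustive_oracle(self, toy_tree, tips):
        anc = dc.fitch_ancestral_codons(_aln(tips), toy_tree)
        changes = sum(anc[toy_tree.labels[i]] != anc[toy_tree.labels[toy_tree.parent[i]]]
                      for i in range(1, len(toy_tree.labels)))
        assert changes == exhaustive_parsimony_changes(toy_tree, tips)

    def test_gapped_input_rejected(self, toy_tree):
        aln = GeneAlignment("g", list("abcd"), ["AT-", "ATG", "ATG", "ATG"],
                            NUCLEOTIDE)
        with pytest.raises(ValueError, match="gapped"):
            dc.fitch_ancestral_codons(aln, toy_tree)

    def test_taxon_mismatch_rejected(self, toy_tree):
        aln = _aln({"a": "ATG", "b": "ATG", "c": "ATG", "z": "ATG"})
        with pytest.raises(ValueError, match="match"):
            dc.fitch_ancestral_codons(aln, toy_tree)


class TestNgSiteCounts:
    def test_phenylalanine_by_hand(self):
        # TTT: position 3 has TTC synonymous, TTA/TTG nonsynonymous;
        # positions 1-2 all nonsynonymous, no stop neighbors
        n, s = dc.ng_site_counts("TTT")
        assert s == pytest.approx(1.0 / 3.0)
        assert n == pytest.approx(8.0 / 3.0)

    def test_methionine_has_no_synonymous_sites(self):
        n, s = dc.ng_site_counts("ATG")
        assert s == 0.0

    def test_totals_conserved_up_to_stop_exclusion(self):
        for seq in ("TTTATGAAA", "TGGCGACGG"):
            n, s = dc.ng_site_counts(seq)
            n_codons = len(seq) // 3
            stop_neighbors = sum(
                1 for k in range(n_codons)
                for pos in range(3) for nt in "ACGT"
                if nt != seq[3 * k + pos]
                and (seq[3 * k:3 * k + pos] + nt + seq[3 * k + pos + 1:3 * k + 3])
                in STOP_CODONS)
            assert n + s == pytest.approx(3 * n_codons - stop_neighbors / 3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            dc.ng_site_counts("TAA")


class TestCountBranchChanges:
    def test_identity_is_zero(self):
        assert dc.count_branch_changes("AAA", "AAA") == (0.0, 0.0)

    def test_single_synonymous_step(self):
        assert dc.count_branch_changes("TTT", "TTC") == (0.0, 1.0)

    def test_single_nonsynonymous_step(self):
        assert dc.count_branch_changes("TTT", "GTT") == (1.0, 0.0)

    def test_two_position_pathways_average(self):
        # TTT (Phe) -> TTA via TTA-path intermediates; both orders checked
        nd, sd = dc.count_branch_changes("TTT", "CTA")
        assert nd + sd == pytest.approx(2.0)

    def test_pathway_length_conserved_over_random_pairs(self, rng):
        codons = rng.choice(len(SENSE_CODONS), size=(100, 2))
        for i, j in codons:
            a, b = SENSE_CODONS[i], SENSE_CODONS[j]
            nd, sd = dc.count_branch_changes(a, b)
            hamming = sum(x != y for x, y in zip(a, b))
            assert nd + sd == pytest.approx(hamming)

    def test_symmetric_for_reversible_pairs(self):
        for a, b in [("TTT", "TTC"), ("AAA", "AAG"), ("ATG", "ACG")]:
            assert dc.count_branch_changes(a, b) == dc.count_branch_changes(b, a)


class TestOmegaByClass:
    def test_identical_sequences_give_undefined_omega(self, toy_tree, toy_partition):
        aln = _aln({t: "ATGAAATTT" for t in "abcd"})
        fg, bg = dc.omega_by_class(aln, toy_tree, toy_partition)
        assert fg.nd == fg.sd == bg.nd == bg.sd == 0.0
        assert fg.omega is None and bg.omega is None

    def test_partition_tree_mismatch_rejected(self, toy_tree):
        part = dc.TaxonPartition(frozenset({"a", "zz"}), frozenset({"c", "d"}))
        aln = _aln({t: "ATG" for t in "abcd"})
        with pytest.raises(ValueError, match="not in tree"):
            dc.omega_by_class(aln, toy_tree, part)

    def test_equal_omegas_recovered_near_one(self, waterfowl_tree, waterfowl_partition):
        cfg = dc.ModelConfig(mode="codon", length=2000, omega_bg=1.0, seed=17)
        aln, _ = dc.simulate_gene(waterfowl_tree, cfg)
        fg, bg = dc.omega_by_class(aln, waterfowl_tree, waterfowl_partition)
        assert fg.omega == pytest.approx(1.0, rel=0.25)
        assert bg.omega == pytest.approx(1.0, rel=0.25)

    def test_branch_class_bookkeeping(self, waterfowl_tree, waterfowl_partition):
        cfg = dc.ModelConfig(mode="codon", length=300, omega_bg=0.5, seed=23)
        aln, _ = dc.simulate_gene(waterfowl_tree, cfg)
        fg, bg = dc.omega_by_class(aln, waterfowl_tree, waterfowl_partition)
        # 8 foreground terminal branches; everything else is background
        assert fg.branch_class == "foreground" and bg.branch_class == "background"
        assert fg.total_branch_length < bg.total_branch_length
        # N + S per class stays near 3 x codon count (stop exclusion aside)
        for cls in (fg, bg):
            assert cls.n_sites + cls.s_sites == pytest.approx(3 * 300, rel=0.05)


class TestPermutationTest:
    def test_same_seed_same_p(self, waterfowl_tree, waterfowl_partition):
        cfg = dc.ModelConfig(mode="codon", length=300, omega_bg=0.5, seed=31)
        aln, _ = dc.simulate_gene(waterfowl_tree, cfg)
        r1 = dc.permutation_test(aln, waterfowl_tree, waterfowl_partition,
                                 n_perm=99, seed=7)
        r2 = dc.permutation_test(aln, waterfowl_tree, waterfowl_partition,
                                 n_perm=99, seed=7)
        assert r1.p_value == r2.p_value
        assert 0.0 < r1.p_value <= 1.0

    def test_undefined_delta_reports_p_one(self, toy_tree, toy_partition):
        aln = _aln({t: "ATGAAATTT" for t in "abcd"})
        res = dc.permutation_test(aln, toy_tree, toy_partition, n_perm=99, seed=1)
        assert res.p_value == 1.0 and res.undefined

    def test_foreground_equal_to_tipset_rejected(self, toy_tree):
        part = dc.TaxonPartition(frozenset("abcd"), frozenset({"x"}))
        aln = _aln({t: "ATGAAA" for t in "abcd"})
        with pytest.raises(ValueError, match="permutation space"):
            dc.permutation_test(aln, toy_tree, part, n_perm=99, seed=1)

    def test_elevated_foreground_omega_yields_small_p(self, waterfowl_tree,
                                                      waterfowl_partition):
        cfg = dc.ModelConfig(mode="codon", length=2000, omega_bg=0.2, omega_fg=2.0,
                             foreground_tips=frozenset(waterfowl_partition.foreground),
                             seed=41)
        aln, _ = dc.simulate_gene(waterfowl_tree, cfg)
        res = dc.permutation_test(aln, waterfowl_tree, waterfowl_partition,
                                  n_perm=199, seed=2)
        assert res.p_value <= 0.05


class TestLrtMachinery:
    def test_chi_square_quantile(self):
        assert dc.lrt_pvalue(0.0, 3.841459 / 2.0, df=1) == pytest.approx(0.05, abs=1e-3)

    def test_equal_likelihoods_give_p_one(self):
        assert dc.lrt_pvalue(-100.0, -100.0) == 1.0

    def test_worse_alternative_clamped(self):
        assert dc.lrt_pvalue(-100.0, -105.0) == 1.0

    def test_mixture_null_halves_tail(self):
        stat = 3.0
        plain = dc.lrt_pvalue(0.0, stat / 2.0, df=1)
        mixed = dc.lrt_pvalue(0.0, stat / 2.0, df=1, mixture=True)
        assert mixed == pytest.approx(plain / 2.0)

    def test_nonfinite_likelihood_rejected(self):
        with pytest.raises(ValueError):
            dc.lrt_pvalue(float("nan"), 0.0)

    def test_lrt_table_flags_by_fdr(self):
        records = [("g1", -100.0, -90.0), ("g2", -100.0, -99.9), ("g3", -50.0, -50.0)]
        table = dc.lrt_table(records)
        assert list(table.gene_id) == ["g1", "g2", "g3"]
        assert table.loc[0, "significant"]
        assert not table.loc[2, "significant"]


class TestBhFdr:
    def test_step_up_by_hand(self):
        q = dc.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert dc.bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_ones_stay_one(self):
        assert np.allclose(dc.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_order_preserved_and_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=20)
        q = dc.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dc.bh_fdr([0.5, 1.5])
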