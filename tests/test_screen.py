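"""Convergence screen: column classifier, alignment scan, gene aggregation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diveconv as dc
from diveconv.io_model import PROTEIN, GeneAlignment
from diveconv.screen import ScreenPolicy, UnknownTaxonError


from _oracles import brute_force_call

# immutable partition shared by the property tests (module-level so
# hypothesis can reuse it across generated examples)
PART_3BG_2FG = dc.TaxonPartition(frozenset({"f1", "f2"}), frozenset({"b1", "b2", "b3"}))


@pytest.fixture
def part_3bg_2fg():
    return PART_3BG_2FG


class TestClassifyColumn:
    def test_uniform_bg_vs_uniform_fg_called(self, waterfowl_partition):
        column = {t: "L" for t in waterfowl_partition.background}
        column.update({t: "M" for t in waterfowl_partition.foreground})
        assert dc.classify_column(column, waterfowl_partition) == ("L", "M")

    def test_invariant_column_not_called(self, waterfowl_partition):
        column = {t: "L" for t in waterfowl_partition.taxa}
        assert dc.classify_column(column, waterfowl_partition) is None

    def test_nonuniform_foreground_not_called(self, waterfowl_partition):
        column = {t: "L" for t in waterfowl_partition.background}
        fg = sorted(waterfowl_partition.foreground)
        column.update({t: "M" for t in fg[:-1]})
        column[fg[-1]] = "L"
        assert dc.classify_column(column, waterfowl_partition) is None

    def test_gap_vetoes_under_strict(self, waterfowl_partition):
        column = {t: "L" for t in waterfowl_partition.background}
        column.update({t: "M" for t in waterfowl_partition.foreground})
        column[sorted(waterfowl_partition.background)[0]] = "-"
        assert dc.classify_column(column, waterfowl_partition) is None

    def test_tolerate_k_allows_bounded_missing(self, waterfowl_partition):
        column = {t: "L" for t in waterfowl_partition.background}
        column.update({t: "M" for t in waterfowl_partition.foreground})
        column[sorted(waterfowl_partition.background)[0]] = "-"
        policy = ScreenPolicy(missing_policy="tolerate_k", max_missing=1,
                              require_all_taxa_present=False)
        assert dc.classify_column(column, waterfowl_partition, policy) == ("L", "M")
        column[sorted(waterfowl_partition.background)[1]] = "X"
        assert dc.classify_column(column, waterfowl_partition, policy) is None

    def test_unknown_taxon_rejected(self, part_3bg_2fg):
        with pytest.raises(UnknownTaxonError):
            dc.classify_column({"zz": "A"}, part_3bg_2fg)

    @settings(max_examples=200, deadline=None)
    @given(chars=st.lists(st.sampled_from("ACD-X*"), min_size=5, max_size=5))
    def test_matches_brute_force_oracle(self, chars):
        part = PART_3BG_2FG
        taxa = sorted(part.background) + sorted(part.foreground)
        column = dict(zip(taxa, chars))
        assert dc.classify_column(column, part) == brute_force_call(column, part)

    @settings(max_examples=100, deadline=None)
    @given(chars=st.lists(st.sampled_from("ACDL"), min_size=5, max_size=5))
    def test_swap_symmetry(self, chars):
        part = PART_3BG_2FG
        taxa = sorted(part.background) + sorted(part.foreground)
        column = dict(zip(taxa, chars))
        call = dc.classify_column(column, part)
        swapped = dc.classify_column(column, part.swapped())
        assert swapped == (None if call is None else (call[1], call[0]))

    @settings(max_examples=100, deadline=None)
    @given(chars=st.lists(st.sampled_from("ACDL"), min_size=5, max_size=5),
           new_char=st.sampled_from("ACDL"), to_fg=st.booleans())
    def test_adding_a_taxon_never_creates_calls(self, chars, new_char, to_fg):
        part = PART_3BG_2FG
        taxa = sorted(part.background) + sorted(part.foreground)
        column = dict(zip(taxa, chars))
        if dc.classify_column(column, part) is not None:
            return
        if to_fg:
            bigger = dc.TaxonPartition(part.foreground | {"new"}, part.background)
        else:
            bigger = dc.TaxonPartition(part.foreground, part.background | {"new"})
        column["new"] = new_char
        assert dc.classify_column(column, bigger) is None


class TestScanAlignment:
    def test_toy_columns_derived_by_hand(self, part_3bg_2fg):
        # columns: invariant A | bg L / fg M | invariant G | bg T / fg S
        rows = {"b1": "ALGT", "b2": "ALGT", "b3": "ALGT",
                "f1": "AMGS", "f2": "AMGS"}
        aln = GeneAlignment("toy", list(rows), list(rows.values()), PROTEIN)
        sites = dc.scan_alignment(aln, part_3bg_2fg)
        assert [(s.column, s.bg_residue, s.fg_residue) for s in sites] == \
            [(2, "L", "M"), (4, "T", "S")]

    def test_reference_positions_reported(self, part_3bg_2fg):
        rows = {"b1": "-LGT", "b2": "ALGT", "b3": "ALGT",
                "f1": "AMGS", "f2": "AMGS"}
        aln = GeneAlignment("toy", list(rows), list(rows.values()), PROTEIN)
        policy = ScreenPolicy(missing_policy="tolerate_k", max_missing=1,
                              require_all_taxa_present=False)
        sites = dc.scan_alignment(aln, part_3bg_2fg, policy, ref_taxon="b1")
        # b1 is gapped at column 1, so reference positions shift down by one
        assert [(s.column, s.ref_position) for s in sites] == [(2, 1), (4, 3)]

    def test_planted_sites_recovered(self, waterfowl_tree, waterfowl_partition):
        aln, _ = dc.simulate_gene(waterfowl_tree,
                                  dc.ModelConfig(mode="protein", length=120, seed=21))
        planted, truth = dc.plant_convergent_sites(aln, waterfowl_partition, 4, seed=22)
        sites = dc.scan_alignment(planted, waterfowl_partition)
        found = {(s.column, s.bg_residue, s.fg_residue) for s in sites}
        assert set(truth.planted_columns) <= found

    def test_missing_partition_taxon_rejected_when_required(self, part_3bg_2fg):
        aln = GeneAlignment("toy", ["b1", "b2", "f1", "f2"],
                            ["AL", "AL", "AM", "AM"], PROTEIN)
        with pytest.raises(ValueError, match="missing"):
            dc.scan_alignment(aln, part_3bg_2fg)


class TestScreenGenes:
    def test_worked_example_recovers_all_reported_genes(self):
        from diveconv import waterfowl
        alignments = waterfowl.build_worked_example(n_decoys=4, seed=0)
        sites, genes = dc.screen_genes(alignments, waterfowl.default_partition(),
                                       ref_taxon=waterfowl.REFERENCE_TAXON)
        expected = {(g, p, b, f) for g, p, b, f
                    in waterfowl.KNOWN_CONVERGENT_SUBSTITUTIONS}
        observed = {(r.gene_id, r.ref_position, r.bg_residue, r.fg_residue)
                    for r in sites.itertuples()}
        assert observed == expected
        assert len(genes) == 11

    def test_empty_input_gives_empty_tables(self, waterfowl_partition):
        sites, genes = dc.screen_genes([], waterfowl_partition)
        assert sites.empty and genes.empty

    def test_duplicate_gene_ids_rejected(self, part_3bg_2fg):
        rows = ["AL", "AL", "AL", "AM", "AM"]
        taxa = ["b1", "b2", "b3", "f1", "f2"]
        a1 = GeneAlignment("dup", taxa, rows, PROTEIN)
        a2 = GeneAlignment("dup", taxa, rows, PROTEIN)
        with pytest.raises(ValueError, match="duplicate"):
            dc.screen_genes([a1, a2], part_3bg_2fg)
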