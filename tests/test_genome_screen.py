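import numpy as np
import pytest

from centrodyad.dyad_analysis import reverse_complement
from centrodyad.genome_screen import (
    dollo_loss_events,
    find_orfs,
    genes_lost_anywhere,
    screen_intergenic,
    shared_pre_post_losses,
    species_retaining_all,
)
from centrodyad.io_formats import SequenceRecord, SpeciesTree

from _oracles import dollo_min_events, maximal_absent_clades, orf_oracle
from conftest import make_matrix, random_dna

WGD4 = {"A": "PRE_WGD", "B": "PRE_WGD", "C": "POST_WGD", "D": "POST_WGD"}


def toy_matrix(cells, genes=("g1", "g2", "g3", "g4", "g5")):
    return make_matrix(list(genes), list(WGD4), WGD4, cells, default_post=2)


class TestMatrixScreens:
    def test_lost_anywhere_requires_a_zero_cell(self):
        m = toy_matrix({("g2", "C"): 0, ("g4", "A"): 0, ("g5", "D"): 1})
        assert genes_lost_anywhere(m) == ["g2", "g4"]

    def test_single_ohnolog_retention_is_not_loss_by_default(self):
        m = toy_matrix({("g1", "C"): 1})
        assert genes_lost_anywhere(m) == []
        assert genes_lost_anywhere(m, single_copy_post_is_loss=True) == ["g1"]

    def test_lost_anywhere_monotone_under_extra_zeros(self):
        base = {("g2", "C"): 0}
        m1 = toy_matrix(base)
        m2 = toy_matrix({**base, ("g3", "B"): 0})
        assert set(genes_lost_anywhere(m1)) <= set(genes_lost_anywhere(m2))

    def test_shared_pre_post_requires_loss_on_both_sides(self):
        m = toy_matrix(
            {("g1", "C"): 0,                      # post only
             ("g2", "A"): 0,                      # pre only
             ("g3", "B"): 0, ("g3", "D"): 0,      # both
             ("g4", "A"): 0, ("g4", "C"): 0}      # both
        )
        assert shared_pre_post_losses(m) == ["g3", "g4"]

    def test_species_retaining_all(self):
        m = toy_matrix({("g1", "C"): 0, ("g2", "C"): 0, ("g2", "D"): 0})
        assert species_retaining_all(m, []) == 4
        assert species_retaining_all(m, ["g1", "g2"]) == 2
        m_absent = toy_matrix(
            {("g1", sp): 0 for sp in WGD4}
        )
        assert species_retaining_all(m_absent, ["g1"]) == 0
        with pytest.raises(ValueError, match="unknown gene"):
            species_retaining_all(m, ["nope"])


class TestDolloLossEvents:
    def test_clade_loss_maps_to_single_stem_event(self, quartet_tree):
        m = toy_matrix({("g1", "A"): 0, ("g1", "B"): 0})
        report = dollo_loss_events(m, quartet_tree, "g1")
        assert report.loss_branches == frozenset({"A|B"})
        assert report.species_lost == frozenset({"A", "B"})
        assert report.lost_in_pre and not report.lost_in_post

    def test_scattered_losses_map_to_leaf_events(self, quartet_tree):
        m = toy_matrix({("g1", "A"): 0, ("g1", "C"): 0})
        report = dollo_loss_events(m, quartet_tree, "g1")
        assert report.loss_branches == frozenset({"A", "C"})

    def test_gene_absent_everywhere_uses_root_children(self, quartet_tree):
        m = toy_matrix({("g1", sp): 0 for sp in WGD4})
        report = dollo_loss_events(m, quartet_tree, "g1")
        assert report.loss_branches == frozenset({"A|B", "C|D"})

    def test_no_loss_gives_empty_report(self, quartet_tree):
        m = toy_matrix({})
        report = dollo_loss_events(m, quartet_tree, "g1")
        assert report.loss_branches == frozenset()
        assert report.n_events == 0

    def test_mismatched_species_sets_rejected(self, quartet_tree):
        wgd = {"A": "PRE_WGD", "B": "PRE_WGD", "X": "POST_WGD"}
        m = make_matrix(["g1"], ["A", "B", "X"], wgd, {})
        with pytest.raises(ValueError, match="differ"):
            dollo_loss_events(m, quartet_tree, "g1")

    def test_random_patterns_match_exhaustive_minimisation(self, rng):
        tree = SpeciesTree.from_newick("(((A,B),(C,(D,E))),(F,G));")
        leaves = tree.leaf_labels
        wgd = {sp: "POST_WGD" for sp in leaves}
        for _ in range(25):
            absent = {sp for sp in leaves if rng.random() < 0.4}
            if len(absent) == len(leaves):
                continue
            m = make_matrix(
                ["g1"], leaves, wgd, {("g1", sp): 0 for sp in absent},
                default_post=2,
            )
            report = dollo_loss_events(m, tree, "g1")
            assert report.loss_branches == frozenset(
                dollo_min_events(tree, frozenset(absent))
            )
            # minimality and disjointness: no reported branch ancestral to another
            assert report.loss_branches == frozenset(
                maximal_absent_clades(tree, frozenset(absent))
            )
            covered = set()
            for bid in report.loss_branches:
                leaves_below = set(bid.split("|"))
                assert not (covered & leaves_below)
                covered |= leaves_below
            assert covered == absent


class TestFindOrfs:
    def test_minimal_orf_translation(self):
        orfs = find_orfs("ATGAAATAG", min_len=0)
        assert len(orfs) == 1
        orf = orfs[0]
        assert (orf.start, orf.end, orf.strand) == (0, 9, "+")
        assert orf.length_nt == 9
        assert orf.protein == "MK"

    def test_five_prime_most_atg_per_stop(self):
        orfs = [o for o in find_orfs("ATGATGAAATAG", min_len=0) if o.strand == "+"]
        assert [(o.start, o.end) for o in orfs] == [(0, 12)]
        assert orfs[0].protein == "MMK"

    def test_min_len_filters_short_orfs(self):
        assert find_orfs("ATGAAATAG", min_len=12) == []

    def test_unterminated_orf_only_with_flag(self):
        seq = "ATGAAAAAA"
        assert find_orfs(seq, min_len=0) == []
        orfs = find_orfs(seq, min_len=0, include_unterminated=True, both_strands=False)
        assert [(o.start, o.end, o.terminated) for o in orfs] == [(0, 9, False)]
        assert orfs[0].protein == "MKK"

    def test_reverse_strand_coordinates_map_to_forward(self):
        fwd = "ATGAAATAG"
        seq = reverse_complement(fwd)
        orfs = find_orfs(seq, min_len=0)
        assert [(o.start, o.end, o.strand) for o in orfs] == [(0, 9, "-")]
        assert orfs[0].protein == "MK"

    def test_strand_symmetric_length_multiset(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 300, gc=0.4)
            lengths = sorted(o.length_nt for o in find_orfs(seq, min_len=30))
            rc_lengths = sorted(
                o.length_nt for o in find_orfs(reverse_complement(seq), min_len=30)
            )
            assert lengths == rc_lengths

    def test_matches_six_frame_oracle_on_random_sequences(self, rng):
        for _ in range(30):
            seq = random_dna(rng, 300, gc=0.35)
            got = [
                (o.start, o.end, o.strand, o.protein)
                for o in find_orfs(seq, min_len=30)
            ]
            assert got == orf_oracle(seq, min_len=30)


class TestScreenIntergenic:
    def test_record_without_atg_flagged(self):
        table = screen_intergenic([SequenceRecord("r1", "CCCCCCCCCCCC")], min_len=0)
        row = table.iloc[0]
        assert row["n_orfs"] == 0
        assert row["note"] == "no ORF"

    def test_planted_orf_recovered_exactly(self, rng):
        # 33-codon ORF embedded in stop-free-frame-safe random padding
        core = "ATG" + "GCT" * 31 + "TAA"
        seq = "CCCCC" + core + "CCCCC"
        table = screen_intergenic([SequenceRecord("r1", seq)], min_len=len(core))
        row = table.iloc[0]
        assert row["longest_orf_length"] == len(core)
        assert row["longest_orf_protein"] == "M" + "A" * 31

    def test_reverse_complement_preserves_longest_orf(self, rng):
        seq = random_dna(rng, 400, gc=0.4)
        t1 = screen_intergenic([SequenceRecord("r1", seq)], min_len=30)
        t2 = screen_intergenic(
            [SequenceRecord("r1", reverse_complement(seq))], min_len=30
        )
        assert (
            t1.iloc[0]["longest_orf_length"] == t2.iloc[0]["longest_orf_length"]
        )
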