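import pytest

from mitocomp import (ancestral_insect_signature, architecture_summary,
                      compare_gene_order, gene_order_signature, igs_summary,
                      junction_table, length_conservation_check,
                      overlap_summary)
from mitocomp.annotation import GeneFeature, MitogenomeAnnotation
from mitocomp.architecture import GeneOrderSignature

# The published intergenic-nucleotide columns, one signed spacer per junction
# in genome order, ending with the circular control-region -> trnI junction.
PED_SPACERS = [12, 33, 0, -2, -8, 4, -35, 1, 1, 0, 0, 0, -7, -1, -1, 0, -2,
               0, 0, -2, 0, 0, 0, 1, 0, -7, 2, 0, 2, -1, 0, 18, 1, 0, 0, 0,
               0, 0]
PPR_SPACERS = [14, 12, 0, 2, -8, 0, -35, 0, 0, 0, 0, 0, -7, -1, -2, 0, 162,
               165, 0, -2, 0, 1, 0, 1, 0, -7, 2, 0, 2, 12, 0, 28, 1, 0, 0, 0,
               0, 0]


def _toy(features, length, circular=True):
    return MitogenomeAnnotation("toy", length, features, circular=circular)


class TestJunctionTable:
    def test_published_column_reproduced_row_for_row(self, ped, ppr):
        assert [j.spacer for j in junction_table(ped)] == PED_SPACERS
        assert [j.spacer for j in junction_table(ppr)] == PPR_SPACERS

    def test_named_junctions(self, ped, ppr):
        by_pair = {(j.upstream, j.downstream): j.spacer for j in junction_table(ped)}
        assert by_pair[("trnW", "trnC")] == -8
        assert by_pair[("trnY", "COI")] == -35
        by_pair = {(j.upstream, j.downstream): j.spacer for j in junction_table(ppr)}
        assert by_pair[("ND3", "trnA")] == 162
        assert by_pair[("trnA", "trnR")] == 165

    def test_abutting_genes_have_zero_spacer(self):
        ann = _toy([GeneFeature("rrnL", "rRNA", "majority", 1, 10),
                    GeneFeature("rrnS", "rRNA", "majority", 11, 20)], 20,
                   circular=False)
        assert [j.spacer for j in junction_table(ann)] == [0]

    def test_circular_junction_flagged_last(self, ped):
        records = junction_table(ped)
        assert records[-1].circular
        assert (records[-1].upstream, records[-1].downstream) == ("CR", "trnI")


class TestOverlapAndIgs:
    def test_overlap_totals_match_study(self, ped, ppr):
        count, total, biggest = overlap_summary(ped)
        assert (total, biggest) == (66, ("trnY", "COI", 35))
        count, total, biggest = overlap_summary(ppr)
        assert (total, biggest) == (62, ("trnY", "COI", 35))

    def test_igs_totals_match_study(self, ped, ppr):
        assert igs_summary(ppr) == (12, 402, ("trnA", "trnR", 165))
        count, total, _ = igs_summary(ped)
        assert (count, total) == (10, 75)

    def test_no_negative_spacers(self):
        ann = _toy([GeneFeature("rrnL", "rRNA", "majority", 1, 10),
                    GeneFeature("rrnS", "rRNA", "majority", 11, 20)], 20)
        assert overlap_summary(ann) == (0, 0, None)
        assert igs_summary(ann) == (0, 0, None)


class TestArchitectureSummary:
    def test_study_values(self, ped, ppr):
        s = architecture_summary(ped)
        assert s.pcg_total_bp == 11246
        assert s.pcg_fraction_of_genome == pytest.approx(0.7362, abs=5e-4)
        assert s.cr_bp == 547
        assert s.rrnL_bp == 1255
        s = architecture_summary(ppr)
        assert s.pcg_total_bp == 11223
        assert s.cr_bp == 998
        assert s.trna_min_bp == 62
        assert set(s.trna_min_genes) == {"trnC", "trnP"}

    def test_trna_extremes_across_both_genomes(self, ped, ppr):
        mins = min(architecture_summary(a).trna_min_bp for a in (ped, ppr))
        maxs = max(architecture_summary(a).trna_max_bp for a in (ped, ppr))
        assert (mins, maxs) == (62, 71)

    def test_single_gene_toy(self):
        ann = _toy([GeneFeature("ND2", "PCG", "majority", 1, 300,
                                start_codon="ATG", stop_codon="TAA")], 300)
        assert architecture_summary(ann).pcg_total_bp == 300


class TestGeneOrder:
    def test_study_order_is_ancestral(self, ped, ppr):
        ref = ancestral_insect_signature()
        for ann in (ped, ppr):
            assert compare_gene_order(gene_order_signature(ann), ref) == (True, 0)

    def test_identity_and_symmetry(self, ped):
        sig = gene_order_signature(ped)
        assert compare_gene_order(sig, sig) == (True, 0)

    def test_adjacent_transposition_gives_three_breakpoints(self):
        # circular A B C D E vs A C B D E: adjacencies AB, BC, CD are lost
        # (B->C is not matched by C->B without sign flips), DE/EA survive.
        a = GeneOrderSignature(tuple((g, 1) for g in "ABCDE"))
        b = GeneOrderSignature(tuple((g, 1) for g in "ACBDE"))
        assert compare_gene_order(a, b) == (False, 3)
        # breakpoint distance is symmetric
        assert compare_gene_order(b, a)[1] == compare_gene_order(a, b)[1]

    def test_signed_block_reversal_gives_two_breakpoints(self):
        # A B C D E vs A -C -B D E: interior adjacency B->C survives as the
        # reverse reading of -C->-B; only the flanks A|B and C|D break.
        a = GeneOrderSignature(tuple((g, 1) for g in "ABCDE"))
        b = GeneOrderSignature((("A", 1), ("C", -1), ("B", -1), ("D", 1), ("E", 1)))
        assert compare_gene_order(a, b) == (False, 2)

    def test_differing_gene_sets_rejected(self):
        a = GeneOrderSignature(tuple((g, 1) for g in "ABC"))
        b = GeneOrderSignature(tuple((g, 1) for g in "ABD"))
        with pytest.raises(ValueError, match="C.*D|D.*C"):
            compare_gene_order(a, b)

    def test_missing_anchor_rejected(self, ped):
        ann = MitogenomeAnnotation(
            ped.organism, ped.genome_length,
            [f for f in ped.features if f.name != "trnI"])
        with pytest.raises(ValueError, match="trnI"):
            gene_order_signature(ann)


class TestConservation:
    def test_study_fixtures_close_the_circle(self, ped, ppr):
        assert length_conservation_check(ped)
        assert length_conservation_check(ppr)

    def test_corrupted_coordinate_detected(self, ped):
        feats = list(ped.features)
        cr = ped["CR"]
        feats[-1] = GeneFeature("CR", "CR", cr.strand, cr.start, cr.end + 40)
        bad = MitogenomeAnnotation(ped.organism, ped.genome_length, feats)
        assert not length_conservation_check(bad)
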