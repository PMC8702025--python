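import math

import numpy as np
import pytest

from mitocomp import (gene_kaks, invertebrate_mito_code, jukes_cantor,
                      ng86_pairwise, ng86_site_counts, pairwise_pi,
                      sliding_window_pi)
from mitocomp.simulate import evolve_cds_set, generate_cds

from ng86_oracle import oracle_diff_partition, oracle_site_counts

CODE = invertebrate_mito_code()


class TestPairwisePi:
    def test_identical_sequences(self):
        assert pairwise_pi(["ACGT" * 25] * 2) == 0.0

    def test_three_differences_in_100(self):
        a = "A" * 100
        b = "T" + "A" * 50 + "T" + "A" * 40 + "T" + "A" * 7
        assert pairwise_pi([a, b]) == pytest.approx(0.03)

    def test_mean_over_pairs(self):
        # three sequences with pairwise differences 2, 4, 6 over 100 sites
        base = "A" * 100
        s1 = base
        s2 = "TT" + base[2:]                      # 2 diffs vs s1
        s3 = base[:2] + "CCCC" + base[6:]         # 4 vs s1, 6 vs s2
        assert pairwise_pi([s1, s2, s3]) == pytest.approx((0.02 + 0.04 + 0.06) / 3)

    def test_complete_deletion_of_gap_and_ambiguity_columns(self):
        a = "AC-TA"
        b = "ACGTN"
        # only columns 1, 2, 4 remain; no differences there
        assert pairwise_pi([a, b]) == 0.0

    def test_invariance_under_reordering(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
        assert pairwise_pi(seqs) == pytest.approx(pairwise_pi(seqs[::-1]))

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_pi(["ACGT"])
        with pytest.raises(ValueError, match="no comparable"):
            pairwise_pi(["----", "AAAA"])


class TestSlidingWindow:
    def test_identical_sequences_all_zero(self):
        track = sliding_window_pi(["A" * 200] * 3, window=100, step=25)
        assert all(pi == 0 for _, _, pi in track.windows)
        assert [w[0] for w in track.windows] == [1, 26, 51, 76, 101]

    def test_windows_match_independent_per_slice_recomputation(self):
        rng = np.random.default_rng(42)
        seqs = ["".join(rng.choice(list("ACGT"), 400)) for _ in range(4)]
        track = sliding_window_pi(seqs, window=100, step=25)
        for start, end, pi in track.windows:
            slice_pi = pairwise_pi([s[start - 1:end] for s in seqs])
            assert pi == pytest.approx(slice_pi, abs=1e-12)

    def test_divergent_block_is_argmax(self):
        rng = np.random.default_rng(7)
        a = "".join(rng.choice(list("ACGT"), 500))
        b = list(a)
        for i in range(200, 300):  # heavily diverge one 100 bp block
            b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
        track = sliding_window_pi([a, "".join(b)], window=100, step=25)
        start, end, _ = max(track.windows, key=lambda w: w[2])
        assert start <= 300 and end >= 201  # argmax window overlaps the block

    def test_partial_final_window_dropped(self):
        track = sliding_window_pi(["ACGT" * 30] * 2, window=100, step=25)
        assert all(end - start + 1 == 100 for start, end, _ in track.windows)
        assert track.windows[-1][1] <= 120

    def test_window_validation(self):
        with pytest.raises(ValueError, match="window"):
            sliding_window_pi(["ACGT"] * 2, window=1)


class TestJukesCantor:
    @pytest.mark.parametrize("p", [0.001, 0.01, 0.1, 0.3, 0.5, 0.7])
    def test_correction_exceeds_proportion(self, p):
        d = jukes_cantor(p)
        assert d >= p
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))

    def test_small_p_limit(self):
        assert jukes_cantor(1e-6) == pytest.approx(1e-6, rel=1e-3)

    def test_saturation(self):
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.9) is None


class TestSiteCounts:
    def test_phe_third_position(self):
        syn, nonsyn = ng86_site_counts("TTT")
        assert syn == pytest.approx(1 / 3)
        assert nonsyn == pytest.approx(3 - 1 / 3)

    def test_four_fold_third_position(self):
        syn, _ = ng86_site_counts("GGA")  # Gly: every third-position change syn
        assert syn == pytest.approx(1.0)

    @pytest.mark.parametrize("codon", ["CGA", "TTA", "ATG", "TGG", "AGA", "CTG"])
    def test_matches_exhaustive_enumeration(self, codon):
        assert ng86_site_counts(codon) == pytest.approx(oracle_site_counts(codon))

    def test_each_codon_contributes_three_sites(self):
        for codon in CODE.sense_codons:
            syn, nonsyn = ng86_site_counts(codon)
            assert syn + nonsyn == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_site_counts("TAA")


class TestNG86Pairwise:
    def test_identical_cds(self):
        r = ng86_pairwise("ATGAAA", "ATGAAA")
        assert (r.pN, r.pS, r.dN, r.dS) == (0.0, 0.0, 0.0, 0.0)

    def test_single_synonymous_difference(self):
        # 30 codons, one third-position synonymous change (GGA->GGC)
        a = "GGA" * 30
        b = "GGC" + "GGA" * 29
        r = ng86_pairwise(a, b)
        assert r.syn_diffs == pytest.approx(1.0)
        assert r.nonsyn_diffs == 0.0
        assert r.pS == pytest.approx(1.0 / r.syn_sites)
        assert r.pN == 0.0

    def test_two_substitution_codon_averages_both_orderings(self):
        sd, nd = 0.0, 0.0
        r = ng86_pairwise("TTT", "GTA")
        osd, ond = oracle_diff_partition("TTT", "GTA")
        assert (r.syn_diffs, r.nonsyn_diffs) == pytest.approx((osd, ond))
        assert r.syn_diffs + r.nonsyn_diffs == pytest.approx(2.0)

    def test_site_totals_symmetric(self):
        a, b = "ATGAAATTTGGA", "ATAAAGTTCGGC"
        r1, r2 = ng86_pairwise(a, b), ng86_pairwise(b, a)
        assert r1.syn_sites == pytest.approx(r2.syn_sites)
        assert (r1.syn_diffs, r1.nonsyn_diffs) == pytest.approx(
            (r2.syn_diffs, r2.nonsyn_diffs))

    def test_ambiguous_codons_skipped(self):
        r = ng86_pairwise("ATGNNN", "ATGAAA")
        assert r.codons_used == 1

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            ng86_pairwise("ATG", "ATGAAA")
        with pytest.raises(ValueError, match="stop"):
            ng86_pairwise("TAA", "TAA")


class TestGeneKaks:
    def test_omega_ordering_recovered(self):
        rng = np.random.default_rng(3)
        anc = {g: generate_cds(120, rng) for g in ("slow", "mid", "fast")}
        ev = evolve_cds_set(anc, n_taxa=8, divergence=0.3,
                            omega={"slow": 0.05, "mid": 0.3, "fast": 0.7},
                            kappa=2.0, seed=17)
        ratios = {s.gene: s.ratio for s in gene_kaks(ev)}
        assert ratios["slow"] < ratios["mid"] < ratios["fast"]

    def test_neutral_recovery(self):
        rng = np.random.default_rng(4)
        anc = {"g": generate_cds(300, rng)}
        ev = evolve_cds_set(anc, n_taxa=10, divergence=0.3, omega=1.0,
                            kappa=1.0, seed=21)
        sel = gene_kaks(ev)[0]
        assert sel.n_pairs == 45
        assert sel.ratio == pytest.approx(1.0, abs=0.2)

    def test_zero_divergence(self):
        rng = np.random.default_rng(5)
        anc = {"g": generate_cds(50, rng)}
        ev = evolve_cds_set(anc, n_taxa=4, divergence=0.0, omega=0.5, seed=1)
        sel = gene_kaks(ev)[0]
        assert sel.mean_ka == 0.0 and sel.mean_ks == 0.0
        assert sel.ratio is None  # 0/0 is undefined, not 0
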