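import numpy as np
import pytest

from mitocomp import (architecture_summary, base_composition,
                      length_conservation_check, sliding_window_pi,
                      validate_annotation)
from mitocomp.simulate import (SimulationConfig, default_codon_weights,
                               evolve_cds, evolve_cds_set, generate_cds,
                               simulate_annotation, table1_fixture)


class TestTable1Fixture:
    def test_study_genome_shapes(self):
        ped = table1_fixture("Ped")
        assert len(ped.features) == 38
        assert ped.genome_length == 15274
        ppr = table1_fixture("Ppr")
        assert ppr.genome_length == 16031
        assert (ppr["CR"].start, ppr["CR"].end) == (15034, 16031)

    def test_fixtures_validate_cleanly(self):
        assert validate_annotation(table1_fixture("edmundsi")) == []
        assert validate_annotation(table1_fixture("projecta")) == []

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown species"):
            table1_fixture("nope")


class TestSimulateAnnotation:
    def test_deterministic_under_fixed_seed(self):
        a = simulate_annotation(SimulationConfig(seed=11))
        b = simulate_annotation(SimulationConfig(seed=11))
        assert a.sequence == b.sequence
        assert a.features == b.features
        c = simulate_annotation(SimulationConfig(seed=12))
        assert c.sequence != a.sequence

    def test_template_architecture_round_trips(self, sim_genome):
        s = architecture_summary(sim_genome)
        # the default template mirrors the 15,274 bp study genome
        assert (s.overlap_total_bp, s.igs_total_bp) == (66, 75)
        assert s.max_overlap == ("trnY", "COI", 35)
        assert sim_genome.genome_length == 15274

    def test_complete_and_conserved(self, sim_genome):
        assert validate_annotation(sim_genome) == []
        assert length_conservation_check(sim_genome)

    @pytest.mark.parametrize("seed", range(20))
    def test_conservation_identity_across_seeds(self, seed):
        ann = simulate_annotation(SimulationConfig(seed=seed))
        assert length_conservation_check(ann)

    def test_at_target_recovered_at_genome_scale(self):
        for seed, target in ((0, 0.73), (1, 0.65)):
            ann = simulate_annotation(SimulationConfig(seed=seed, at_target=target))
            measured = base_composition(ann.sequence).at_content
            assert measured == pytest.approx(100 * target, abs=2.0)

    def test_pcgs_start_atn_and_stop_per_template(self, sim_genome):
        # ND4's coding start lies inside ND4L (a genuine PCG-PCG overlap),
        # so its annotated start codon is nominal; every other PCG's frame
        # is written with precedence and must begin with its ATN start.
        for f in sim_genome.pcgs:
            if f.name == "ND4":
                continue
            sense = f.sense_sequence(sim_genome.sequence)
            assert sense[:3] == f.start_codon
            assert sense.startswith("AT")

    def test_overlap_free_template_gives_fully_consistent_pcgs(self):
        from dataclasses import replace
        from mitocomp.codons import codon_usage_table
        from mitocomp.composition import region_partition
        from mitocomp.simulate import default_template
        template = tuple(replace(g, spacer_before=max(0, g.spacer_before))
                         for g in default_template())
        ann = simulate_annotation(SimulationConfig(seed=2, template=template))
        assert architecture_summary(ann).overlap_total_bp == 0
        for f in ann.pcgs:
            sense = f.sense_sequence(ann.sequence)
            assert sense[:3] == f.start_codon
        table = codon_usage_table(ann)  # no warnings expected: clean frames
        assert table.total_aa == len(region_partition(ann)["PCGs3"])


class TestCodonWeights:
    def test_weights_are_calibrated_distribution(self):
        w = default_codon_weights(0.73, 3.0)
        assert sum(w.values()) == pytest.approx(1.0)
        assert "TAA" not in w and "TAG" not in w
        at = sum(v * sum(b in "AT" for b in c) for c, v in w.items()) / 3
        assert at == pytest.approx(0.73, abs=1e-6)

    def test_boost_prefers_dominant_codons(self):
        w = default_codon_weights(0.73, 3.0)
        assert w["TTA"] > w["TTG"]
        assert w["ATT"] > w["ATC"]


class TestEvolveCds:
    def test_zero_divergence_identity(self):
        rng = np.random.default_rng(0)
        cds = generate_cds(100, rng)
        assert evolve_cds(cds, 0.0, 0.5, 2.0, rng) == cds

    def test_no_stops_ever_introduced(self):
        from mitocomp import invertebrate_mito_code
        code = invertebrate_mito_code()
        rng = np.random.default_rng(1)
        cds = generate_cds(200, rng)
        out = evolve_cds(cds, 1.0, 1.0, 2.0, rng)
        codons = [out[i:i + 3] for i in range(0, len(out), 3)]
        assert not any(code.is_stop(c) for c in codons)

    def test_star_tree_set_shapes_and_determinism(self):
        rng = np.random.default_rng(2)
        anc = {"g1": generate_cds(50, rng), "g2": generate_cds(60, rng)}
        ev1 = evolve_cds_set(anc, n_taxa=5, divergence=0.1, omega=0.3, seed=9)
        ev2 = evolve_cds_set(anc, n_taxa=5, divergence=0.1, omega=0.3, seed=9)
        assert ev1 == ev2
        assert set(ev1) == {"g1", "g2"}
        assert list(ev1["g1"]) == [f"t{i:02d}" for i in range(1, 6)]
        assert all(len(s) == 150 for s in ev1["g1"].values())

    def test_divergence_ordering_visible_in_pi(self):
        rng = np.random.default_rng(3)
        anc = generate_cds(200, rng)
        low = evolve_cds_set({"g": anc}, 6, 0.02, 1.0, seed=5)["g"]
        high = evolve_cds_set({"g": anc}, 6, 0.20, 1.0, seed=5)["g"]
        pi_low = sliding_window_pi(low, 100, 25)
        pi_high = sliding_window_pi(high, 100, 25)
        mean = lambda t: sum(w[2] for w in t.windows) / len(t.windows)
        assert mean(pi_high) > mean(pi_low)

    def test_negative_divergence_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="divergence"):
            evolve_cds("ATG", -0.1, 1.0, 2.0, rng)
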