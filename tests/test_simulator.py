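"""Simulator behaviour: assembly, SHM statistics, expansion, noise, fixtures."""

import numpy as np
import pytest

import edlib

from bcrp.records import ConfigurationError, PairedCell
from bcrp.simulate import (
    SimulationConfig,
    assemble_heavy_ancestor,
    assemble_light_ancestor,
    cdr3_span_nt,
    derive_rng,
    draw_mutation_types,
    expand_family,
    generate_chain_mixed,
    generate_noise,
    generate_public_fixture,
    mutate_once,
    simulate_benchmark,
)

CFG = SimulationConfig()


def _family(germline, seed=5, **overrides):
    cfg = SimulationConfig(**overrides) if overrides else CFG
    rng = np.random.default_rng(seed)
    heavy = assemble_heavy_ancestor(germline, cfg, rng)
    light = assemble_light_ancestor(germline, cfg, rng)
    heavy.cell_id = light.cell_id = "anc"
    heavy.true_clone_id = light.true_clone_id = "fam0"
    return cfg, rng, PairedCell("anc", heavy, light)


class TestAncestorAssembly:
    def test_seeded_determinism(self, germline):
        a = assemble_heavy_ancestor(germline, CFG, np.random.default_rng(11))
        b = assemble_heavy_ancestor(germline, CFG, np.random.default_rng(11))
        assert a.sequence_nt == b.sequence_nt and a.v_call == b.v_call

    def test_heavy_indel_counts_in_range(self, germline):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            rec = assemble_heavy_ancestor(germline, CFG, rng)
            assert 1 <= rec.extra["vd_indels"] <= 3
            assert 1 <= rec.extra["dj_indels"] <= 3
            assert rec.v_sequence_end < rec.j_sequence_start

    def test_light_indel_counts_in_range(self, germline):
        rng = np.random.default_rng(2)
        for _ in range(2000):
            rec = assemble_light_ancestor(germline, CFG, rng)
            assert 0 <= rec.extra["vj_indels"] <= 2

    def test_kappa_fraction_matches_configured_probability(self, germline):
        rng = np.random.default_rng(3)
        n = 10_000
        kappa = sum(
            assemble_light_ancestor(germline, CFG, rng).locus == "IGK"
            for _ in range(n)
        )
        se = (0.6 * 0.4 / n) ** 0.5
        assert abs(kappa / n - 0.60) < 3 * se

    def test_kappa_probability_one_gives_all_kappa(self, germline):
        cfg = SimulationConfig(kappa_probability=1.0)
        rng = np.random.default_rng(4)
        assert all(
            assemble_light_ancestor(germline, cfg, rng).locus == "IGK"
            for _ in range(200)
        )

    def test_junction_anchored_on_conserved_codons(self, germline):
        rng = np.random.default_rng(5)
        rec = assemble_heavy_ancestor(germline, CFG, rng)
        assert rec.junction_aa.startswith("C")


class TestMutationEngine:
    def test_zero_rate_is_identity(self, germline, rng):
        rec = assemble_heavy_ancestor(germline, CFG, rng)
        seq, events = mutate_once(
            rec.sequence_nt, cdr3_span_nt(rec), 15, CFG, rng, rate=0.0
        )
        assert seq == rec.sequence_nt and events == []

    def test_mutations_confined_to_window(self, germline):
        rng = np.random.default_rng(6)
        rec = assemble_heavy_ancestor(germline, CFG, rng)
        start, end = cdr3_span_nt(rec)
        window = 15
        n_events = 0
        while n_events < 100_000:
            _, events = mutate_once(
                rec.sequence_nt, (start, end), window, CFG, rng, rate=0.4
            )
            for ev in events:
                assert start - window <= ev.position < end + window
            n_events += len(events)

    def test_type_ratio_converges(self):
        rng = np.random.default_rng(7)
        kinds = draw_mutation_types(1_000_000, CFG, rng)
        counts = np.bincount(kinds, minlength=3)
        n = counts.sum()
        for idx, weight in enumerate((0.8, 1.0, 100.0)):
            p = weight / 101.8
            se = (p * (1 - p) / n) ** 0.5
            assert abs(counts[idx] / n - p) < 3 * se
        assert counts[2] / counts[1] == pytest.approx(100, rel=0.1)
        assert counts[0] / counts[1] == pytest.approx(0.8, rel=0.1)

    def test_g_substitution_row(self):
        rng = np.random.default_rng(8)
        seq = "G" * 5000
        to_a = total = 0
        while total < 100_000:
            _, events = mutate_once(seq, (0, len(seq)), 0, CFG, rng, rate=0.5)
            subs = [e for e in events if e.kind == "substitution"]
            total += len(subs)
            to_a += sum(1 for e in subs if e.detail[1] == "A")
        se = (0.7 * 0.3 / total) ** 0.5
        assert abs(to_a / total - 0.70) < 3 * se

    def test_events_in_position_order_and_valid(self, germline, rng):
        rec = assemble_heavy_ancestor(germline, CFG, rng)
        for _ in range(50):
            _, events = mutate_once(
                rec.sequence_nt, cdr3_span_nt(rec), 15, CFG, rng, rate=0.3
            )
            positions = [e.position for e in events]
            assert positions == sorted(positions)
            for ev in events:
                if ev.kind == "substitution":
                    assert ev.detail[0] != ev.detail[1]

    def test_invalid_rate_rejected(self, germline, rng):
        rec = assemble_heavy_ancestor(germline, CFG, rng)
        with pytest.raises(ConfigurationError):
            mutate_once(rec.sequence_nt, cdr3_span_nt(rec), 15, CFG, rng, rate=1.5)


class TestExpansion:
    def test_no_rounds_gives_founders_plus_ancestor(self, germline):
        cfg, rng, anc = _family(germline, n_rounds=0)
        members = expand_family(anc, cfg, rng)
        assert len(members) == cfg.initial_cells + 1
        assert all(c.heavy.shm_count == 0 for c in members)

    def test_initial_expansion_count_is_five_under_defaults(self, germline):
        cfg, rng, anc = _family(germline)
        stats = []
        expand_family(anc, cfg, rng, stats_out=stats)
        # five founders each spawning expansion_factor offspring in round 1
        assert stats[0][0] == 5 * cfg.expansion_factor

    def test_apoptosis_accounting(self, germline):
        cfg, rng, anc = _family(germline, seed=9)
        stats = []
        expand_family(anc, cfg, rng, stats_out=stats)
        assert len(stats) == cfg.n_rounds
        for n_new, n_disc in stats:
            assert n_disc == round(cfg.apoptosis_fraction * n_new)

    def test_pooled_discard_fraction_near_forty_percent(self, germline):
        rng = np.random.default_rng(10)
        total_new = total_disc = 0
        for seed in range(30):
            cfg, _, anc = _family(germline, seed=seed)
            stats = []
            expand_family(anc, cfg, rng, stats_out=stats)
            total_new += sum(s[0] for s in stats)
            total_disc += sum(s[1] for s in stats)
        assert total_disc / total_new == pytest.approx(0.40, abs=0.005)

    def test_shm_accumulates_and_labels_set(self, germline):
        cfg, rng, anc = _family(germline, seed=11)
        members = expand_family(anc, cfg, rng)
        assert all(c.heavy.true_clone_id == "fam0" for c in members)
        assert all((c.heavy.shm_count or 0) >= 0 for c in members)
        assert any((c.heavy.shm_count or 0) > 0 for c in members)

    def test_bernoulli_apoptosis_mode(self, germline):
        cfg, rng, anc = _family(germline, seed=12, apoptosis_mode="bernoulli",
                                n_rounds=3)
        stats = []
        members = expand_family(anc, cfg, rng, stats_out=stats)
        assert members and len(stats) == 3


class TestNoise:
    def test_noise_preserves_template_gene_calls(self, germline):
        cfg, rng, anc = _family(germline, seed=13, n_rounds=2)
        family = expand_family(anc, cfg, rng)
        cfg2 = SimulationConfig(n_noise=50, n_rounds=2)
        noise = generate_noise(family, cfg2, rng)
        calls = {(c.heavy.v_call, c.heavy.j_call) for c in family}
        assert len(noise) == 50
        for cell in noise:
            assert (cell.heavy.v_call, cell.heavy.j_call) in calls
            assert cell.heavy.true_clone_id == "noise"
            assert cell.light.true_clone_id == "noise"

    def test_noise_junctions_diverge_more_than_family(self, germline):
        cfg, rng, anc = _family(germline, seed=14, n_rounds=3)
        family = expand_family(anc, cfg, rng)
        noise = generate_noise(family, SimulationConfig(n_noise=60, n_rounds=3), rng)

        def norm_dist(a, b):
            return edlib.align(a, b)["editDistance"] / max(len(a), len(b), 1)

        anc_j = anc.heavy.junction_aa
        within = np.mean([norm_dist(c.heavy.junction_aa, anc_j) for c in family])
        across = np.mean(
            [norm_dist(c.heavy.junction_aa, c.heavy.extra["template_junction_aa"])
             for c in noise]
        )
        assert across > within

    def test_zero_noise_is_empty(self, germline):
        cfg, rng, anc = _family(germline, seed=15, n_rounds=0)
        family = expand_family(anc, cfg, rng)
        assert generate_noise(family, SimulationConfig(n_noise=0, n_rounds=0), rng) == []

    def test_chain_mixed_heavy_similar_light_fresh(self, germline):
        cfg, rng, anc = _family(germline, seed=16, n_rounds=2)
        family = expand_family(anc, cfg, rng)
        mixed = generate_chain_mixed(family, 20, cfg, rng, germline)
        fam_lengths = {len(c.heavy.junction_aa) for c in family}
        for cell in mixed:
            assert cell.heavy.true_clone_id == "noise"
            assert len(cell.heavy.junction_aa) in fam_lengths
            assert cell.heavy.extra["noise_kind"] == "chain_mixed"


class TestPublicFixture:
    def test_shared_clone_appears_in_requested_samples(self, germline):
        cfg = SimulationConfig(n_rounds=1, rng_seed=0)
        rng = np.random.default_rng(17)
        reps = generate_public_fixture(
            10, 2, cfg, rng, germline=germline, n_shared_samples=10
        )
        assert len(reps) == 10
        for rep in reps:
            labels = {c.heavy.true_clone_id for c in rep.cells}
            assert {"public0", "public1"} <= labels

    def test_public_members_have_lower_shm_than_families(self, germline):
        cfg = SimulationConfig(n_rounds=4, rng_seed=0)
        rng = np.random.default_rng(18)
        reps = generate_public_fixture(3, 1, cfg, rng, germline=germline)
        pub_shm, fam_shm = [], []
        for rep in reps:
            for cell in rep.cells:
                (pub_shm if cell.heavy.true_clone_id.startswith("public")
                 else fam_shm).append(cell.heavy.shm_count or 0)
        assert np.mean(pub_shm) < np.mean(fam_shm)
        assert max(pub_shm) <= 1

    def test_zero_public_clones_is_plain_simulation(self, germline):
        cfg = SimulationConfig(n_rounds=1, rng_seed=0)
        rng = np.random.default_rng(19)
        reps = generate_public_fixture(2, 0, cfg, rng, germline=germline)
        for rep in reps:
            assert not any(
                c.heavy.true_clone_id.startswith("public") for c in rep.cells
            )


class TestBenchmark:
    def test_family_count_and_noise_labels(self, small_benchmark):
        cfg, rep, truth = small_benchmark
        labels = set(truth.values()) - {"noise"}
        assert len(labels) == cfg.n_families
        assert "noise" in truth.values()

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_families=2, n_noise=20, n_rounds=2, rng_seed=21)
        rep_a, truth_a = simulate_benchmark(cfg)
        rep_b, truth_b = simulate_benchmark(cfg)
        assert truth_a == truth_b
        for a, b in zip(rep_a.cells, rep_b.cells):
            assert a.heavy.sequence_nt == b.heavy.sequence_nt
            assert a.light.sequence_nt == b.light.sequence_nt

    def test_amino_acid_pairs_unique_after_dedup(self, small_benchmark):
        from bcrp.simulate import _pair_aa

        _, rep, _ = small_benchmark
        keys = [_pair_aa(c) for c in rep.cells]
        assert len(keys) == len(set(keys))


def test_stage_keyed_rng_streams_are_independent():
    a1 = derive_rng(1, "simulate").random(5)
    a2 = derive_rng(1, "simulate").random(5)
    b = derive_rng(1, "cluster").random(5)
    assert np.allclose(a1, a2)
    assert not np.allclose(a1, b)
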