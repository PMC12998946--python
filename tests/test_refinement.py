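"""Refinement: LC V-J splitting, publicness flagging, Youden cutoff, filtering."""

import math

import numpy as np
import pytest

from bcrp.clustering import ClonalCluster, cluster_heavy
from bcrp.consistency import fit_frequency_scorer
from bcrp.records import Repertoire, StateError
from bcrp.refinement import (
    RefinementConfig,
    classify_public_cluster,
    cluster_publicness,
    flag_public_clusters,
    run_fastbcr_p,
    split_by_light_vj,
    youden_shm_cutoff,
)
from tests.conftest import make_cell


class TestSplitByLightVJ:
    def test_two_light_groups_of_three(self):
        cells = [
            make_cell(f"c{i}", "CARDYW", "CQQW",
                      lv="IGKV1-39" if i < 3 else "IGLV2-14",
                      lj="IGKJ1" if i < 3 else "IGLJ2",
                      locus="IGK" if i < 3 else "IGL")
            for i in range(6)
        ]
        rep = Repertoire("s", cells=cells)
        cluster = ClonalCluster("C0", [c.heavy.sequence_id for c in cells])
        subs, unassigned = split_by_light_vj(cluster, rep, min_subcluster_size=3)
        assert len(subs) == 2 and unassigned == []
        assert sorted(len(s.members) for s in subs) == [3, 3]

    def test_homogeneous_cluster_unchanged(self, chain_mixed_repertoire):
        cells = chain_mixed_repertoire.cells[:4]  # all IGKV1-1/IGKJ1
        rep = Repertoire("s", cells=cells)
        cluster = ClonalCluster("C0", [c.heavy.sequence_id for c in cells])
        subs, unassigned = split_by_light_vj(cluster, rep)
        assert len(subs) == 1 and unassigned == []
        assert subs[0].cluster_id == "C0"
        assert sorted(subs[0].members) == sorted(cluster.members)

    def test_member_conservation(self, chain_mixed_repertoire):
        cluster = ClonalCluster(
            "C0", [c.heavy.sequence_id for c in chain_mixed_repertoire.cells]
        )
        subs, unassigned = split_by_light_vj(
            cluster, chain_mixed_repertoire, min_subcluster_size=3
        )
        covered = sorted(
            [m for s in subs for m in s.members] + list(unassigned)
        )
        assert covered == sorted(cluster.members)
        assert len(unassigned) == 2  # the minority light group falls below size 3

    def test_unpaired_member_named(self, chain_mixed_repertoire):
        cluster = ClonalCluster("C0", ["ghost_H"])
        with pytest.raises(StateError, match="ghost_H"):
            split_by_light_vj(cluster, chain_mixed_repertoire)


class TestClusterPublicness:
    def _setup(self):
        reps = [
            Repertoire(f"S{s}", cells=[make_cell(f"s{s}c", "CARDSHARED", "CQQW")])
            for s in range(10)
        ]
        target = Repertoire("T", cells=[
            make_cell("t0", "CARDSHARED", "CQQW"),
            make_cell("t1", "CARDPRIV", "CQQW"),
        ])
        scorer = fit_frequency_scorer(reps + [target])
        return target, scorer

    def test_mean_over_members(self):
        target, scorer = self._setup()
        cluster = ClonalCluster("C0", ["t0_H", "t1_H"])
        hc, lc = cluster_publicness(cluster, target, scorer, paired_mode=False)
        # shared key in 11 samples -> 1.0; private key -> 0.1
        assert hc == pytest.approx((1.0 + 0.1) / 2)
        assert lc is None

    def test_paired_mode_returns_both_chains(self):
        target, scorer = self._setup()
        cluster = ClonalCluster("C0", ["t0_H"])
        hc, lc = cluster_publicness(cluster, target, scorer, paired_mode=True)
        assert lc == pytest.approx(11.0)

    def test_order_invariant(self):
        target, scorer = self._setup()
        a = cluster_publicness(ClonalCluster("C", ["t0_H", "t1_H"]), target, scorer)
        b = cluster_publicness(ClonalCluster("C", ["t1_H", "t0_H"]), target, scorer)
        assert a == b

    def test_unfitted_scorer_rejected(self):
        from bcrp.consistency import FrequencyScorer

        target, _ = self._setup()
        with pytest.raises(StateError):
            cluster_publicness(ClonalCluster("C", ["t0_H"]), target,
                               FrequencyScorer())


class TestFlagPublicClusters:
    def _flags(self, scores, q=0.10):
        cfg = RefinementConfig(public_quantile=q)
        return flag_public_clusters(scores, cfg)

    def test_hundred_distinct_scores_flag_ten(self, rng):
        raw = rng.permutation(np.linspace(0.01, 0.99, 100))
        scores = {f"C{i:03d}": (float(raw[i]), None) for i in range(100)}
        flags = self._flags(scores)
        assert sum(f for f, _ in flags.values()) == 10

    def test_maximum_score_always_flagged(self, rng):
        raw = rng.random(37)
        scores = {f"C{i}": (float(raw[i]), None) for i in range(37)}
        flags = self._flags(scores)
        top = max(scores, key=lambda c: scores[c][0])
        assert flags[top][0]

    def test_affine_invariance(self, rng):
        raw = rng.random(40)
        scores = {f"C{i:02d}": (float(raw[i]), None) for i in range(40)}
        shifted = {c: (3.5 * v[0] + 2.0, None) for c, v in scores.items()}
        f1 = self._flags(scores)
        f2 = self._flags(shifted)
        assert {c for c, (f, _) in f1.items() if f} == {
            c for c, (f, _) in f2.items() if f
        }

    def test_zero_variance_falls_back_to_raw_rank(self):
        scores = {f"C{i}": (0.5, None) for i in range(10)}
        flags = self._flags(scores)
        assert sum(f for f, _ in flags.values()) == 1
        assert all(z == 0.0 for _, z in flags.values())

    def test_paired_mode_averages_chain_zscores(self, rng):
        n = 20
        scores = {
            f"C{i:02d}": (float(rng.random()), float(rng.random() * 8))
            for i in range(n)
        }
        flags = self._flags(scores, q=0.25)
        assert sum(f for f, _ in flags.values()) == math.ceil(0.25 * n)


class TestYoudenCutoff:
    def test_separated_classes(self):
        t, j = youden_shm_cutoff([0, 1, 2], [8, 9, 10])
        assert t == 5.0 and j == pytest.approx(1.0)

    def test_identical_distributions_sentinel(self):
        t, j = youden_shm_cutoff([1, 2, 3], [1, 2, 3])
        assert j == pytest.approx(0.0)
        assert t == -math.inf

    def test_matches_exhaustive_search(self, rng):
        for _ in range(200):
            naive = rng.normal(2, 1.5, size=rng.integers(2, 12)).tolist()
            memory = rng.normal(5, 1.5, size=rng.integers(2, 12)).tolist()
            t, j = youden_shm_cutoff(naive, memory)
            # exhaustive: J evaluated on a dense threshold sweep
            pooled = sorted(set(naive) | set(memory))
            sweep = (
                [-math.inf, math.inf]
                + pooled
                + [(a + b) / 2 for a, b in zip(pooled, pooled[1:])]
            )
            best = max(
                sum(m >= s for m in memory) / len(memory)
                + sum(n < s for n in naive) / len(naive)
                - 1.0
                for s in sweep
            )
            assert j == pytest.approx(best)
            achieved = (
                sum(m >= t for m in memory) / len(memory)
                + sum(n < t for n in naive) / len(naive) - 1.0
            )
            assert achieved == pytest.approx(j)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            youden_shm_cutoff([], [1.0])


class TestClassify:
    def test_low_shm_public_filtered(self):
        flags = classify_public_cluster(True, 0.2, 3.0)
        assert flags.origin == "naive_like" and not flags.retained

    def test_high_shm_public_retained(self):
        flags = classify_public_cluster(True, 8.0, 3.0)
        assert flags.origin == "memory_derived" and flags.retained

    def test_non_public_always_retained(self):
        for shm in (0.0, 100.0):
            flags = classify_public_cluster(False, shm, 3.0)
            assert flags.origin == "not_public" and flags.retained


class TestPipeline:
    def test_degenerate_config_equals_heavy_only(self, small_benchmark):
        _, rep, _ = small_benchmark
        cfg = RefinementConfig(scorer=None, paired_mode=False)
        result = run_fastbcr_p(rep, cfg)
        base = cluster_heavy(rep.heavy_chains())
        assert [c.members for c in result.clusters] == [c.members for c in base]
        assert all(f.retained for f in result.flags.values())

    def test_refinement_is_a_partition_refinement(self, small_benchmark):
        _, rep, _ = small_benchmark
        scorer = fit_frequency_scorer([rep])
        result = run_fastbcr_p(rep, RefinementConfig(scorer=scorer))
        base = cluster_heavy(rep.heavy_chains())
        base_of = {}
        for c in base:
            for m in c.members:
                base_of[m] = c.cluster_id
        for sub in result.clusters:
            parents = {base_of[m] for m in sub.members}
            assert len(parents) == 1
        # member conservation
        n_base = sum(len(c.members) for c in base)
        n_out = sum(len(c.members) for c in result.clusters) + len(result.unassigned)
        assert n_out == n_base

    def test_splitting_never_decreases_precision(self, small_benchmark):
        from bcrp.evaluation import LabeledPartition, pairwise_metrics

        _, rep, truth = small_benchmark
        tp = LabeledPartition(truth)
        base = cluster_heavy(rep.heavy_chains())
        scorer = fit_frequency_scorer([rep])
        refined = run_fastbcr_p(rep, RefinementConfig(scorer=scorer))
        p_base, _, _ = pairwise_metrics(
            tp, LabeledPartition.from_clusters(base, list(truth)))
        p_ref, _, _ = pairwise_metrics(
            tp, LabeledPartition.from_clusters(refined.clusters, list(truth)))
        assert p_ref >= p_base

    def test_public_fixture_clones_flagged_and_filtered(self, germline):
        from bcrp.simulate import SimulationConfig, generate_public_fixture

        cfg = SimulationConfig(n_rounds=4)
        rng = np.random.default_rng(23)
        reps = generate_public_fixture(
            10, 1, cfg, rng, germline=germline, members_per_sample=6,
            background_families=2,
        )
        scorer = fit_frequency_scorer(reps)
        target = reps[0]
        result = run_fastbcr_p(
            target,
            RefinementConfig(scorer=scorer, shm_cutoff=2.0, paired_mode=True),
        )
        by_heavy = target.cell_by_heavy_id()
        public_flags = []
        for c in result.clusters:
            labels = {by_heavy[m].heavy.true_clone_id for m in c.members}
            if labels == {"public0"}:
                public_flags.append(result.flags[c.cluster_id])
        assert public_flags, "public pseudo-clone was not clustered"
        for flags in public_flags:
            assert flags.is_public
            assert flags.origin == "naive_like" and not flags.retained

    def test_auto_cutoff_without_annotations_errors(self, small_benchmark):
        _, rep, _ = small_benchmark
        scorer = fit_frequency_scorer([rep])
        with pytest.raises(StateError, match="shm-cutoff"):
            run_fastbcr_p(
                rep, RefinementConfig(scorer=scorer, shm_cutoff="auto")
            )
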