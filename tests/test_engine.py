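import math
import random

import pytest

from mnalign.clustering import ClusterSet, agglomerative_cluster
from mnalign.core import (
    AlignmentParams,
    InputFormatError,
    Network,
    NetworkCollection,
    SimilarityMatrix,
    _canon,
)
from mnalign.engine import (
    AlignmentState,
    align_remaining,
    expand_seeds,
    generate_seeds,
    merge_criterion,
    run_pipeline,
)
from mnalign.similarity import preprocess_similarity

from .conftest import random_instance


def example_clusters(nets, sim_dec) -> ClusterSet:
    return agglomerative_cluster(sim_dec, 3, "i1")


class TestGenerateSeeds:
    def test_worked_example_seeds(self, worked_example):
        nets, sim = worked_example
        pre = preprocess_similarity(nets, sim)
        seeds = generate_seeds(example_clusters(nets, pre), nets, pre, 50.0)
        assert seeds == {("A2", "B2"), ("A2", "B3")}

    def test_infinite_tau_gives_no_seeds(self, worked_example):
        nets, sim = worked_example
        pre = preprocess_similarity(nets, sim)
        seeds = generate_seeds(example_clusters(nets, pre), nets, pre, math.inf)
        assert seeds == set()

    def test_tau_zero_gives_all_cross_network_cluster_pairs(self):
        # one cluster of c mutually similar proteins across 2 networks
        a = Network("A", frozenset({"a1", "a2"}), frozenset())
        b = Network("B", frozenset({"b1", "b2", "b3"}), frozenset())
        nets = NetworkCollection([a, b])
        entries = {
            _canon(x, y): 1.0
            for x in a.vertices
            for y in b.vertices
        }
        sim = SimilarityMatrix(entries)
        clusters = ClusterSet([frozenset(a.vertices | b.vertices)], "i1")
        seeds = generate_seeds(clusters, nets, sim, 0.0)
        # C(5,2) minus within-network pairs C(2,2)+C(3,2)
        assert len(seeds) == math.comb(5, 2) - 1 - 3

    def test_seed_count_monotone_in_tau(self, worked_example):
        nets, sim = worked_example
        pre = preprocess_similarity(nets, sim)
        clusters = example_clusters(nets, pre)
        counts = [
            len(generate_seeds(clusters, nets, pre, tau))
            for tau in [0, 10, 30, 50, 60, 61, 85, 86, 1000]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_negative_tau_rejected(self, worked_example):
        nets, sim = worked_example
        with pytest.raises(InputFormatError):
            generate_seeds(example_clusters(nets, sim), nets, sim, -1.0)


class TestMergeCriterion:
    def test_two_positive_singletons_merge(self, worked_example, pairwise_params):
        nets, sim = worked_example
        state = AlignmentState(nets, sim)
        assert merge_criterion("A2", "B2", state, pairwise_params)
        assert state.match_set["A2"] is state.match_set["B2"]
        assert state.ali["A2"] and state.ali["B2"]

    def test_size_gate(self, pairwise_params):
        # |S(vi)| + |S(vj)| = 6 > omega * |Net(union)| = 2.5 * 2 = 5
        nets = NetworkCollection(
            [
                Network("A", frozenset({"a1", "a2", "a3"}), frozenset()),
                Network("B", frozenset({"b1", "b2", "b3"}), frozenset()),
            ]
        )
        sim = SimilarityMatrix({("a1", "b1"): 10.0})
        state = AlignmentState(nets, sim)
        big_a = {"a1", "a2", "a3"}
        big_b = {"b1", "b2", "b3"}
        for v in big_a:
            state.match_set[v] = big_a
        for v in big_b:
            state.match_set[v] = big_b
        assert not merge_criterion("a1", "b1", state, pairwise_params)
        assert state.counters.rejects_size == 1

    def test_worked_example_rejects_extending_pair_by_third(self, worked_example):
        nets, sim = worked_example
        pre = preprocess_similarity(nets, sim)
        params = AlignmentParams(tau=50, beta=0.1, rho=0.6, omega=2.5)
        state = AlignmentState(nets, pre)
        assert merge_criterion("A2", "B2", state, params)
        # maxSim = 85, count = 1 (only A2-B3 > 8.5), expandRatio = 1,
        # 1 * 1 < 2 * 1 * 0.6
        assert not merge_criterion("A2", "B3", state, params)
        assert state.match_set["B3"] == {"B3"}

    def test_zero_sim_singletons_merge_only_when_allowed(self, worked_example):
        nets, sim = worked_example
        params = AlignmentParams(rho=0.6)
        state = AlignmentState(nets, sim)
        assert not merge_criterion("A3", "B2", state, params)
        assert merge_criterion(
            "A3", "B2", state, params, allow_zero_sim_singletons=True
        )
        state2 = AlignmentState(nets, sim)
        params_off = AlignmentParams(rho=0.6, merge_zero_sim_singletons=False)
        assert not merge_criterion(
            "A3", "B2", state2, params_off, allow_zero_sim_singletons=True
        )

    def test_symmetric_in_arguments(self, worked_example, pairwise_params):
        nets, sim = worked_example
        s1 = AlignmentState(nets, sim)
        s2 = AlignmentState(nets, sim)
        assert merge_criterion("A2", "B2", s1, pairwise_params) == merge_criterion(
            "B2", "A2", s2, pairwise_params
        )


class TestExpandSeeds:
    def test_worked_example_expansion(self, worked_example, pairwise_params):
        nets, sim = worked_example
        pre = preprocess_similarity(nets, sim)
        state = AlignmentState(nets, pre)
        expand_seeds({("A2", "B2"), ("A2", "B3")}, state, pairwise_params)
        aln = state.to_alignment()
        assert set(aln.as_sets()) == {
            frozenset({"A1", "B1"}),
            frozenset({"A2", "B2"}),
            frozenset({"A3", "B4"}),
        }

    def test_empty_seed_set_gives_empty_alignment(self, worked_example, pairwise_params):
        nets, sim = worked_example
        state = AlignmentState(nets, sim)
        expand_seeds(set(), state, pairwise_params)
        assert len(state.to_alignment()) == 0

    def test_ring_propagation(self):
        """One seed on two identical 10-rings with identity similarity
        propagates all the way around."""
        n = 10
        ra = [f"r{i}" for i in range(n)]
        rb = [f"s{i}" for i in range(n)]
        nets = NetworkCollection(
            [
                Network(
                    "A",
                    frozenset(ra),
                    frozenset(_canon(ra[i], ra[(i + 1) % n]) for i in range(n)),
                ),
                Network(
                    "B",
                    frozenset(rb),
                    frozenset(_canon(rb[i], rb[(i + 1) % n]) for i in range(n)),
                ),
            ]
        )
        sim = SimilarityMatrix({_canon(ra[i], rb[i]): 1.0 for i in range(n)})
        state = AlignmentState(nets, sim)
        expand_seeds({_canon("r0", "s0")}, state, AlignmentParams(rho=0.6))
        aln = state.to_alignment()
        assert set(aln.as_sets()) == {
            frozenset({ra[i], rb[i]}) for i in range(n)
        }

    def test_singletons_discarded_from_alignment(self, worked_example, pairwise_params):
        nets, sim = worked_example
        pre = preprocess_similarity(nets, sim)
        state = AlignmentState(nets, pre)
        expand_seeds({("A2", "B2"), ("A2", "B3")}, state, pairwise_params)
        aln = state.to_alignment()
        assert "B3" not in aln.covered()
        assert all(len(s) >= 2 for s in aln.as_sets())


class TestAlignRemaining:
    def test_worked_example_is_noop_after_expansion(self, worked_example, pairwise_params):
        nets, sim = worked_example
        pre = preprocess_similarity(nets, sim)
        state = AlignmentState(nets, pre)
        expand_seeds({("A2", "B2"), ("A2", "B3")}, state, pairwise_params)
        before = set(state.to_alignment().as_sets())
        align_remaining(state, pairwise_params)
        assert set(state.to_alignment().as_sets()) == before

    def test_two_unaligned_similar_proteins_pair_up(self, worked_example, pairwise_params):
        nets, sim = worked_example
        state = AlignmentState(nets, sim)
        align_remaining(state, pairwise_params)
        assert state.match_set["A2"] is state.match_set["B3"]  # top score 60

    def test_three_network_chain_matches_stepwise_oracle(self):
        nets = NetworkCollection(
            [
                Network("A", frozenset({"x"}), frozenset()),
                Network("B", frozenset({"y"}), frozenset()),
                Network("C", frozenset({"z"}), frozenset()),
            ]
        )
        sim = SimilarityMatrix(
            {("x", "y"): 5.0, ("y", "z"): 4.0, ("x", "z"): 3.0}
        )
        params = AlignmentParams()
        state = AlignmentState(nets, sim)
        align_remaining(state, params)
        # oracle replay: (x,y) merges first (score 5); then (y,z) offers
        # {x,y} + {z}: maxSim 5, count 2 (scores 4 and 3 > 0.5),
        # expandRatio 3/2, 3 >= 2 * 0.5 -> merged into a 3-network set
        assert state.match_set["x"] == {"x", "y", "z"}

    def test_zero_score_pairs_never_considered(self):
        nets = NetworkCollection(
            [
                Network("A", frozenset({"x"}), frozenset()),
                Network("B", frozenset({"y"}), frozenset()),
            ]
        )
        state = AlignmentState(nets, SimilarityMatrix())
        align_remaining(state, AlignmentParams())
        assert len(state.to_alignment()) == 0


class TestPipeline:
    def test_worked_example_with_preprocessing(self, worked_example, pairwise_params):
        nets, sim = worked_example
        aln, report = run_pipeline(nets, sim, pairwise_params)
        assert set(aln.as_sets()) == {
            frozenset({"A1", "B1"}),
            frozenset({"A2", "B2"}),
            frozenset({"A3", "B4"}),
        }
        assert report.n_seeds == 2
        assert report.clustering_runs == 1

    def test_worked_example_without_preprocessing(self, worked_example):
        nets, sim = worked_example
        params = AlignmentParams(
            tau=50, beta=0.1, rho=0.6, omega=2.5, preprocess=False
        )
        aln, _ = run_pipeline(nets, sim, params)
        assert set(aln.as_sets()) == {
            frozenset({"A2", "B3"}),
            frozenset({"A3", "B2"}),
            frozenset({"A1", "B1"}),
        }

    def test_single_network_rejected(self):
        nets = NetworkCollection(
            [Network("A", frozenset({"a", "b"}), frozenset({("a", "b")}))]
        )
        with pytest.raises(InputFormatError):
            run_pipeline(nets, SimilarityMatrix(), AlignmentParams())

    def test_deterministic(self, worked_example, pairwise_params):
        nets, sim = worked_example
        a1, _ = run_pipeline(nets, sim, pairwise_params)
        a2, _ = run_pipeline(nets, sim, pairwise_params)
        assert a1 == a2

    @pytest.mark.parametrize("seed", range(5))
    def test_match_sets_always_disjoint(self, seed):
        rng = random.Random(seed)
        nets, sim = random_instance(rng, k=3, max_n=10)
        if not sim.proteins():
            return
        aln, _ = run_pipeline(nets, sim, AlignmentParams(tau=10.0))
        seen = set()
        for s in aln.as_sets():
            assert not (s & seen)
            seen |= s

    @pytest.mark.parametrize("seed", range(8))
    def test_pairwise_mode_limits_match_sets_to_two(self, seed):
        """With rho > 0.5 and two networks every match-set has exactly 2
        members (the pairwise-alignment constraint)."""
        rng = random.Random(100 + seed)
        nets, sim = random_instance(rng, k=2, max_n=12)
        if not sim.proteins():
            return
        aln, _ = run_pipeline(
            nets, sim, AlignmentParams(tau=0.0, rho=0.6)
        )
        assert all(len(s) == 2 for s in aln.as_sets())

    def test_every_merge_passed_criterion_replay(self, worked_example, pairwise_params):
        """Replaying the merge log against a fresh reference state accepts
        every logged merge at its moment of execution."""
        nets, sim = worked_example
        pre = preprocess_similarity(nets, sim)
        state = AlignmentState(nets, pre)
        expand_seeds({("A2", "B2"), ("A2", "B3")}, state, pairwise_params)
        align_remaining(state, pairwise_params)
        replay = AlignmentState(nets, pre)
        for vi, vj in state.merge_log:
            assert merge_criterion(
                vi, vj, replay, pairwise_params, allow_zero_sim_singletons=True
            )
        assert {frozenset(s) for s in replay.match_set.values()} == {
            frozenset(s) for s in state.match_set.values()
        }
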