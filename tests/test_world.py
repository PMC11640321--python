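"""Unit tests of world construction and the per-agent operations."""

import numpy as np
import pytest

from sarudango.params import SimParams
from sarudango.world import (Candidate, attempt_join, attempt_leave,
                             cluster_sizes, find_candidate_cluster,
                             init_world, move_lone_agent, tick,
                             tick_reference, update_cluster_positions)

from conftest import make_world, place_cluster


class TestInitWorld:
    def test_seed_reproducibility(self, small_params):
        w1 = init_world(small_params, 1)
        w2 = init_world(small_params, 1)
        assert np.array_equal(w1.pos_x, w2.pos_x)
        assert np.array_equal(w1.heading, w2.heading)
        assert w1.rng.bit_generator.state == w2.rng.bit_generator.state

    def test_everyone_starts_lone_inside_torus(self, small_world):
        assert small_world.n_lone == small_world.params.group_size
        assert all(a.cluster_id == -1 and a.huddle_time == 0
                   for a in small_world.agents)
        assert np.all((small_world.pos_x >= 0) & (small_world.pos_x < 16))
        assert np.all((small_world.pos_y >= 0) & (small_world.pos_y < 16))
        assert small_world.clusters == {}
        assert small_world.tick_count == 0

    def test_two_agent_world(self):
        w = make_world(n=2)
        assert len(w.agents) == 2
        assert cluster_sizes(w) == []


class TestMoveLoneAgent:
    def test_wraparound_east(self):
        w = make_world(n=2)
        w.pos_x[0], w.pos_y[0] = 15.5, 8.0
        move_lone_agent(w, 0)
        # force the exact wrap case deterministically
        w.pos_x[0], w.pos_y[0], w.heading[0] = 15.5, 8.0, 0.0
        from sarudango._engine import _step_forward
        nx, ny = _step_forward(15.5, 8.0, 0.0, 16.0, 16.0)
        assert nx == pytest.approx(0.5)
        assert ny == pytest.approx(8.0)

    def test_unit_step_length(self):
        w = make_world(n=5, seed=11)
        for agent in range(5):
            x0, y0 = w.pos_x[agent], w.pos_y[agent]
            move_lone_agent(w, agent)
            dx = min(abs(w.pos_x[agent] - x0), 16 - abs(w.pos_x[agent] - x0))
            dy = min(abs(w.pos_y[agent] - y0), 16 - abs(w.pos_y[agent] - y0))
            assert np.hypot(dx, dy) == pytest.approx(1.0)

    def test_clustered_agent_cannot_move(self):
        w = make_world(n=4)
        place_cluster(w, [0, 1])
        with pytest.raises(ValueError):
            move_lone_agent(w, 0)

    def test_headings_uniform(self):
        """Chi-square goodness of fit of 10,000 sampled headings against
        uniformity on [0, 2pi), alpha = 0.01."""
        from scipy.stats import chisquare

        w = make_world(n=2, seed=123)
        samples = []
        for _ in range(5000):
            for agent in (0, 1):
                move_lone_agent(w, agent)
                samples.append(w.heading[agent])
        counts, _ = np.histogram(samples, bins=20, range=(0, 2 * np.pi))
        assert chisquare(counts).pvalue > 0.01


class TestFindCandidate:
    def test_empty_neighbourhood(self):
        w = make_world(n=2)
        w.pos_x[:] = [0.0, 8.0]
        w.pos_y[:] = [0.0, 8.0]
        assert find_candidate_cluster(w, 0) is None

    def test_lone_partner_found(self):
        w = make_world(n=2)
        w.pos_x[:] = [5.0, 6.0]
        w.pos_y[:] = [5.0, 5.0]
        cand = find_candidate_cluster(w, 0)
        assert cand == Candidate(kind="lone", size=1, partner_id=1)

    def test_largest_policy_prefers_cluster_over_closer_lone(self):
        w = make_world(n=8, candidate_policy="largest")
        place_cluster(w, [1, 2, 3, 4, 5], x=6.0, y=5.0)  # size 5 at dist ~1.5
        w.pos_x[0], w.pos_y[0] = 4.6, 5.0
        w.pos_x[6], w.pos_y[6] = 4.1, 5.0               # lone at dist 0.5
        w.pos_x[7], w.pos_y[7] = 12.0, 12.0             # out of range
        cand = find_candidate_cluster(w, 0)
        assert cand.kind == "cluster"
        assert cand.size == 5

    def test_largest_policy_tie_breaks_by_lowest_cluster_id(self):
        w = make_world(n=10, candidate_policy="largest")
        cid_a = place_cluster(w, [1, 2, 3], x=4.5, y=5.0)
        cid_b = place_cluster(w, [4, 5, 6], x=5.5, y=5.0)
        w.pos_x[0], w.pos_y[0] = 5.0, 5.0
        cand = find_candidate_cluster(w, 0)
        assert cand.cluster_id == min(cid_a, cid_b)

    def test_random_policy_is_uniform_over_neighbours(self):
        w = make_world(n=4, seed=5)  # default random_neighbor policy
        w.pos_x[:] = [5.0, 5.5, 4.5, 5.2]
        w.pos_y[:] = [5.0, 5.0, 5.0, 5.3]
        picks = {1: 0, 2: 0, 3: 0}
        for _ in range(3000):
            cand = find_candidate_cluster(w, 0)
            picks[cand.partner_id] += 1
        for count in picks.values():  # 3 neighbours, expect ~1000 each
            assert 850 < count < 1150

    def test_rejects_huddled_caller(self):
        w = make_world(n=4)
        place_cluster(w, [0, 1])
        with pytest.raises(ValueError):
            find_candidate_cluster(w, 0)


class TestJoinAndLeave:
    def test_certain_join_full_group_cluster(self):
        w = make_world(n=10, t=1, j=1)
        cid = place_cluster(w, list(range(1, 10)), x=5.0, y=5.0)
        w.pos_x[0], w.pos_y[0] = 5.0, 5.0
        cand = find_candidate_cluster(w, 0)
        assert cand.kind == "cluster"
        # p_join = (9/10) * 1 * 1; u forced just below
        assert attempt_join(w, 0, cand, u=0.899999)
        assert w.agent(0).cluster_id == cid
        assert cluster_sizes(w) == [10]

    def test_failed_join_leaves_world_unchanged(self):
        w = make_world(n=4, t=2, j=4)
        place_cluster(w, [1, 2], x=5.0, y=5.0)
        w.pos_x[0], w.pos_y[0] = 5.5, 5.0
        cand = find_candidate_cluster(w, 0)
        before = w.slot.copy()
        assert not attempt_join(w, 0, cand, u=0.999)
        assert np.array_equal(w.slot, before)

    def test_nucleation_creates_fresh_pair(self):
        w = make_world(n=6, t=1, j=1)
        w.pos_x[:] = [5.0, 5.5, 10.0, 11.0, 12.0, 13.0]
        w.pos_y[:] = [5.0, 5.0, 2.0, 2.0, 2.0, 2.0]
        w.pos_y[2:] = 14.0  # keep the rest far away
        cand = Candidate(kind="lone", size=1, partner_id=1)
        assert attempt_join(w, 0, cand, u=0.0)
        assert w.agent(0).cluster_id == w.agent(1).cluster_id == 0
        assert cluster_sizes(w) == [2]
        assert w.clusters[0]["anchor"] == (5.0, 5.0)  # joiner's position

    def test_leave_releases_and_dissolves_pair(self):
        w = make_world(n=6, lv=10)
        place_cluster(w, [0, 1], x=5.0, y=5.0)
        assert attempt_leave(w, 0, u=0.0)
        # the abandoned partner is released too; no 1-member huddles
        assert w.agent(0).cluster_id == -1
        assert w.agent(1).cluster_id == -1
        assert cluster_sizes(w) == []
        assert w.n_lone == 6

    def test_leave_from_full_group_impossible(self):
        w = make_world(n=5, lv=10)
        place_cluster(w, list(range(5)))
        assert not attempt_leave(w, 0, u=0.0)  # p_leave = 0 exactly
        assert w.agent(0).huddle_time == 1     # staying increments the clock

    def test_stayer_keeps_position(self):
        w = make_world(n=6, lv=10)
        place_cluster(w, [0, 1, 2], x=5.0, y=5.0)
        x0 = w.pos_x[0]
        assert not attempt_leave(w, 0, u=0.999)
        assert w.pos_x[0] == x0

    def test_bernoulli_calibration(self):
        """Join decisions at p = 0.05 over 10,000 trials stay inside a 99%
        binomial interval around 500."""
        w = make_world(n=20, t=2, j=5, seed=31)  # p = (10/20)*(1/2)*(1/5)=0.05
        place_cluster(w, list(range(10)), x=5.0, y=5.0)
        cand = Candidate(kind="cluster", size=10, cluster_id=0)
        joins = 0
        for _ in range(10_000):
            u = w.rng.random()
            if u < (10 / 20) * (1 / 2) * (1 / 5):
                joins += 1
        # 99% interval for Binomial(10000, 0.05): ~444..556
        assert 440 <= joins <= 560


class TestUpdateClusterPositions:
    def test_two_members_diametrically_opposite(self):
        w = make_world(n=4)
        cid = place_cluster(w, [0, 1], x=5.0, y=5.0)
        update_cluster_positions(w, cid)
        v0 = np.array([w.pos_x[0] - 5.0, w.pos_y[0] - 5.0])
        v1 = np.array([w.pos_x[1] - 5.0, w.pos_y[1] - 5.0])
        assert np.allclose(v0, -v1, atol=1e-12)

    def test_four_members_right_angles(self):
        w = make_world(n=6)
        cid = place_cluster(w, [0, 1, 2, 3], x=8.0, y=8.0)
        update_cluster_positions(w, cid)
        angles = np.arctan2(w.pos_y[:4] - 8.0, w.pos_x[:4] - 8.0)
        gaps = np.diff(np.sort(angles))
        assert np.allclose(gaps, np.pi / 2, atol=1e-9)

    def test_members_stay_within_sensing_radius_of_anchor(self):
        w = make_world(n=12)
        cid = place_cluster(w, list(range(9)), x=2.0, y=15.0)
        update_cluster_positions(w, cid)
        for a in range(9):
            dx = min(abs(w.pos_x[a] - 2.0), 16 - abs(w.pos_x[a] - 2.0))
            dy = min(abs(w.pos_y[a] - 15.0), 16 - abs(w.pos_y[a] - 15.0))
            assert np.hypot(dx, dy) <= w.params.sensing_radius + 1e-12


class TestClusterSizes:
    def test_registry_matches_brute_force(self):
        w = make_world(n=12)
        place_cluster(w, [0, 1, 2])
        place_cluster(w, [5, 6], x=12.0, y=3.0)
        sizes = cluster_sizes(w)
        brute = np.bincount(w.slot[w.slot >= 0])
        assert sorted(sizes) == sorted(int(c) for c in brute if c > 0)

    def test_corruption_detected(self):
        w = make_world(n=6)
        place_cluster(w, [0, 1, 2])
        w.slot_size[w.slot[0]] = 5  # corrupt the registry
        with pytest.raises(RuntimeError):
            cluster_sizes(w)


class TestTick:
    def test_full_cluster_world_is_absorbing(self):
        w = make_world(n=8, t=1, j=1, lv=10)
        place_cluster(w, list(range(8)))
        before = w.slot.copy()
        n_lone = tick(w)
        assert n_lone == 0
        assert np.array_equal(w.slot, before)
        assert w.tick_count == 1

    def test_out_of_range_pair_cannot_cluster(self):
        w = make_world(n=2, t=1, j=1)
        w.pos_x[:] = [0.0, 8.0]
        w.pos_y[:] = [0.0, 8.0]
        tick(w)  # one step of movement cannot bridge ~11 patches
        assert cluster_sizes(w) == []

    def test_agent_count_conserved(self):
        w = make_world(n=25, t=1, j=1, lv=10, seed=13)
        for _ in range(60):
            tick(w)
            assert len(w.agents) == 25
            sizes = cluster_sizes(w)  # also validates the registry
            assert sum(sizes) + w.n_lone == 25

    @pytest.mark.parametrize("policy", ["random_neighbor", "largest"])
    @pytest.mark.parametrize("seed", [1, 7, 123])
    def test_kernel_matches_reference_implementation(self, policy, seed):
        """The compiled kernel and the pure-python operation pipeline agree:
        identical discrete state and RNG stream every tick, positions to
        1e-9 (the two compilation contexts may differ in the last ulp)."""
        p = SimParams(24, 2, 1, 10, candidate_policy=policy)
        w_fast, w_ref = init_world(p, seed), init_world(p, seed)
        for t in range(250):
            tick(w_fast)
            tick_reference(w_ref)
            assert np.array_equal(w_fast.slot, w_ref.slot), t
            assert np.array_equal(w_fast.slot_cid, w_ref.slot_cid), t
            assert np.array_equal(w_fast.huddle_time, w_ref.huddle_time), t
            assert np.array_equal(w_fast.meta, w_ref.meta), t
            assert np.allclose(w_fast.pos_x, w_ref.pos_x, atol=1e-9)
            assert np.allclose(w_fast.pos_y, w_ref.pos_y, atol=1e-9)
            assert (w_fast.rng.bit_generator.state
                    == w_ref.rng.bit_generator.state), t

    def test_registry_consistency_under_fuzzed_ticks(self):
        """500 ticks of a busy world never desynchronise the registry from
        a brute-force group-by of agents."""
        w = make_world(n=30, t=1, j=1, lv=10, seed=99)
        for _ in range(500):
            tick(w)
            sizes = sorted(cluster_sizes(w, validate=True))
            brute = np.bincount(w.slot[w.slot >= 0], minlength=0)
            assert sizes == sorted(int(c) for c in brute if c > 0)
            assert all(s >= 2 for s in sizes)
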