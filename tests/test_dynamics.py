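"""Dynamical engine: weight construction, threshold update, classification,
and the exhaustive enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import attractorprune as ap
from attractorprune.dynamics import (
    FIXED_POINT,
    LIMIT_CYCLE,
    NONCONVERGENT,
    enumerate_attractors,
    probe_basins,
)


def _pattern(n, seed):
    return ap.random_attractor(n, np.random.default_rng(seed))


class TestOuterMatrix:
    @pytest.mark.parametrize(
        "s, expected",
        [
            ([1, 1], [[1, 1], [1, 1]]),
            ([1, -1], [[1, -1], [-1, 1]]),
        ],
    )
    def test_small_dyads(self, s, expected):
        assert ap.outer_attractor_matrix(np.array(s)).tolist() == expected

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_eigen_relation_and_rank(self, seed):
        s = _pattern(50, seed)
        w = ap.outer_attractor_matrix(s)
        assert np.array_equal(w, w.T)
        assert np.array_equal(w.astype(int) @ s.astype(int), 50 * s.astype(int))
        assert np.linalg.matrix_rank(w.astype(float)) == 1

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_pattern_and_complement_are_fixed(self, seed):
        s = _pattern(24, seed)
        w = ap.outer_attractor_matrix(s)
        assert ap.is_fixed_point(w, s)
        assert ap.is_fixed_point(w, -s)


class TestStep:
    def test_pattern_is_fixed_and_complement_maps_to_itself(self):
        s = _pattern(20, 3)
        w = ap.outer_attractor_matrix(s)
        assert np.array_equal(ap.step(w, s), s)
        assert np.array_equal(ap.step(w, -s), -s)

    def test_orthogonal_state_hits_the_zero_sum_tie_rule(self):
        # x ⟂ s gives every node a zero input sum; ties resolve to +1.
        rng = np.random.default_rng(4)
        s = ap.random_attractor(10, rng)
        x = ap.orthogonal_partner(s, rng)
        w = ap.outer_attractor_matrix(s)
        assert np.array_equal(ap.step(w, x), np.ones(10, dtype=np.int8))

    def test_dimension_mismatch_raises(self):
        w = ap.outer_attractor_matrix(np.array([1, -1, 1]))
        with pytest.raises(ValueError):
            ap.step(w, np.array([1, -1]))


class TestIsFixedPoint:
    def test_zero_matrix_pins_everything_to_all_ones(self):
        w = np.zeros((4, 4), dtype=np.int8)
        assert ap.is_fixed_point(w, np.ones(4, dtype=np.int8))
        assert not ap.is_fixed_point(w, np.array([1, -1, 1, 1], dtype=np.int8))

    def test_orthogonal_vector_is_not_fixed(self):
        rng = np.random.default_rng(8)
        s = ap.random_attractor(12, rng)
        r = ap.orthogonal_partner(s, rng)
        if np.all(r == 1):  # the one state the tie rule does fix
            r = -r
        assert not ap.is_fixed_point(ap.outer_attractor_matrix(s), r)


class TestEvolve:
    def test_full_net_converges_within_two_steps_off_the_knife_edge(self):
        rng = np.random.default_rng(5)
        s = ap.random_attractor(30, rng)
        w = ap.outer_attractor_matrix(s)
        for _ in range(20):
            x = ap.random_initial_states(30, 1, rng)[0]
            if int(x.astype(int) @ s.astype(int)) == 0:
                continue
            res = ap.evolve(w, x)
            assert res.outcome == FIXED_POINT
            assert res.iterations <= 2
            assert any(np.array_equal(res.terminal_states[0], t) for t in (s, -s))

    def test_start_at_fixed_point_costs_no_iterations(self):
        s = _pattern(16, 6)
        res = ap.evolve(ap.outer_attractor_matrix(s), s)
        assert res.outcome == FIXED_POINT and res.iterations <= 1

    def test_constructed_two_cycle(self):
        # Negative self-links flip both nodes every step: (1,1) <-> (-1,-1).
        w = -np.eye(2, dtype=np.int8)
        res = ap.evolve(w, np.array([1, 1], dtype=np.int8))
        assert res.outcome == LIMIT_CYCLE and res.period == 2
        assert len(res.terminal_states) == 2

    def test_period_four_rotation(self):
        w = np.array([[0, -1], [1, 0]], dtype=np.int8)
        res = ap.evolve(w, np.array([1, -1], dtype=np.int8))
        assert res.outcome == LIMIT_CYCLE and res.period == 4

    def test_cycle_beyond_screen_reports_nonconvergent(self):
        w = np.array([[0, -1], [1, 0]], dtype=np.int8)
        res = ap.evolve(w, np.array([1, -1], dtype=np.int8), max_period=2, max_iters=50)
        assert res.outcome == NONCONVERGENT


class TestEnumeration:
    def test_full_net_terminals_are_the_pattern_pair(self):
        s = _pattern(8, 9)
        atts = enumerate_attractors(ap.outer_attractor_matrix(s))
        assert sum(a.basin_size for a in atts) == 256
        assert all(a.period == 1 for a in atts)
        terminals = [a.states[0] for a in atts]
        assert len(terminals) == 2
        for t in terminals:
            assert np.array_equal(t, s) or np.array_equal(t, -s)

    def test_zero_matrix_single_global_fixed_point(self):
        atts = enumerate_attractors(np.zeros((4, 4), dtype=np.int8))
        assert len(atts) == 1
        assert atts[0].period == 1 and atts[0].basin_size == 16
        assert np.array_equal(atts[0].states[0], np.ones(4, dtype=np.int8))

    def test_refuses_large_state_spaces(self):
        with pytest.raises(ValueError):
            enumerate_attractors(np.zeros((25, 25), dtype=np.int8))

    def test_sampled_basin_fractions_match_exact_basins(self):
        # a partially pruned net, so ±s no longer own the whole state space
        rng = np.random.default_rng(10)
        s = ap.random_attractor(10, rng)
        full = ap.outer_attractor_matrix(s)
        # prune progressively harder until foreign attractors own part of
        # the state space but ±s still hold some of it
        for drop in (60, 70, 80, 88):
            w = full.copy()
            w.flat[rng.choice(100, size=drop, replace=False)] = 0
            p = 0.0
            for a in enumerate_attractors(w):
                if a.period == 1 and any(
                    np.array_equal(a.states[0], t) for t in (s, -s)
                ):
                    p += a.basin_size / 1024
            if 0.0 < p < 1.0:
                break
        assert 0.0 < p < 1.0
        starts = ap.random_initial_states(10, 400, rng)
        report = probe_basins(w, starts, [s], fail_fast=False)
        tol = 4 * np.sqrt(p * (1 - p) / 400)
        assert abs(report.target_hits[0] / 400 - p) <= tol


def _classification_agrees(w, max_iters=500, max_period=4):
    """Check every state's evolve() outcome against the exhaustive oracle."""
    n = w.shape[0]
    atts = enumerate_attractors(w)
    state_of = {}
    for a in atts:
        for st_vec in a.states:
            state_of[tuple(int(v) for v in st_vec)] = a
    for k in range(1 << n):
        x = np.array([1 if (k >> i) & 1 else -1 for i in range(n)], dtype=np.int8)
        res = ap.evolve(w, x, max_iters=max_iters, max_period=max_period)
        if res.outcome == NONCONVERGENT:
            # only legitimate when the true terminal cycle exceeds the screen
            term = _terminal_of(w, x, state_of)
            assert term.period > max_period
        else:
            assert res.period == _terminal_of(w, x, state_of).period
            key = tuple(int(v) for v in res.terminal_states[0])
            assert key in state_of


def _terminal_of(w, x, state_of):
    seen = set()
    while tuple(int(v) for v in x) not in state_of:
        key = tuple(int(v) for v in x)
        assert key not in seen
        seen.add(key)
        x = ap.step(w, x)
    return state_of[tuple(int(v) for v in x)]


@pytest.mark.parametrize("builder", ["full", "bulk", "rotation", "zero"])
def test_evolve_agrees_with_exhaustive_oracle(builder):
    rng = np.random.default_rng(11)
    if builder == "full":
        w = ap.outer_attractor_matrix(ap.random_attractor(8, rng))
    elif builder == "bulk":
        s = ap.random_attractor(10, rng)
        w = ap.outer_attractor_matrix(s)
        drop = rng.choice(100, size=40, replace=False)
        w.flat[drop] = 0
    elif builder == "rotation":
        w = np.array([[0, -1], [1, 0]], dtype=np.int8)
    else:
        w = np.zeros((6, 6), dtype=np.int8)
    _classification_agrees(w)


class TestEdgeList:
    def test_round_trip_is_lossless(self, tmp_path, rng):
        s = ap.random_attractor(15, rng)
        w = ap.outer_attractor_matrix(s)
        w.flat[rng.choice(225, size=150, replace=False)] = 0
        path = tmp_path / "net.tsv"
        ap.write_edgelist(w, path)
        assert np.array_equal(ap.read_edgelist(path, n_nodes=15), w)

    def test_header_and_orientation(self, tmp_path):
        w = np.zeros((3, 3), dtype=np.int8)
        w[2, 0] = -1  # link from node 0 into node 2
        path = tmp_path / "one.tsv"
        ap.write_edgelist(w, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "source\ttarget\tweight"
        assert lines[1] == "0\t2\t-1"
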