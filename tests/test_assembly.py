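"""Unit and property tests for the permutation-method assembly pipeline."""

import numpy as np
import pytest
from scipy import stats

from permnet import (
    AssemblyConfig,
    AssemblyFailure,
    BiDegreeSequence,
    DegreeSequenceSpec,
    assemble,
    build_precursor,
    donor_sweep,
    feasible_moves,
    generate_degree_sequences,
    inert_shuffle,
    multi_edge_proportion,
    out_degree_residual,
    permute_rows,
    transfer_edge,
)
from permnet.sampling import enumerate_initial_permutations, matrix_key
from conftest import REALISATIONS_121, START_EXAMPLE


def nw_corner(row_sums, col_sums):
    """North-west-corner transportation fill: a matrix with given margins."""
    row_sums, col_sums = list(row_sums), list(col_sums)
    assert sum(row_sums) == sum(col_sums)
    a = np.zeros((len(row_sums), len(col_sums)), dtype=np.int64)
    i = j = 0
    while i < len(row_sums) and j < len(col_sums):
        x = min(row_sums[i], col_sums[j])
        a[i, j] = x
        row_sums[i] -= x
        col_sums[j] -= x
        if row_sums[i] == 0:
            i += 1
        else:
            j += 1
    return a


class TestPrecursor:
    def test_binary_left_packed(self, seq121):
        a = build_precursor(seq121, AssemblyConfig())
        assert a.tolist() == [[1, 0, 0], [1, 1, 0], [1, 0, 0]]

    def test_zero_multi_target_equals_binary(self, toy_seq, rng):
        cfg = AssemblyConfig(multi_target_proportion=0.0)
        assert np.array_equal(
            build_precursor(toy_seq, cfg, rng), build_precursor(toy_seq, AssemblyConfig())
        )

    def test_single_row_high_target(self, rng):
        seq = BiDegreeSequence([5, 0], [0, 5])
        a = build_precursor(seq, AssemblyConfig(multi_target_proportion=0.8), rng)
        assert a.sum() == 5
        assert np.maximum(a - 1, 0).sum() == 4  # round(0.8 * 5) multi-edge units
        assert multi_edge_proportion(a) == pytest.approx(4 / 5)

    @pytest.mark.parametrize("proportion", [0.1, 0.5, 0.9])
    def test_multi_count_hits_target_or_capacity(self, proportion, rng):
        spec = DegreeSequenceSpec(n_nodes=40, k_min=2, k_max=12, seed=3)
        seq = generate_degree_sequences(spec)
        cfg = AssemblyConfig(multi_target_proportion=proportion)
        a = build_precursor(seq, cfg, rng)
        assert np.array_equal(a.sum(axis=1), seq.k_in)
        target = round(proportion * seq.n_edges)
        capacity = int(np.maximum(seq.k_in - 1, 0).sum())
        assert int(np.maximum(a - 1, 0).sum()) == min(target, capacity)


class TestPermuteRows:
    def test_zero_row_unchanged_and_sums_preserved(self, toy_seq, rng):
        a = build_precursor(toy_seq, AssemblyConfig())
        a[0] = 0
        p = permute_rows(a, rng)
        assert np.array_equal(p[0], np.zeros(9, dtype=np.int64))
        assert np.array_equal(p.sum(axis=1), a.sum(axis=1))

    def test_joint_uniformity_chi2(self, seq121, rng):
        """All 3*3*3 = 27 row arrangements equally likely (alpha = 0.001)."""
        a0 = build_precursor(seq121, AssemblyConfig())
        n_draws = 27_000
        counts = {}
        for _ in range(n_draws):
            key = matrix_key(permute_rows(a0, rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 27
        _, p_value = stats.chisquare(list(counts.values()))
        assert p_value > 0.001


class TestResidual:
    def test_worked_nine_node_example(self, toy_seq):
        realised = [0, 3, 3, 2, 1, 4, 6, 4, 0]
        a = nw_corner(toy_seq.k_in, realised)
        state = out_degree_residual(a, toy_seq)
        assert state.residual.tolist() == [-1, -1, 2, 1, 0, 2, 3, -5, -1]
        assert state.r_out == pytest.approx(np.sqrt(46))
        assert state.donors.tolist() == [2, 3, 5, 6]
        assert state.recipients.tolist() == [0, 1, 7, 8]
        assert state.inerts.tolist() == [4]

    def test_converged_state(self, seq121):
        a = np.array(REALISATIONS_121[0])
        state = out_degree_residual(a, seq121)
        assert state.r_out == 0.0
        assert state.inerts.size == 3 and state.donors.size == 0


class TestTransferEdge:
    def test_two_feasible_moves_from_example_start(self, seq121):
        a = START_EXAMPLE.copy()
        state = out_degree_residual(a, seq121)
        rows, recips = feasible_moves(a, 0, state, AssemblyConfig())
        assert rows.size == 2
        assert set(zip(rows.tolist(), recips.tolist())) == {(0, 1), (1, 1)}

    def test_blocked_binary_target_cell(self, seq121):
        a = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1]])
        state = out_degree_residual(a, seq121)  # residual [2, -1, -1]... donor 0
        before = a.copy()
        # row 1 already has an edge in column 1: binary cap forbids the move
        assert not transfer_edge(a, donor=0, recipient=1, row=1,
                                 config=AssemblyConfig(), state=state)
        assert np.array_equal(a, before)

    def test_transfer_decreases_abs_residual_by_two(self, rng):
        cfg = AssemblyConfig()
        performed = 0
        while performed < 1000:
            spec = DegreeSequenceSpec(
                n_nodes=12, k_min=1, k_max=6, seed=int(rng.integers(2**31))
            )
            seq = generate_degree_sequences(spec)
            a = permute_rows(build_precursor(seq, cfg), rng)
            state = out_degree_residual(a, seq)
            for d in state.donors:
                rows, recips = feasible_moves(a, int(d), state, cfg)
                if rows.size == 0:
                    continue
                k = int(rng.integers(rows.size))
                before_abs = state.sum_abs
                before_rows = a.sum(axis=1).copy()
                assert transfer_edge(a, int(d), int(recips[k]), int(rows[k]),
                                     cfg, state)
                assert state.sum_abs == before_abs - 2
                assert np.array_equal(a.sum(axis=1), before_rows)
                performed += 1


class TestDonorSweep:
    def test_no_donors_returns_zero(self, seq121, rng):
        a = np.array(REALISATIONS_121[1])
        state = out_degree_residual(a, seq121)
        assert donor_sweep(a, state, AssemblyConfig(), rng) == (0, 0)

    def test_toy_network_converges_without_shuffling(self, toy_seq):
        # a run of the demonstration network that never needs the annealing
        cfg = AssemblyConfig(seed=1, inert_activation_ratio=0.0)
        result = assemble(toy_seq, cfg)
        assert result.trace.status == "converged"
        assert sum(result.trace.shuffles) == 0
        assert result.trace.n_sweeps <= 25

    def test_sweeps_never_increase_abs_residual(self, rng):
        cfg = AssemblyConfig()
        spec = DegreeSequenceSpec(n_nodes=50, k_min=2, k_max=20, seed=9)
        seq = generate_degree_sequences(spec)
        a = permute_rows(build_precursor(seq, cfg), rng)
        state = out_degree_residual(a, seq)
        prev = state.sum_abs
        for _ in range(30):
            donor_sweep(a, state, cfg, rng)
            assert state.sum_abs <= prev
            prev = state.sum_abs


class TestInertShuffle:
    def test_checkerboard_preserves_both_margins(self, rng):
        # inert column 0, recipient column 1: the only swap is the checkerboard
        seq = BiDegreeSequence([1, 1], [1, 1])
        a = np.array([[1, 0], [0, 1]])
        state = out_degree_residual(a, BiDegreeSequence([1, 1], [1, 2]))
        # state: residual [0, -1] -> column 0 inert, column 1 active
        done = inert_shuffle(a, state, AssemblyConfig(allow_self_loops=True), rng)
        if done:
            assert a.tolist() == [[0, 1], [1, 0]]
        assert np.array_equal(a.sum(axis=1), seq.k_in)
        assert np.array_equal(a.sum(axis=0), np.array([1, 1]))

    def test_shuffle_closure_on_small_space(self, seq121, rng):
        """Shuffles keep every k_in-respecting binary start valid, residual intact."""
        cfg = AssemblyConfig()
        for a1 in enumerate_initial_permutations(seq121, cfg):
            state = out_degree_residual(a1, seq121)
            if state.inerts.size == 0 or state.donors.size == 0:
                continue
            a = a1.copy()
            res_before = state.residual.copy()
            inert_shuffle(a, state, cfg, rng)
            assert np.array_equal(a.sum(axis=1), seq121.k_in)
            assert np.array_equal(state.residual, res_before)
            assert np.array_equal(a.sum(axis=0) - seq121.k_out, res_before)
            assert a.max() <= 1


class TestAssemble:
    def test_small_instance_lands_on_a_valid_realisation(self, seq121):
        result = assemble(seq121, AssemblyConfig(seed=2))
        assert matrix_key(result.matrix) in set(REALISATIONS_121)

    def test_toy_network_forced_self_loop(self, toy_seq):
        result = assemble(toy_seq, AssemblyConfig(seed=0))
        a = result.matrix
        assert a[7, 7] >= 1  # node 8's k_out = 9 = N forces the loop
        assert np.array_equal(a.sum(axis=1), toy_seq.k_in)
        assert np.array_equal(a.sum(axis=0), toy_seq.k_out)

    @pytest.mark.parametrize("proportion", [0.0, 0.4])
    def test_random_sequences_matched_exactly(self, proportion):
        for seed in range(5):
            spec = DegreeSequenceSpec(n_nodes=50, k_min=3, k_max=20, seed=seed)
            seq = generate_degree_sequences(spec)
            cfg = AssemblyConfig(
                seed=seed, multi_target_proportion=proportion, debug_checks=True
            )
            result = assemble(seq, cfg)
            a = result.matrix
            assert np.array_equal(a.sum(axis=1), seq.k_in)
            assert np.array_equal(a.sum(axis=0), seq.k_out)
            if proportion == 0:
                assert a.max() <= 1

    def test_multi_edge_count_invariant_through_assembly(self):
        spec = DegreeSequenceSpec(n_nodes=40, k_min=3, k_max=15, seed=21)
        seq = generate_degree_sequences(spec)
        cfg = AssemblyConfig(seed=4, multi_target_proportion=0.3)
        result = assemble(seq, cfg)
        final_m = int(np.maximum(result.matrix - 1, 0).sum())
        assert final_m == result.trace.multi_achieved_count
        assert result.trace.multi_achieved_count == round(0.3 * seq.n_edges)

    def test_no_self_loop_mode_keeps_diagonal_empty(self):
        spec = DegreeSequenceSpec(n_nodes=30, k_min=2, k_max=10, seed=8)
        seq = generate_degree_sequences(spec)
        result = assemble(
            seq, AssemblyConfig(seed=1, allow_self_loops=False, debug_checks=True)
        )
        assert np.all(np.diag(result.matrix) == 0)

    def test_small_n_success_rate_without_shuffling(self):
        """Tiny binary assemblies occasionally dead-end; most still succeed."""
        seq = BiDegreeSequence([2, 3, 1, 2, 2], [2, 2, 2, 2, 2])
        cfg = AssemblyConfig(inert_activation_ratio=0.0, stall_sweeps=5)
        rng = np.random.default_rng(77)
        ok = 0
        n_runs = 200
        for _ in range(n_runs):
            try:
                assemble(seq, cfg, rng)
                ok += 1
            except AssemblyFailure:
                pass
        assert ok / n_runs >= 0.75

    def test_failure_carries_trace(self, toy_seq):
        cfg = AssemblyConfig(seed=3, max_donor_loops=1)
        with pytest.raises(AssemblyFailure) as err:
            assemble(toy_seq, cfg)
        assert err.value.trace is not None
        assert err.value.trace.status in ("stalled", "loop-limit")
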