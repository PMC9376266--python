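from __future__ import annotations

import itertools

import numpy as np
import pytest

from san import (
    NONE,
    Memory,
    associate,
    compute_outputs,
    init_network,
    readout,
    recall,
)

from conftest import (
    REF_TARGET_M,
    disjoint_dataset,
    make_dataset,
    make_schema,
    random_small_dataset,
)
from oracle import oracle_recall

V_ON = 0.001


class TestInit:
    def test_reference_profile_neuron_count(self):
        state = init_network(make_schema(REF_TARGET_M))
        assert state.n_neurons == 778
        assert not state.weights.any()

    def test_two_singleton_sets(self):
        state = init_network(make_schema((1, 1)))
        assert state.n_neurons == 2
        assert state.allowed_weight_count() == 2

    def test_allowed_weight_count_formula(self):
        sizes = (3, 2, 4)
        state = init_network(make_schema(sizes))
        n = sum(sizes)
        assert state.allowed_weight_count() == n * n - sum(m * m for m in sizes)

    @pytest.mark.parametrize("v_on,e_mag", [(0, 1), (-1, 1), (0.001, 0), (0.001, -2)])
    def test_nonpositive_parameters_rejected(self, v_on, e_mag):
        with pytest.raises(ValueError):
            init_network(make_schema((2, 2)), v_on=v_on, e_mag=e_mag)


class TestComputeOutputs:
    def test_zero_weights_identity(self, eight_set_memory_net):
        state, _ = eight_set_memory_net
        state = init_network(state.schema)  # fresh, all-zero
        e = np.zeros(state.n_neurons)
        e[0] = 1.0
        act = compute_outputs(state, e)
        np.testing.assert_array_equal(act.f, e)

    def test_partial_clamp_feedback_values(self, eight_set_memory_net):
        # one stored memory, external input on 4 of its 8 features
        state, m = eight_set_memory_net
        ids = state.memory_neurons(m)
        e = np.zeros(state.n_neurons)
        e[ids[:4]] = 1.0
        f = compute_outputs(state, e).f
        # each unclamped member feature: 4 programmed incoming weights
        np.testing.assert_allclose(f[ids[4:]], 4 * V_ON)
        # each clamped member feature: e_mag + 3 programmed cross-set weights
        np.testing.assert_allclose(f[ids[:4]], 1.0 + 3 * V_ON)
        # all non-member neurons silent
        mask = np.ones(state.n_neurons, bool)
        mask[ids] = False
        assert not f[mask].any()

    def test_input_validation(self, eight_set_memory_net):
        state, _ = eight_set_memory_net
        with pytest.raises(ValueError):
            compute_outputs(state, np.zeros(3))
        bad = np.zeros(state.n_neurons)
        bad[0] = 0.5  # not in {0, e_mag}
        with pytest.raises(ValueError):
            compute_outputs(state, bad)

    def test_trust_guarantee(self, rng):
        # with fewer than 1/v_on active neurons, any clamped neuron's
        # output strictly exceeds any unclamped neuron's output
        for _ in range(20):
            d = random_small_dataset(rng)
            state = init_network(d.schema)
            for m in d.memories:
                associate(state, m)
            k = int(rng.integers(1, d.schema.n + 1))
            sets = rng.choice(d.schema.n, size=k, replace=False)
            m = d.memories[int(rng.integers(d.i_tot))]
            ids = state.memory_neurons(m)
            e = np.zeros(state.n_neurons)
            e[ids[sets]] = 1.0
            f = compute_outputs(state, e).f
            clamped = e > 0
            if (~clamped).any():
                assert f[clamped].min() > f[~clamped].max()


class TestAssociate:
    def test_single_memory_programs_56_weights(self, eight_set_memory_net):
        state, _ = eight_set_memory_net
        programmed = state.weights > 0
        assert programmed.sum() == 8 * 7
        assert np.all(state.weights[programmed] == V_ON)

    def test_idempotent(self, eight_set_memory_net):
        state, m = eight_set_memory_net
        before = state.weights.copy()
        associate(state, m)
        np.testing.assert_array_equal(state.weights, before)

    def test_two_disjoint_memories_program_112(self):
        d = disjoint_dataset(2, n_sets=8)
        state = init_network(d.schema)
        for m in d.memories:
            associate(state, m)
        assert (state.weights > 0).sum() == 112

    def test_invalid_memory_rejected(self, eight_set_memory_net):
        state, _ = eight_set_memory_net
        with pytest.raises(Exception):
            associate(state, Memory((9, 0, 0, 0, 0, 0, 0, 0)))

    def test_block_zero_preserved(self, rng):
        # no operation writes intra-set or self weights
        d = random_small_dataset(rng)
        state = init_network(d.schema)
        for m in d.memories:
            associate(state, m)
        set_of = state.set_of
        same_set = set_of[:, None] == set_of[None, :]
        assert not state.weights[same_set].any()


class TestReadout:
    def test_all_zero_gives_sentinels(self, eight_set_memory_net):
        state, _ = eight_set_memory_net
        act = compute_outputs(init_network(state.schema), np.zeros(state.n_neurons))
        ro = readout(init_network(state.schema), act)
        assert np.all(ro.y == NONE)
        assert ro.tied_sets == ()

    def test_strict_winners(self, eight_set_memory_net):
        state, m = eight_set_memory_net
        ids = state.memory_neurons(m)
        e = np.zeros(state.n_neurons)
        e[ids] = 1.0
        ro = readout(state, compute_outputs(state, e))
        assert tuple(ro.y) == m.feature_indices

    def test_tie_signalled(self):
        d = make_dataset([[0, 0, 0], [0, 1, 1]])
        state = init_network(d.schema)
        for m in d.memories:
            associate(state, m)
        e = np.zeros(state.n_neurons)
        e[state.memory_neurons(d.memories[0])[0]] = 1.0  # shared feature only
        ro = readout(state, compute_outputs(state, e))
        assert 1 in ro.tied_sets and 2 in ro.tied_sets


class TestRecall:
    def test_single_memory_any_input_subset(self, eight_set_memory_net):
        # perfect deterministic recall from every non-empty input subset
        state, m = eight_set_memory_net
        rng = np.random.default_rng(0)
        for k in range(1, 9):
            for sets in itertools.combinations(range(8), k):
                ro, hit = recall(state, m, sets, rng)
                assert hit
                assert tuple(ro.y) == m.feature_indices

    def test_empty_network_misses_with_sentinels(self):
        schema = make_schema((2, 2, 2, 2))
        state = init_network(schema)
        m = Memory((0, 0, 0, 0))
        ro, hit = recall(state, m, (0, 1), np.random.default_rng(0))
        assert not hit
        assert tuple(ro.y[2:]) == (NONE, NONE)
        assert tuple(ro.y[:2]) == (0, 0)  # clamped sets still win

    def test_two_memory_tie_statistics(self):
        # two memories identical on the 4 input sets, disjoint elsewhere:
        # the first coin flip decides, so hit rate is exactly 1/2
        a = [0, 0, 0, 0, 0, 0, 0, 0]
        b = [0, 0, 0, 0, 1, 1, 1, 1]
        d = make_dataset([a, b])
        state = init_network(d.schema)
        for m in d.memories:
            associate(state, m)
        rng = np.random.default_rng(2024)
        n_trials = 2000
        hits = sum(
            recall(state, d.memories[0], (0, 1, 2, 3), rng)[1] for _ in range(n_trials)
        )
        assert abs(hits / n_trials - 0.5) <= 0.03

    def test_tie_resolution_is_consistent_downstream(self):
        # once a tied feature is clamped, the remaining sets resolve to
        # the same memory (its features get the extra +v_on feedback)
        a = [0, 0, 0, 0, 0, 0, 0, 0]
        b = [0, 0, 0, 0, 1, 1, 1, 1]
        d = make_dataset([a, b])
        state = init_network(d.schema)
        for m in d.memories:
            associate(state, m)
        rng = np.random.default_rng(7)
        for _ in range(200):
            ro, _ = recall(state, d.memories[0], (0, 1, 2, 3), rng)
            assert tuple(ro.y) in {tuple(a), tuple(b)}

    def test_weights_never_mutated(self, eight_set_memory_net):
        state, m = eight_set_memory_net
        before = state.weights.copy()
        recall(state, m, (0, 1), np.random.default_rng(0))
        np.testing.assert_array_equal(state.weights, before)

    def test_input_sets_validation(self, eight_set_memory_net):
        state, m = eight_set_memory_net
        with pytest.raises(ValueError):
            recall(state, m, (), np.random.default_rng(0))
        with pytest.raises(ValueError):
            recall(state, m, (99,), np.random.default_rng(0))


class TestOracleEquivalence:
    def test_200_randomized_instances(self):
        # package recall vs literal neuron-by-neuron reference, same rng
        master = np.random.default_rng(99)
        for _ in range(200):
            d = random_small_dataset(master)
            state = init_network(d.schema)
            for m in d.memories:
                associate(state, m)
            m = d.memories[int(master.integers(d.i_tot))]
            k = int(master.integers(1, d.schema.n))
            sets = tuple(int(s) for s in master.choice(d.schema.n, size=k, replace=False))
            seed = int(master.integers(2**32))
            ro, hit = recall(state, m, sets, np.random.default_rng(seed))
            y_ref, hit_ref = oracle_recall(state, m, sets, np.random.default_rng(seed))
            np.testing.assert_array_equal(ro.y, y_ref)
            assert hit == hit_ref
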