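"""Solver correctness: closed forms, oracle agreement, symmetry, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogtutor.environments import preset_env
from cogtutor.metalevel import (
    TERMINATE,
    Belief,
    CoverageError,
    UnsupportedEnvironmentError,
    brute_force_oracle,
    canonicalize,
    click,
    compute_loss,
    legal_computations,
    optimal_computations,
    solve,
    solve_generic_uncanonicalized,
    termination_value,
    update_belief,
)


def all_beliefs(env):
    """Every belief of a (tiny) discrete environment."""
    nodes = env.graph.reward_nodes()
    options = [(None, *env.spec_for(n).support) for n in nodes]
    for combo in itertools.product(*options):
        yield Belief({n: float(v) for n, v in zip(nodes, combo) if v is not None})


class TestBeliefAndComputations:
    def test_legal_computations_toy2(self, toy2_env):
        empty = Belief.empty()
        assert legal_computations(toy2_env, empty) == {click("d1_0"), click("d1_1"), TERMINATE}
        full = empty.observe("d1_0", 1.0).observe("d1_1", -1.0)
        assert legal_computations(toy2_env, full) == {TERMINATE}

    def test_training_empty_belief_has_13_computations(self):
        env = preset_env("training_3step")
        assert len(legal_computations(env, Belief.empty())) == 13

    def test_update_is_persistent_and_guarded(self):
        b0 = Belief.empty()
        b1 = update_belief(b0, click("d1_0"), 1.0)
        assert len(b0) == 0 and len(b1) == 1 and b1["d1_0"] == 1.0
        with pytest.raises(ValueError):
            update_belief(b1, click("d1_0"), 1.0)  # re-click
        with pytest.raises(ValueError):
            update_belief(b1, TERMINATE, 0.0)


class TestTerminationValue:
    def test_empty_belief_is_prior_best(self, toy2_env):
        assert termination_value(toy2_env, Belief.empty()) == 0.0

    def test_single_observation(self, toy2_env):
        assert termination_value(toy2_env, Belief({"d1_0": 1.0})) == 1.0
        assert termination_value(toy2_env, Belief({"d1_0": -1.0})) == 0.0

    def test_lone_final_48_dominates(self, small_env):
        assert termination_value(small_env, Belief({"d3_0": 48.0})) == 48.0


class TestToy2ClosedForm:
    """Hand derivation: Q(∅, click) = 0.5·E[max(X, 0)] − cost = 0.5 − 0.25."""

    @pytest.mark.parametrize("method", ["fast", "generic", "oracle"])
    def test_empty_belief_values(self, toy2_env, method):
        q = (brute_force_oracle(toy2_env) if method == "oracle"
             else solve(toy2_env, method=method))
        empty = Belief.empty()
        assert q.q(empty, click("d1_0")) == pytest.approx(0.25, abs=1e-12)
        assert q.q(empty, TERMINATE) == 0.0
        assert q.root_value == pytest.approx(0.25, abs=1e-12)
        assert compute_loss(q, empty, TERMINATE) == pytest.approx(0.25, abs=1e-12)
        assert compute_loss(q, empty, click("d1_0")) == 0.0

    def test_bad_first_draw_means_stop(self, toy2_q):
        b = Belief({"d1_0": -1.0})
        assert optimal_computations(toy2_q, b) == {TERMINATE}
        assert toy2_q.value(b) == 0.0

    def test_symmetric_empty_argmax(self, toy2_q):
        assert optimal_computations(toy2_q, Belief.empty()) == {click("d1_0"), click("d1_1")}


@pytest.mark.parametrize("env_fixture", ["toy2_env", "toy21_env", "toy212_env"])
def test_solver_matches_brute_force_oracle_everywhere(env_fixture, request):
    """max |ΔQ| < 1e-9 between the production solver and the naive recursion,
    over every belief and every legal computation."""
    env = request.getfixturevalue(env_fixture)
    q = solve(env)
    oracle = brute_force_oracle(env)
    worst = 0.0
    for belief in all_beliefs(env):
        for c in legal_computations(env, belief):
            worst = max(worst, abs(q.q(belief, c) - oracle.q(belief, c)))
    assert worst < 1e-9


def test_oracle_refuses_large_environments():
    with pytest.raises(UnsupportedEnvironmentError):
        brute_force_oracle(preset_env("training_3step"))


def test_gaussian_environment_rejected_with_pointer():
    with pytest.raises(UnsupportedEnvironmentError, match="goal-setting"):
        solve(preset_env("transfer_5step"))


class TestCanonicalization:
    def test_exchangeable_leaves_share_a_key(self, toy2_env):
        assert canonicalize(toy2_env, Belief({"d1_0": 1.0})) == \
            canonicalize(toy2_env, Belief({"d1_1": 1.0}))

    def test_different_values_different_keys(self, toy2_env):
        assert canonicalize(toy2_env, Belief({"d1_0": 1.0})) != \
            canonicalize(toy2_env, Belief({"d1_0": -1.0}))

    def test_canonicalization_preserves_values(self, toy212_env):
        q_raw = solve_generic_uncanonicalized(toy212_env)
        q = solve(toy212_env)
        for belief in all_beliefs(toy212_env):
            assert q.value(belief) == pytest.approx(q_raw.value(belief), abs=1e-9)

    def test_branch_permutation_leaves_value_invariant(self, small_q):
        # swap the two root branches of the [2,1,2] tree
        swap = {"d1_0": "d1_1", "d1_1": "d1_0", "d2_0": "d2_1", "d2_1": "d2_0",
                "d3_0": "d3_2", "d3_1": "d3_3", "d3_2": "d3_0", "d3_3": "d3_1"}
        rng = np.random.default_rng(7)
        env = small_q.env
        nodes = env.graph.reward_nodes()
        for _ in range(25):
            chosen = [n for n in nodes if rng.random() < 0.5]
            b = Belief({n: float(rng.choice(env.spec_for(n).support)) for n in chosen})
            pb = Belief({swap[n]: v for n, v in b.items()})
            assert small_q.value(b) == pytest.approx(small_q.value(pb), abs=1e-12)


class TestSolvedTableInvariants:
    def test_terminate_q_equals_termination_value(self, small_q, small_env):
        rng = np.random.default_rng(3)
        nodes = small_env.graph.reward_nodes()
        for _ in range(50):
            chosen = [n for n in nodes if rng.random() < 0.4]
            b = Belief({n: float(rng.choice(small_env.spec_for(n).support)) for n in chosen})
            assert small_q.q(b, TERMINATE) == termination_value(small_env, b)
            assert small_q.value(b) >= small_q.q(b, TERMINATE) - 1e-12  # value of information
            best = optimal_computations(small_q, b)
            assert best
            assert all(compute_loss(small_q, b, c) == 0.0 for c in best)

    def test_root_value_nonnegative(self, toy2_q, small_q):
        assert toy2_q.root_value >= 0.0
        assert small_q.root_value >= 0.0

    def test_greedy_prefers_terminate_then_smallest_node(self, toy2_q):
        assert toy2_q.greedy_computation(Belief.empty()) == click("d1_0")
        assert toy2_q.greedy_computation(Belief({"d1_0": 1.0})) == TERMINATE

    def test_coverage_error_for_out_of_support_values(self, toy2_env):
        q = solve(toy2_env, method="generic")
        with pytest.raises(CoverageError):
            q.value(Belief({"d1_0": 0.5}))

    def test_loss_requires_legal_computation(self, toy2_q):
        with pytest.raises(ValueError):
            compute_loss(toy2_q, Belief({"d1_0": 1.0}), click("d1_0"))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_value_dominates_termination_everywhere(toy212_env, data):
    """Property: V(b) ≥ Q(b, ⊥) and every loss is nonnegative."""
    q = solve(toy212_env)
    nodes = toy212_env.graph.reward_nodes()
    obs = {}
    for n in nodes:
        v = data.draw(st.sampled_from((None, *toy212_env.spec_for(n).support)), label=n)
        if v is not None:
            obs[n] = float(v)
    b = Belief(obs)
    assert q.value(b) >= q.q(b, TERMINATE) - 1e-12
    for c in legal_computations(toy212_env, b):
        assert compute_loss(q, b, c) >= 0.0


def test_qtable_json_round_trip(toy2_env):
    q = solve(toy2_env, method="generic")
    text = q.to_json()
    loaded = type(q).from_json(toy2_env, text)
    for b in all_beliefs(toy2_env):
        assert loaded.value(b) == pytest.approx(q.value(b), abs=1e-12)
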