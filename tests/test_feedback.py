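import numpy as np
import pytest

from cogtutor.environments import (
    EnvConfig,
    GroundTruth,
    RewardSpec,
    TaskGraph,
    enumerate_paths,
    preset_env,
    sample_ground_truth,
)
from cogtutor.feedback import (
    CalibrationError,
    FeedbackConfig,
    action_feedback,
    annotate_trial,
    calibrate_scaling,
    feedback_for_mode,
    metacognitive_feedback,
)
from cogtutor.metalevel import TERMINATE, Belief, click, legal_computations, solve
from cogtutor.policies import OptimalPolicy, rollout


@pytest.fixture(scope="module")
def calibrated(small_env, small_q):
    return calibrate_scaling(small_env, small_q, FeedbackConfig())


class TestCalibration:
    def test_toy2_scaling_constant(self, toy2_env, toy2_q):
        cfg = calibrate_scaling(toy2_env, toy2_q, FeedbackConfig())
        # loss of terminating with no information is 0.25 -> a = 40 / 0.25
        assert cfg.scaling_a == pytest.approx(160.0)

    def test_no_planning_delay_hits_target_exactly(self, small_q, calibrated):
        ev = metacognitive_feedback(small_q, Belief.empty(), TERMINATE, calibrated)
        assert ev.delay == 42.0

    def test_constant_reward_env_calibrates_to_same_target(self):
        spec = RewardSpec.discrete((-10, -5, 5, 10))
        env = EnvConfig(graph=TaskGraph.from_branching((2, 1, 2)),
                        reward_by_depth={1: spec, 2: spec, 3: spec},
                        click_cost=1.0, name="constant_small")
        q = solve(env)
        cfg = calibrate_scaling(env, q, FeedbackConfig())
        assert metacognitive_feedback(q, Belief.empty(), TERMINATE, cfg).delay == 42.0

    def test_worthless_planning_cannot_calibrate(self):
        # one-node tree, single path: clicking can never change the decision
        env = EnvConfig(graph=TaskGraph.from_branching((1,)),
                        reward_by_depth={1: RewardSpec.discrete((-1, 1))},
                        click_cost=0.25, name="chain1")
        q = solve(env)
        with pytest.raises(CalibrationError):
            calibrate_scaling(env, q, FeedbackConfig())

    def test_uncalibrated_config_refuses_delays(self, small_q):
        with pytest.raises(CalibrationError):
            metacognitive_feedback(small_q, Belief.empty(), TERMINATE, FeedbackConfig())


class TestMetacognitiveFeedback:
    def test_early_depth1_click_is_penalized_and_redirected(self, small_q, calibrated):
        ev = metacognitive_feedback(small_q, Belief.empty(), click("d1_0"), calibrated)
        assert ev.delay > calibrated.base_delay
        assert ev.message_key == "should_have_inspected"
        assert ev.highlighted
        assert all(small_q.env.graph.depth_of[n] == 3 for n in ev.highlighted)

    def test_optimal_click_costs_nothing(self, small_q, calibrated):
        ev = metacognitive_feedback(small_q, Belief.empty(), click("d3_0"), calibrated)
        assert ev.loss == 0.0
        assert ev.delay == 0.0
        assert ev.message_key == "good_job"
        assert not ev.highlighted

    def test_clicking_past_a_48_draws_stop_message(self, small_q, calibrated):
        b = Belief({"d3_0": 48.0})
        ev = metacognitive_feedback(small_q, b, click("d2_0"), calibrated)
        assert ev.message_key == "should_not_have_inspected"
        assert ev.message == "You shouldn't have inspected any more nodes."

    def test_delay_nonincreasing_in_q(self, small_env, small_q, calibrated):
        b = Belief({"d3_0": -24.0})
        pairs = [(small_q.q(b, c), metacognitive_feedback(small_q, b, c, calibrated).delay)
                 for c in legal_computations(small_env, b)]
        pairs.sort(key=lambda t: t[0])
        delays = [d for _, d in pairs]
        assert all(a >= b for a, b in zip(delays, delays[1:]))
        # zero exactly on the argmax
        best_q = max(q for q, _ in pairs)
        assert all(d == 0.0 for q, d in pairs if abs(q - best_q) < 1e-9)

    def test_highlighted_nodes_are_unobserved(self, small_env, small_q, calibrated):
        rng = np.random.default_rng(0)
        nodes = small_env.graph.reward_nodes()
        for _ in range(20):
            chosen = [n for n in nodes if rng.random() < 0.4]
            b = Belief({n: float(rng.choice(small_env.spec_for(n).support)) for n in chosen})
            for c in legal_computations(small_env, b):
                ev = metacognitive_feedback(small_q, b, c, calibrated)
                assert ev.highlighted.isdisjoint(b.keys())
                assert ev.loss >= 0.0


class TestComponentVariants:
    def exp6(self, mode, **kw):
        return FeedbackConfig(mode=mode, unconditional_click_delay=1.0, **kw)

    def test_delay_only_penalizes_without_information(self, small_env, small_q):
        cfg = calibrate_scaling(small_env, small_q, self.exp6("metacognitive_delay_only"))
        ev = feedback_for_mode(cfg, q=small_q, belief=Belief.empty(), c=click("d1_0"))
        assert ev.delay > 1.0
        assert not ev.highlighted
        assert ev.message is None

    def test_info_only_shows_illustration_for_one_second(self, small_q):
        cfg = self.exp6("metacognitive_info_only")
        ev = feedback_for_mode(cfg, q=small_q, belief=Belief.empty(), c=click("d1_0"))
        assert ev.delay == 1.0
        assert ev.highlighted
        assert ev.message_key == "should_have_inspected"

    def test_full_mode_adds_penalty_to_unconditional_delay(self, small_env, small_q):
        cfg = calibrate_scaling(small_env, small_q, self.exp6("metacognitive_full"))
        bad = feedback_for_mode(cfg, q=small_q, belief=Belief.empty(), c=click("d1_0"))
        good = feedback_for_mode(cfg, q=small_q, belief=Belief.empty(), c=click("d3_0"))
        assert good.delay == 1.0 and good.message == "Good job!"
        assert bad.delay > 1.0 + cfg.base_delay

    def test_none_mode_emits_only_unconditional_delays(self, small_q):
        cfg = self.exp6("none")
        ev = feedback_for_mode(cfg, c=click("d1_0"))
        assert ev.delay == 1.0
        assert ev.message is None and not ev.highlighted
        assert feedback_for_mode(cfg, c=TERMINATE).delay == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            FeedbackConfig(mode="mystery")


class TestActionFeedback:
    def test_correct_move_is_free(self, toy2_env, toy2_q):
        cfg = calibrate_scaling(toy2_env, toy2_q, FeedbackConfig(mode="action"))
        truth = GroundTruth({"d1_0": 1.0, "d1_1": -1.0})
        ev = action_feedback(toy2_env, truth, "d1_0", cfg)
        assert ev.loss == 0.0 and ev.delay == 0.0

    def test_wrong_move_loss_is_path_total_gap(self, toy2_env, toy2_q):
        cfg = calibrate_scaling(toy2_env, toy2_q, FeedbackConfig(mode="action"))
        truth = GroundTruth({"d1_0": 1.0, "d1_1": -1.0})
        ev = action_feedback(toy2_env, truth, "d1_1", cfg)
        assert ev.loss == pytest.approx(2.0)  # 1 − (−1)
        assert ev.delay == pytest.approx(cfg.base_delay + cfg.scaling_a * 2.0)
        assert ev.message == "You should have moved left."

    def test_three_way_direction_labels(self):
        env = preset_env("training_3step")
        truth = sample_ground_truth(env, 1)
        cfg = FeedbackConfig(mode="action", scaling_a=1.0)
        best_first = max(((p, sum(truth[n] for n in p)) for p in enumerate_paths(env.graph)),
                         key=lambda t: t[1])[0][0]
        ev = action_feedback(env, truth, best_first, cfg)
        assert ev.loss == 0.0
        for move in sorted(env.graph.children["root"]):
            ev = action_feedback(env, truth, move, cfg)
            if ev.message_key == "should_have_moved":
                assert set(ev.message_args) <= {"left", "up", "right"}

    def test_invalid_move_rejected(self, toy2_env):
        truth = GroundTruth({"d1_0": 1.0, "d1_1": -1.0})
        with pytest.raises(ValueError):
            action_feedback(toy2_env, truth, "d2_0", FeedbackConfig(mode="action", scaling_a=1.0))

    def test_depends_only_on_truth_and_move(self, small_env, small_q, calibrated):
        # identical event regardless of what was clicked beforehand
        truth = sample_ground_truth(small_env, 6)
        cfg = FeedbackConfig(mode="action", scaling_a=calibrated.scaling_a)
        ev1 = action_feedback(small_env, truth, "d1_0", cfg)
        ev2 = action_feedback(small_env, truth, "d1_0", cfg)
        assert ev1 == ev2


class TestReplay:
    def test_optimal_trace_annotates_cleanly(self, small_env, small_q, calibrated):
        truth = sample_ground_truth(small_env, 2)
        trial = rollout(OptimalPolicy(small_q), small_env, truth, rng=0)
        events = annotate_trial(trial, calibrated, q=small_q, env=small_env, truth=truth)
        assert len(events) == len(trial.computations)
        assert all(ev.loss == 0.0 and ev.delay == 0.0 for ev in events)

    def test_illegal_trace_raises(self, small_env, small_q, calibrated):
        from cogtutor.policies import TrialRecord

        bad = TrialRecord(env=small_env.name, truth_seed=None,
                          computations=[(click("d1_0"), 2.0), (click("d1_0"), 2.0),
                                        (TERMINATE, None)],
                          chosen_path=("d1_0", "d2_0", "d3_0"), raw_score=0.0)
        with pytest.raises(ValueError):
            annotate_trial(bad, calibrated, q=small_q)
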