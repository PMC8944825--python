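"""Synthetic experimental sessions.

Scripted participants play complete sessions — a training block with tutor
feedback followed by a feedback-free test block (defaults 10 and 20 trials)
— producing the same click/move traces a human session would, so the
feedback engine and scoring pipeline can be exercised end to end without
human data.  The participant scripts are deliberately simple stand-ins for
behavioral variety (an optimal planner, an optimal planner with lapses, a
myopic forward satisficer, and a non-planner); they do not learn across
trials and are not models of human participants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .environments import EnvConfig, preset_env, sample_ground_truth
from .feedback import FeedbackConfig, annotate_trial, calibrate_scaling
from .metalevel import TERMINATE, MetaQ, click, legal_computations, solve
from .policies import Policy, RandomBaselinePolicy, TrialRecord, rollout

__all__ = [
    "ParticipantSpec",
    "SessionLog",
    "STRATEGIES",
    "simulate_participant",
    "make_fixture_suite",
]

STRATEGIES = ("optimal", "backward_lapse", "forward_satisficer", "non_planner")


@dataclass(frozen=True)
class ParticipantSpec:
    """A scripted participant."""

    strategy: str
    lapse_rate: float = 0.0
    satisficing_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.strategy}_s{self.seed}"


@dataclass
class SessionLog:
    participant: str
    condition: str
    env_name: str
    training: list[TrialRecord] = field(default_factory=list)
    test: list[TrialRecord] = field(default_factory=list)


class LapsePolicy(Policy):
    """Optimal policy that, with probability ``lapse_rate`` per step, emits a
    uniformly random legal computation instead."""

    def __init__(self, q: MetaQ, lapse_rate: float):
        self.q = q
        self.lapse_rate = lapse_rate
        self._rng: np.random.Generator | None = None

    def reset(self, env, rng):  # noqa: ARG002
        self._rng = rng

    def step(self, env, belief):
        if self.lapse_rate > 0 and self._rng.random() < self.lapse_rate:
            legal = sorted(legal_computations(env, belief))
            return legal[int(self._rng.integers(len(legal)))]
        return self.q.greedy_computation(belief)


class ForwardSatisficerPolicy(Policy):
    """Myopic foil: inspects first-step nodes in id order and stops at the
    first value at or above its threshold (or when all are checked)."""

    def __init__(self, threshold: float):
        self.threshold = threshold

    def step(self, env, belief):
        for node in env.graph.reward_nodes():
            if env.graph.depth_of[node] != 1:
                continue
            if node in belief:
                if belief[node] >= self.threshold:
                    return TERMINATE
            else:
                return click(node)
        return TERMINATE


def _policy_for(spec: ParticipantSpec, q: MetaQ | None) -> Policy:
    if spec.strategy in ("optimal", "backward_lapse"):
        if q is None:
            raise ValueError(f"strategy {spec.strategy!r} needs a solved Q table")
        rate = spec.lapse_rate if spec.strategy == "backward_lapse" else 0.0
        return LapsePolicy(q, rate)
    if spec.strategy == "forward_satisficer":
        return ForwardSatisficerPolicy(spec.satisficing_threshold)
    return RandomBaselinePolicy()


def simulate_participant(spec: ParticipantSpec, env: EnvConfig, q: MetaQ | None,
                         cfg: FeedbackConfig, n_train: int = 10,
                         n_test: int = 20) -> SessionLog:
    """Simulate one participant's session: training with feedback, test
    without.  All clicks precede the move, as the task enforces; the run is
    deterministic under ``spec.seed``."""
    if cfg.mode.startswith("metacognitive") and q is None:
        raise ValueError("metacognitive feedback conditions need a solved Q table")
    policy = _policy_for(spec, q)
    log = SessionLog(participant=spec.label, condition=cfg.mode, env_name=env.name)
    for block, n_trials, with_feedback in (("train", n_train, True), ("test", n_test, False)):
        for t in range(n_trials):
            tseed = int(np.random.SeedSequence((spec.seed, 0 if block == "train" else 1, t))
                        .generate_state(1)[0])
            truth = sample_ground_truth(env, tseed)
            trial = rollout(policy, env, truth,
                            rng=np.random.default_rng((spec.seed, block == "test", t)),
                            truth_seed=tseed)
            trial.participant = spec.label
            if with_feedback and cfg.mode != "none":
                trial.feedback = annotate_trial(trial, cfg, q=q, env=env, truth=truth)
            (log.training if block == "train" else log.test).append(trial)
    return log


DEFAULT_SPECS = (
    ParticipantSpec("optimal"),
    ParticipantSpec("backward_lapse", lapse_rate=0.2),
    ParticipantSpec("forward_satisficer", satisficing_threshold=2.0),
    ParticipantSpec("non_planner"),
)

FIXTURE_CONDITIONS = ("metacognitive_full", "action", "none")


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write a deterministic fixture suite: environment configs, solved toy
    Q-tables, and per-condition session logs (3 conditions × 4 participant
    scripts on the reduced three-step web), plus a manifest of content
    hashes.  Re-running with the same seed reproduces identical bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def write(relpath: str, text: str) -> None:
        p = out / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(text)
        files[relpath] = hashlib.sha256(text.encode()).hexdigest()

    for name in ("toy2", "training_3step_small", "training_3step",
                 "constant_3step", "transfer_5step"):
        write(f"envs/{name}.json", preset_env(name).to_json())

    for name in ("toy2",):
        env = preset_env(name)
        write(f"qtables/{name}.json", solve(env, method="generic").to_json())

    env = preset_env("training_3step_small")
    q = solve(env)
    sessions: list[str] = []
    for condition in FIXTURE_CONDITIONS:
        cfg = FeedbackConfig(mode=condition)
        if condition in ("metacognitive_full", "action"):
            cfg = calibrate_scaling(env, q, cfg)
        for i, base_spec in enumerate(DEFAULT_SPECS):
            spec = ParticipantSpec(base_spec.strategy, base_spec.lapse_rate,
                                   base_spec.satisficing_threshold,
                                   seed=seed * 1000 + i)
            log = simulate_participant(spec, env, q, cfg)
            rel = f"sessions/{condition}/{spec.label}.jsonl"
            lines = [json.dumps({**t.to_dict(), "block": b}, sort_keys=True)
                     for b, trials in (("train", log.training), ("test", log.test))
                     for t in trials]
            write(rel, "\n".join(lines) + "\n")
            sessions.append(rel)

    manifest = {"seed": seed, "files": files, "sessions": sessions,
                "conditions": list(FIXTURE_CONDITIONS),
                "n_participants_per_condition": len(DEFAULT_SPECS)}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return manifest
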