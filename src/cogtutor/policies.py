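"""Executable planning strategies and Monte-Carlo policy evaluation.

A policy chooses computations (clicks / terminate) given the current belief
and, once it terminates, a root-to-leaf path.  Provided strategies:

* the optimal metalevel policy (greedy in a solved Q table),
* the no-planning random baseline (zero clicks, uniformly random path),
* the goal-setting strategy: check final-step nodes in random order until
  one exceeds a threshold, then commit — the tractable stand-in for the
  optimal policy in environments too large to solve exactly, with
  Monte-Carlo threshold optimization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from statistics import NormalDist
from typing import Mapping, Sequence

import numpy as np

from .environments import (
    EnvConfig,
    GroundTruth,
    enumerate_paths,
    expected_path_value,
    sample_ground_truth,
    trial_score,
)
from .metalevel import TERMINATE, Belief, Computation, MetaQ, click, legal_computations, update_belief

__all__ = [
    "TrialRecord",
    "GoalSettingParams",
    "Policy",
    "OptimalPolicy",
    "RandomBaselinePolicy",
    "GoalSettingPolicy",
    "random_baseline",
    "goal_setting_policy",
    "optimize_threshold",
    "rollout",
    "evaluate_policy",
    "PolicyEvaluation",
    "write_trials_jsonl",
    "read_trials_jsonl",
]


@dataclass
class TrialRecord:
    """One trial's process trace: ordered computations, path choice, score."""

    env: str
    truth_seed: int | None
    computations: list[tuple[Computation, float | None]]
    chosen_path: tuple[str, ...]
    raw_score: float
    feedback: list = field(default_factory=list)
    participant: str | None = None

    @property
    def n_clicks(self) -> int:
        return sum(1 for c, _ in self.computations if c.is_click)

    @property
    def first_click(self) -> Computation | None:
        for c, _ in self.computations:
            if c.is_click:
                return c
        return None

    def to_dict(self) -> dict:
        comps = [{"node": c.node, "value": v} if c.is_click else {"node": "terminate"}
                 for c, v in self.computations]
        doc = {"env": self.env, "seed": self.truth_seed, "computations": comps,
               "path": list(self.chosen_path), "raw_score": self.raw_score}
        if self.participant is not None:
            doc["participant"] = self.participant
        if self.feedback:
            doc["feedback"] = [ev.to_dict() for ev in self.feedback]
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "TrialRecord":
        comps: list[tuple[Computation, float | None]] = []
        for entry in doc["computations"]:
            if entry["node"] == "terminate":
                comps.append((TERMINATE, None))
            else:
                comps.append((click(entry["node"]), float(entry["value"])))
        return cls(env=doc["env"], truth_seed=doc.get("seed"), computations=comps,
                   chosen_path=tuple(doc["path"]), raw_score=float(doc["raw_score"]),
                   participant=doc.get("participant"))


def write_trials_jsonl(trials: Sequence[TrialRecord], path) -> None:
    with open(path, "w") as fh:
        for t in trials:
            fh.write(json.dumps(t.to_dict(), sort_keys=True) + "\n")


def read_trials_jsonl(path) -> list[TrialRecord]:
    with open(path) as fh:
        return [TrialRecord.from_dict(json.loads(line)) for line in fh if line.strip()]


# --------------------------------------------------------------------------
# Policies


class Policy:
    """Base class: per-trial control of computations and the final path.

    ``reset`` is called once per trial with the trial's random stream; the
    default path choice maximizes expected value under the final belief
    (ties broken lexicographically by path).
    """

    default_seed: int = 0

    def reset(self, env: EnvConfig, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def step(self, env: EnvConfig, belief: Belief) -> Computation:
        raise NotImplementedError

    def choose_path(self, env: EnvConfig, belief: Belief,
                    rng: np.random.Generator) -> tuple[str, ...]:
        paths = enumerate_paths(env.graph)
        values = [expected_path_value(env, p, belief) for p in paths]
        best = max(values)
        return next(p for p, v in zip(paths, values) if v == best)


class OptimalPolicy(Policy):
    """Greedy in the exactly solved metalevel Q table (terminate at ties)."""

    def __init__(self, q: MetaQ):
        self.q = q

    def step(self, env: EnvConfig, belief: Belief) -> Computation:  # noqa: ARG002
        return self.q.greedy_computation(belief)


class RandomBaselinePolicy(Policy):
    """No planning: terminate immediately, pick a path uniformly at random."""

    def step(self, env: EnvConfig, belief: Belief) -> Computation:  # noqa: ARG002
        return TERMINATE

    def choose_path(self, env, belief, rng):  # noqa: ARG002
        paths = enumerate_paths(env.graph)
        return paths[int(rng.integers(len(paths)))]


@dataclass(frozen=True)
class GoalSettingParams:
    """Threshold and check-order seed of the goal-setting strategy."""

    threshold: float
    check_order_seed: int = 0
    candidate_means: Mapping[float, float] | None = field(default=None, compare=False)


class GoalSettingPolicy(Policy):
    """Check final-step nodes (seeded random order) until one exceeds the
    threshold (strictly), then commit to a path through it; if all are
    checked, commit to the best value found (ties → first encountered)."""

    def __init__(self, params: GoalSettingParams):
        self.params = params
        self.default_seed = params.check_order_seed
        self._order: list[str] = []
        self._checked: list[str] = []

    def reset(self, env: EnvConfig, rng: np.random.Generator) -> None:
        leaves = env.graph.leaves()
        self._order = [leaves[i] for i in rng.permutation(len(leaves))]
        self._checked = []

    def _target(self, belief: Belief) -> str | None:
        for n in self._checked:
            if belief[n] > self.params.threshold:
                return n
        return None

    def step(self, env: EnvConfig, belief: Belief) -> Computation:  # noqa: ARG002
        if self._target(belief) is not None or len(self._checked) == len(self._order):
            return TERMINATE
        node = self._order[len(self._checked)]
        self._checked.append(node)
        return click(node)

    def choose_path(self, env, belief, rng):
        target = self._target(belief)
        if target is None and self._checked:
            best = max(belief[n] for n in self._checked)
            target = next(n for n in self._checked if belief[n] == best)
        paths = enumerate_paths(env.graph)
        if target is not None:
            paths = [p for p in paths if target in p]
        values = [expected_path_value(env, p, belief) for p in paths]
        top = max(values)
        return next(p for p, v in zip(paths, values) if v == top)


def random_baseline() -> RandomBaselinePolicy:
    return RandomBaselinePolicy()


def goal_setting_policy(params: GoalSettingParams) -> GoalSettingPolicy:
    return GoalSettingPolicy(params)


# --------------------------------------------------------------------------
# Rollouts and evaluation


def rollout(policy: Policy, env: EnvConfig, truth: GroundTruth,
            rng: np.random.Generator | int | None = None,
            truth_seed: int | None = None) -> TrialRecord:
    """Run one trial: reveal ground-truth values on clicks until the policy
    terminates, then let it choose a path.  Raises if the policy emits an
    illegal computation (e.g. re-clicking an observed node)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(policy.default_seed if rng is None else rng)
    policy.reset(env, rng)
    belief = Belief.empty()
    computations: list[tuple[Computation, float | None]] = []
    n_nodes = env.graph.n_reward_nodes()
    while True:
        c = policy.step(env, belief)
        if c not in legal_computations(env, belief):
            raise ValueError(f"policy emitted illegal computation {c!r}")
        if not c.is_click:
            computations.append((TERMINATE, None))
            break
        value = truth[c.node]
        belief = update_belief(belief, c, value)
        computations.append((c, value))
        assert len(computations) <= n_nodes + 1
    path = policy.choose_path(env, belief, rng)
    score = trial_score(env, truth, path, sum(1 for c, _ in computations if c.is_click))
    return TrialRecord(env=env.name, truth_seed=truth_seed, computations=computations,
                       chosen_path=tuple(path), raw_score=score)


def _truth_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n)


@dataclass(frozen=True)
class PolicyEvaluation:
    mean: float
    se: float
    ci_lo: float
    ci_hi: float
    n: int
    scores: np.ndarray = field(repr=False, compare=False)


def evaluate_policy(policy: Policy, env: EnvConfig, n: int, seed: int = 0,
                    n_boot: int = 1000) -> PolicyEvaluation:
    """Mean raw score over ``n`` seeded rollouts, with SE and a seeded
    percentile bootstrap CI (``n_boot`` resamples)."""
    if n < 2:
        raise ValueError("need n >= 2 rollouts")
    seeds = _truth_seeds(seed, n)
    scores = np.empty(n)
    for i, s in enumerate(seeds):
        truth = sample_ground_truth(env, int(s))
        scores[i] = rollout(policy, env, truth, rng=np.random.default_rng((seed, i)),
                            truth_seed=int(s)).raw_score
    rng = np.random.default_rng((seed, 0xB007))
    boot = rng.choice(scores, size=(n_boot, n), replace=True).mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return PolicyEvaluation(mean=float(scores.mean()),
                            se=float(scores.std(ddof=1) / np.sqrt(n)),
                            ci_lo=float(lo), ci_hi=float(hi), n=n, scores=scores)


def default_threshold_candidates(env: EnvConfig) -> list[float]:
    """Final-depth support values plus midpoints (discrete), or 17 evenly
    spaced quantiles of the final-depth Gaussian."""
    spec = env.reward_by_depth[env.graph.max_depth]
    if spec.is_discrete:
        vals = sorted(spec.support)
        mids = [(a + b) / 2 for a, b in zip(vals, vals[1:])]
        return sorted(set(vals + mids))
    dist = NormalDist(spec.mean, spec.sd)
    return [dist.inv_cdf(p) for p in np.linspace(0.05, 0.95, 17)]


def optimize_threshold(env: EnvConfig, candidates: Sequence[float] | None = None,
                       n_sim: int = 1000, seed: int = 0) -> GoalSettingParams:
    """Pick the goal-setting threshold with the best Monte-Carlo mean score.

    All candidates are evaluated on common random numbers (same ground
    truths and same check-order streams); ties go to the smallest threshold.
    """
    if candidates is None:
        candidates = default_threshold_candidates(env)
    if not candidates:
        raise ValueError("need at least one threshold candidate")
    if n_sim < 1:
        raise ValueError("need n_sim >= 1")
    truths = [sample_ground_truth(env, int(s)) for s in _truth_seeds(seed, n_sim)]
    means: dict[float, float] = {}
    for thr in sorted(candidates):
        pol = GoalSettingPolicy(GoalSettingParams(threshold=thr, check_order_seed=seed))
        total = 0.0
        for i, truth in enumerate(truths):
            total += rollout(pol, env, truth, rng=np.random.default_rng((seed, 7, i))).raw_score
        means[thr] = total / n_sim
    best = max(means.values())
    thr = min(t for t, m in means.items() if m == best)
    return GoalSettingParams(threshold=thr, check_order_seed=seed, candidate_means=means)
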