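"""Relative-score normalization and behavioral metrics.

Raw trial payoffs are mapped to a scale on which 0 points is the expected
score of choosing a path uniformly at random with no clicks and 100 points
is the expected score of the (approximately) optimal strategy:

    relative_score(s) = 100 · (s − s̄_rand) / (s̄_opt − s̄_rand)

The optimal anchor is the exact solver's V(∅) where the environment is
solvable, otherwise the Monte-Carlo performance of the threshold-optimized
goal-setting strategy.  Also here: the backward-planning classifier (first
click on a final-step node) and participant-level summaries with bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .environments import EnvConfig, enumerate_paths, expected_path_value
from .metalevel import MetaQ, solve
from .policies import (
    TrialRecord,
    evaluate_policy,
    goal_setting_policy,
    optimize_threshold,
    random_baseline,
)

__all__ = [
    "ScoreNorm",
    "score_norm",
    "random_baseline_expected_score",
    "relative_score",
    "is_backward_planning",
    "summarize",
    "Summary",
    "summarize_sessions",
]


@dataclass(frozen=True)
class ScoreNorm:
    """Anchors of the relative-score scale for one environment."""

    s_opt: float
    s_rand: float
    method: str  # "exact" | "goal_setting_approx"
    env_name: str

    def __post_init__(self) -> None:
        if not self.s_opt > self.s_rand:
            raise ValueError(
                f"normalization undefined: s_opt ({self.s_opt}) must exceed "
                f"s_rand ({self.s_rand})")


def random_baseline_expected_score(env: EnvConfig) -> float:
    """Closed-form chance anchor: mean over paths of prior-mean path sums
    (zero clicks, uniform path choice)."""
    paths = enumerate_paths(env.graph)
    return float(np.mean([expected_path_value(env, p) for p in paths]))


def score_norm(env: EnvConfig, mode: str = "exact", n_sim: int = 10_000,
               seed: int = 0, q: MetaQ | None = None) -> ScoreNorm:
    """Compute the normalization anchors.

    ``exact`` uses V(∅) from backward induction (discrete environments
    only) and the analytic chance score; ``goal_setting_approx`` estimates
    the upper anchor by the threshold-optimized goal-setting strategy and
    the chance anchor by Monte Carlo.
    """
    if mode == "exact":
        q = q if q is not None else solve(env)
        return ScoreNorm(s_opt=q.root_value,
                         s_rand=random_baseline_expected_score(env),
                         method="exact", env_name=env.name)
    if mode == "goal_setting_approx":
        params = optimize_threshold(env, n_sim=n_sim, seed=seed)
        s_opt = evaluate_policy(goal_setting_policy(params), env, n=n_sim, seed=seed + 1).mean
        s_rand = evaluate_policy(random_baseline(), env, n=n_sim, seed=seed + 2).mean
        return ScoreNorm(s_opt=s_opt, s_rand=s_rand,
                         method="goal_setting_approx", env_name=env.name)
    raise ValueError(f"unknown score_norm mode {mode!r}")


def relative_score(s: float, norm: ScoreNorm) -> float:
    """Map a raw score to the 0 = chance, 100 = optimal scale (not clipped)."""
    return 100.0 * (s - norm.s_rand) / (norm.s_opt - norm.s_rand)


def is_backward_planning(trial: TrialRecord, env: EnvConfig) -> bool:
    """True iff the trial's first click inspects a final-step node."""
    first = trial.first_click
    if first is None:
        return False
    return env.graph.depth_of[first.node] == env.graph.max_depth


@dataclass(frozen=True)
class Summary:
    n_participants: int
    n_trials: int
    mean_relative_score: float
    score_ci: tuple[float, float]
    backward_rate: float
    backward_ci: tuple[float, float]
    per_participant: pd.DataFrame


def summarize(trials: Iterable[TrialRecord], norm: ScoreNorm, env: EnvConfig,
              n_boot: int = 1000, seed: int = 0) -> Summary:
    """Participant-level averages of relative score and backward-planning
    rate, with percentile bootstrap CIs over participant means."""
    rows = [{"participant": t.participant if t.participant is not None else "p0",
             "relative_score": relative_score(t.raw_score, norm),
             "backward": float(is_backward_planning(t, env))}
            for t in trials]
    if not rows:
        raise ValueError("no trials to summarize")
    df = pd.DataFrame(rows)
    per = df.groupby("participant", sort=True).mean(numeric_only=True)
    rng = np.random.default_rng((seed, 0xB007))

    def ci(values: np.ndarray) -> tuple[float, float]:
        boot = rng.choice(values, size=(n_boot, len(values)), replace=True).mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        return float(lo), float(hi)

    return Summary(
        n_participants=len(per),
        n_trials=len(df),
        mean_relative_score=float(per["relative_score"].mean()),
        score_ci=ci(per["relative_score"].to_numpy()),
        backward_rate=float(per["backward"].mean()),
        backward_ci=ci(per["backward"].to_numpy()),
        per_participant=per,
    )


def summarize_sessions(logs: Sequence, norm: ScoreNorm, env: EnvConfig,
                       block: str = "test", n_boot: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Per-condition summary table over session logs (one row per feedback
    condition): n, mean relative score with CI, backward-planning rate."""
    by_condition: dict[str, list[TrialRecord]] = {}
    for log in logs:
        trials = log.test if block == "test" else log.training
        by_condition.setdefault(log.condition, []).extend(trials)
    rows = []
    for condition in sorted(by_condition):
        s = summarize(by_condition[condition], norm, env, n_boot=n_boot, seed=seed)
        rows.append({"condition": condition, "n": s.n_participants,
                     "mean_relative_score": s.mean_relative_score,
                     "ci_lo": s.score_ci[0], "ci_hi": s.score_ci[1],
                     "backward_rate": s.backward_rate})
    return pd.DataFrame(rows)
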