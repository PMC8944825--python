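"""The intelligent tutor: turning Q-value regret into feedback.

Each inferred planning operation c in belief b is scored by its regret
``loss(b, c) = max_c' Q(b, c') − Q(b, c)``.  A suboptimal operation draws a
delay penalty of ``base + a·loss`` seconds, where the scaling factor a is
calibrated so that terminating at the empty belief — acting without any
planning — costs a configured target delay (42 s by default).  Info-bearing
modes additionally highlight the optimal click targets and attach a
message; component-ablation modes (delay-only, info-only, none) reproduce
the factorial feedback variants.  Action feedback instead scores only the
first move, against the full-information task-level values.

Delays are numbers in the returned event; nothing here ever sleeps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .environments import ROOT, EnvConfig, GroundTruth, enumerate_paths
from .metalevel import (
    TERMINATE,
    Belief,
    Computation,
    MetaQ,
    compute_loss,
    optimal_computations,
    update_belief,
)

__all__ = [
    "FeedbackConfig",
    "FeedbackEvent",
    "CalibrationError",
    "MESSAGES",
    "MODES",
    "calibrate_scaling",
    "metacognitive_feedback",
    "action_feedback",
    "feedback_for_mode",
    "annotate_trial",
]

MODES = ("metacognitive_full", "metacognitive_delay_only", "metacognitive_info_only",
         "action", "none")
_META_MODES = MODES[:3]
_INFO_MODES = ("metacognitive_full", "metacognitive_info_only")
_DELAY_MODES = ("metacognitive_full", "metacognitive_delay_only", "action")

LOSS_TOL = 1e-9

MESSAGES: Mapping[str, str] = {
    "good_job": "Good job!",
    "should_have_inspected": "You should have inspected one of the highlighted nodes.",
    "should_not_have_inspected": "You shouldn't have inspected any more nodes.",
    "should_have_moved": "You should have moved {directions}.",
}

DELAY_SCREEN_TEXT = "Delay penalty for poor planning: {seconds} seconds"


class CalibrationError(ValueError):
    """Delay scaling cannot be calibrated (e.g. planning is worthless)."""


@dataclass(frozen=True)
class FeedbackConfig:
    """Tutor configuration.

    ``scaling_a`` (seconds per money unit) is normally set by
    :func:`calibrate_scaling` so that the no-planning delay equals
    ``target_no_planning_delay``.  ``unconditional_click_delay`` and
    ``posttrial_delay`` support the component-ablation variants;
    ``min_planning_time`` is recorded for session runners and not enforced
    here.
    """

    mode: str = "metacognitive_full"
    base_delay: float = 2.0
    scaling_a: float | None = None
    target_no_planning_delay: float = 42.0
    unconditional_click_delay: float = 0.0
    posttrial_delay: float = 0.0
    min_planning_time: float = 7.0
    direction_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown feedback mode {self.mode!r}; choose from {MODES}")
        for name in ("base_delay", "target_no_planning_delay",
                     "unconditional_click_delay", "posttrial_delay", "min_planning_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.scaling_a is not None and self.mode in _DELAY_MODES and not self.scaling_a > 0:
            raise ValueError("scaling_a must be > 0 for delay-bearing modes")

    def _require_scaling(self) -> float:
        if self.scaling_a is None:
            raise CalibrationError(
                "scaling_a is unset; run calibrate_scaling() before generating "
                "delay-bearing feedback")
        return self.scaling_a


@dataclass(frozen=True)
class FeedbackEvent:
    """The tutor's response to one operation."""

    computation: Computation
    loss: float
    delay: float
    highlighted: frozenset[str] = frozenset()
    message_key: str = "none"
    message_args: tuple[str, ...] = ()
    move: str | None = None  # set for action feedback, which evaluates a move

    @property
    def message(self) -> str | None:
        if self.message_key == "none":
            return None
        text = MESSAGES[self.message_key]
        if self.message_key == "should_have_moved":
            return text.format(directions="/".join(self.message_args))
        return text

    def to_dict(self) -> dict:
        return {"computation": self.computation.node if self.computation.is_click else "terminate",
                "loss": self.loss, "delay": self.delay,
                "highlighted": sorted(self.highlighted),
                "message_key": self.message_key, "message_args": list(self.message_args)}


def calibrate_scaling(env: EnvConfig, q: MetaQ, cfg: FeedbackConfig) -> FeedbackConfig:
    """Set ``a`` so the delay for acting without planning hits the target.

    Acting without planning is terminating at the empty belief; its loss is
    V(∅) − Q(∅, ⊥), so a = (target − base) / loss makes base + a·loss equal
    the target exactly.
    """
    loss0 = compute_loss(q, Belief.empty(), TERMINATE)
    if loss0 <= LOSS_TOL:
        raise CalibrationError(
            "planning is worthless in this environment (terminating at the empty "
            "belief has zero loss); the delay scaling is undefined")
    a = (cfg.target_no_planning_delay - cfg.base_delay) / loss0
    return replace(cfg, scaling_a=a)


def metacognitive_feedback(q: MetaQ, belief: Belief, c: Computation,
                           cfg: FeedbackConfig) -> FeedbackEvent:
    """Feedback on one planning operation (click or terminate)."""
    if cfg.mode not in _META_MODES:
        raise ValueError(f"metacognitive_feedback requires a metacognitive mode, got {cfg.mode!r}")
    loss = compute_loss(q, belief, c)
    uncond = cfg.unconditional_click_delay if c.is_click else 0.0
    info = cfg.mode in _INFO_MODES

    if loss <= LOSS_TOL:
        return FeedbackEvent(computation=c, loss=loss, delay=uncond,
                             message_key="good_job" if info else "none")

    if cfg.mode == "metacognitive_info_only":
        # the illustration is shown for at least 1 s; no loss-proportional delay
        delay = max(uncond, 1.0)
    else:
        delay = uncond + cfg.base_delay + cfg._require_scaling() * loss

    highlighted: frozenset[str] = frozenset()
    message_key = "none"
    if info:
        best = optimal_computations(q, belief)
        best_clicks = {cc.node for cc in best if cc.is_click}
        if best_clicks:
            highlighted = frozenset(best_clicks)
            message_key = "should_have_inspected"
        elif c.is_click:
            message_key = "should_not_have_inspected"
    return FeedbackEvent(computation=c, loss=loss, delay=delay,
                         highlighted=highlighted, message_key=message_key)


def _direction_labels(env: EnvConfig) -> tuple[str, ...]:
    first_moves = sorted(env.graph.children[ROOT])
    defaults = {2: ("left", "right"), 3: ("left", "up", "right")}
    return defaults.get(len(first_moves),
                        tuple(f"direction {i}" for i in range(len(first_moves))))


def action_feedback(env: EnvConfig, truth: GroundTruth, first_move: str,
                    cfg: FeedbackConfig) -> FeedbackEvent:
    """Feedback on the first move only, under full-information task values.

    The loss is the gap between the best achievable path total overall and
    the best total among paths starting with the chosen move; the delay uses
    the same equation and scaling constant as the metacognitive tutor.
    """
    first_moves = sorted(env.graph.children[ROOT])
    if first_move not in first_moves:
        raise ValueError(f"{first_move!r} is not a child of the root")
    totals = {p: sum(truth[n] for n in p) for p in enumerate_paths(env.graph)}
    best_overall = max(totals.values())
    best_from = max(v for p, v in totals.items() if p[0] == first_move)
    task_loss = best_overall - best_from
    labels = cfg.direction_labels or _direction_labels(env)
    label_of = dict(zip(first_moves, labels))
    if task_loss <= LOSS_TOL:
        return FeedbackEvent(computation=TERMINATE, loss=0.0, delay=0.0,
                             message_key="good_job", move=first_move)
    optimal_moves = sorted({p[0] for p, v in totals.items() if v == best_overall})
    delay = cfg.base_delay + cfg._require_scaling() * task_loss
    return FeedbackEvent(computation=TERMINATE, loss=task_loss, delay=delay,
                         message_key="should_have_moved",
                         message_args=tuple(label_of[m] for m in optimal_moves),
                         move=first_move)


def feedback_for_mode(cfg: FeedbackConfig, *, q: MetaQ | None = None,
                      belief: Belief | None = None, c: Computation | None = None,
                      env: EnvConfig | None = None, truth: GroundTruth | None = None,
                      first_move: str | None = None) -> FeedbackEvent:
    """Dispatch to the feedback variant selected by ``cfg.mode``."""
    if cfg.mode in _META_MODES:
        if q is None or belief is None or c is None:
            raise ValueError("metacognitive modes need q, belief and c")
        return metacognitive_feedback(q, belief, c, cfg)
    if cfg.mode == "action":
        if env is None or truth is None or first_move is None:
            raise ValueError("action mode needs env, truth and first_move")
        return action_feedback(env, truth, first_move, cfg)
    if cfg.mode == "none":
        if c is None:
            raise ValueError("none mode needs the computation c")
        uncond = cfg.unconditional_click_delay if c.is_click else 0.0
        return FeedbackEvent(computation=c, loss=0.0, delay=uncond)
    raise ValueError(f"unknown feedback mode {cfg.mode!r}")


def annotate_trial(trial, cfg: FeedbackConfig, q: MetaQ | None = None,
                   env: EnvConfig | None = None,
                   truth: GroundTruth | None = None) -> list[FeedbackEvent]:
    """Replay a trial's computations through the tutor, returning one event
    per evaluated operation.  Raises on illegal traces (re-clicks etc.)."""
    events: list[FeedbackEvent] = []
    belief = Belief.empty()
    for c, value in trial.computations:
        if cfg.mode in _META_MODES or cfg.mode == "none":
            events.append(feedback_for_mode(cfg, q=q, belief=belief, c=c))
        if c.is_click:
            belief = update_belief(belief, c, value)
    if cfg.mode == "action":
        if env is None or truth is None:
            raise ValueError("action-mode replay needs env and truth")
        events.append(action_feedback(env, truth, trial.chosen_path[0], cfg))
    return events
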