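# Methods

## Task environments

An environment is a rooted tree whose non-root nodes each conceal a reward
drawn independently from a per-depth distribution; the agent may inspect
any node for a fixed fee before committing to a root-to-leaf path, and the
trial payoff is the realized path sum minus total inspection fees.  All
leaves sit at the same depth, node ids are stable strings `d{depth}_{index}`,
and configurations round-trip through a small JSON schema
(`EnvConfig.to_json` / `from_json`).

Presets (money units throughout):

| name | branching | rewards by depth | click cost |
|---|---|---|---|
| `training_3step` | [3, 1, 2] | uniform {−4,−2,+2,+4} / {−8,−4,+4,+8} / {−48,−24,+24,+48} | 1 |
| `training_3step_small` | [2, 1, 2] | same as above | 1 |
| `constant_3step` | [3, 1, 2] | uniform {−10,−5,+5,+10} at every depth | 1 |
| `transfer_5step` | [3, 1, 1, 1, 2] | Gaussian, mean 0, σ_i = 2^(i−1) for i ≤ 4, σ_5 = 2^5 | 3 |
| `toy2` | [2] | uniform {−1,+1} | 0.25 |

The increasing-variance structure of the three-step web is the substantive
choice: distal outcomes dominate proximal ones, so far-sighted (backward)
planning is what the optimal strategy must discover.  The exact tree
shapes are package choices — a [3,1,2] profile (12 reward nodes) keeps the
web multi-branched while remaining exactly solvable, and the [2,1,2]
variant preserves the qualitative structure at a size every test can
afford.  Both are configurable (`training_env(branching=...)`).
`toy2` exists because its solution is hand-derivable (see Tolerances).

Ground-truth draws are counter-based — node *i* uses the stream seeded by
`(seed, i)` — so a node's realized reward does not depend on enumeration
order.

## The metalevel MDP and its exact solution

Beliefs are partial observation maps; computations are one click per
unobserved node plus terminate.  (Re-clicking an observed node is excluded
from C: it pays the fee and changes nothing, so it is strictly dominated;
traces that contain it are rejected as illegal rather than scored.)
Termination pays the best expected path value under the current belief —
observed values where known, prior means elsewhere.  Backward induction is
well-founded because each click strictly increases the observation count.

Two exact backends implement the same recursion:

* **generic** — memoized depth-first recursion over *canonicalized*
  beliefs.  The canonical key sorts exchangeable sibling subtrees
  (identical topology; reward specs are depth-keyed, so same-shaped
  siblings always share specs); the value function is invariant under
  these permutations.
* **fast** — for trees whose root branches are structurally identical
  (all presets): a belief factorizes into one canonical *branch state* per
  branch, and branches are exchangeable, so a global state is a multiset
  of branch-state indices.  Multisets are ranked by the combinatorial
  number system (rank of sorted x_0 ≤ … ≤ x_{k−1} is Σ_i C(x_i + i, i+1)),
  making V a flat numpy array and child lookups pure arithmetic; the DP
  sweeps observation-count layers from fully observed down to the empty
  belief.  For `training_3step` this collapses 5^12 ≈ 2.4·10^8 raw beliefs
  to C(377, 3) = 8 859 500 canonical states and solves in roughly half a
  minute on one CPU.

`solve()` picks the fast backend when applicable, the generic one
otherwise.  A deliberately naive `brute_force_oracle` (plain recursion on
raw beliefs, own path enumeration, no canonicalization; capped at 8 reward
nodes) serves as an independent cross-check in the tests; the two
production backends are additionally checked against each other.

Q tables store V only; Q(b, c) is recovered from successor values, which
makes the invariant Q(b, ⊥) = termination value hold identically and keeps
the big table at one float per canonical state.  Generic-backend tables
serialize to JSON (canonical key → per-computation Q, with an environment
content hash); the fast table is held in memory.

Gaussian environments are refused by `solve()` — the belief space is
continuous and the backward-induction table undefined — and callers are
directed to the goal-setting approximation in the scoring module.

## Feedback

Every inferred operation is charged its regret, Eq. (loss) of the README.
Delay-bearing modes convert it to `base + a·loss` seconds (base 2 s);
`calibrate_scaling` sets `a = (target − base) / loss(∅, ⊥)` so that
terminating with zero observations — acting without planning — costs the
42-s target exactly.  Optimal operations (loss ≤ 1e−9) cost nothing and,
in info-bearing modes, earn "Good job!".  Info-bearing modes highlight the
argmax clicks and attach "You should have inspected one of the highlighted
nodes." (optimal set contains clicks) or "You shouldn't have inspected any
more nodes." (clicking when termination was optimal).  Terminating when
clicks were optimal needs no special case: it is scored by the same regret
through the ⊥ computation.

Component-ablation variants: *delay-only* keeps penalties but drops
highlighting and messages; *info-only* shows the highlighting for
`max(unconditional delay, 1 s)` with no loss-proportional penalty; *none*
emits only the unconditional per-click delay.  Where a variant combines an
unconditional click delay with a penalty, the two add — the penalty is an
*additional* delay.  Post-trial delays (11 s vs 1 s) and the 7-s minimum
planning time are carried in the configuration for session runners; the
library reports delays as numbers and never sleeps.

Action feedback evaluates only the first move, replacing metalevel values
with task-level ones under full information: the loss is the gap between
the best path total overall and the best total among paths opening with
the chosen move.  It reuses the same delay equation and the same scaling
constant `a` ("same equation, same constants"); whether an independent
calibration would be preferable is undecidable from the delay rule alone,
and reusing `a` keeps the two feedback types on one scale.  Direction
labels default to left/up/right (three first moves) or left/right (two),
assigned in node-id order, and are configurable since screen geometry is
not part of the model.

## Scoring

`relative_score` is Eq. (score) of the README.  The chance anchor s̄_rand
is computed in closed form as the mean over paths of prior-mean path sums
(0 for every symmetric preset); the optimal anchor is V(∅) where exact
solving is possible.  Otherwise the **goal-setting strategy** stands in:
check final-step nodes in a seeded random order (no order is privileged;
randomization averages out in evaluation) until one strictly exceeds the
threshold, then commit to a path through it, else commit to the best value
found.  "Strictly exceeds" matters: with support {−48,−24,+24,+48} a
threshold of 24 targets only +48.  Thresholds are optimized by common-
random-number Monte Carlo over the final-depth support values plus
midpoints (discrete) or 17 evenly spaced quantiles (Gaussian); ties go to
the smallest threshold.  The approximation is a lower bound on the
optimum, so relative scores remain conservative where it is used.

Per-trial relative scores are not clipped; averaging happens on the raw
scale, participant-first.  Confidence intervals are percentile bootstraps
(1 000 resamples over participant means, seeded).  Backward planning is
operationalized as the first click landing on a final-step node; zero-
click trials count as not backward.

After terminating, rollouts choose the path maximizing expected value
under the final belief (ties lexicographic) — the decision maker knows
only what was clicked, not the ground truth.  The random baseline instead
picks uniformly among all paths, which is what its closed-form anchor
assumes.

## Synthetic sessions

`simulate_participant` produces full sessions — 10 training trials with
feedback, 20 test trials without, matching the block structure the scoring
conventions assume — for four scripted strategies: `optimal` (greedy in
the solved table; terminate preferred at ties, then smallest node id, a
determinism-only rule that never affects feedback because feedback uses
the full argmax set), `backward_lapse` (optimal with a per-step lapse
probability of a uniformly random legal computation), `forward_satisficer`
(inspects step-1 nodes in order and stops at the first value ≥ its
threshold — a plausible myopic foil), and `non_planner` (zero clicks,
random path).  Scripts do not learn across trials: no learning model is
part of this package, so training-block feedback changes delays, never
behavior.  Consequently passing tests demonstrate that the tutor measures
and penalizes what it should, not that feedback would improve a human
learner.  All clicks precede the move, as the task interface enforces.

`make_fixture_suite` writes environment configs, a solved toy Q table and
session logs for 3 feedback conditions × 4 scripts on
`training_3step_small`, with a SHA-256 manifest; identical seeds reproduce
identical bytes.

## Tolerances, ties, degenerate inputs

* Double precision throughout; supports and costs are small rationals and
  error growth is bounded by tree depth.  Tie tolerance 1e−9 for argmax
  sets and zero-loss classification; solver cross-checks assert agreement
  below 1e−9, hand-derived constants below 1e−12.
* `toy2` closed form: Q(∅, click) = ½·E[max(X, 0)] − ¼ = ¼, V(∅) = ¼,
  loss(∅, ⊥) = ¼ — the frozen oracle for solver and calibration tests
  (calibrated a = 40/0.25 = 160 s per unit).
* Calibration requires loss(∅, ⊥) > 0; environments where planning is
  worthless (e.g. a single path) raise `CalibrationError`.
* Normalization requires s̄_opt > s̄_rand; degenerate anchors raise.
* Losses are clamped at 0 against roundoff; `V(b) ≥ Q(b, ⊥)` holds by
  construction.
* Beliefs with values outside a node's support are outside the solved
  state space and raise a coverage error rather than re-solving silently.

## Problem sizes used by the tests and the acceptance script

The shared expensive artifact is the exact `training_3step` solve
(8 859 500 states, ≈ half a minute).  Monte-Carlo checks use 10 000
rollouts where they gate a 3·SE comparison against an exact value, and
1 000–4 000 where they only exercise machinery.  The goal-setting
threshold search uses 10 000 common-random-number simulations per
candidate on the full environment.  These sizes make every stochastic
assertion's standard error small relative to the effect it checks.

## Known limitations

* Exact solving requires discrete supports and benefits from identical
  root branches; irregular trees fall back to the generic backend, which
  scales exponentially in nodes without inter-branch symmetry to exploit.
* Approximate solvers for large metalevel MDPs, models of human
  metacognitive *learning*, and inference on human data are out of scope.
* The goal-setting anchor is itself Monte Carlo; its seed and simulation
  count are part of any reported relative score in Gaussian environments.
* The five-step transfer topology, like the three-step one, is a
  configurable package default rather than a property of the model.
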