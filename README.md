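# cogtutor

Optimal planning-strategy discovery and metacognitive feedback for
click-based (Mouselab-MDP) planning tasks.

Many planning experiments externalize deliberation: every reward in a
rooted "web" of states is concealed, and the participant pays a small fee
per click to reveal one before committing to a root-to-leaf path.  The
click sequence is then a process trace of the planning strategy itself.
`cogtutor` is for researchers who build on this paradigm: it defines such
environments, derives the *optimal* planning strategy for them, turns
deviations from it into calibrated tutoring feedback, and scores behavior
on an interpretable scale — plus a synthetic-session generator so the whole
pipeline can be exercised and tested without human data.

## The model

Planning is treated as a **metalevel MDP** (B, C, T_meta, r_meta): states
are beliefs *b* (the set of observed node rewards), actions are
computations *c* — inspect an unobserved node, or terminate (⊥) and act —
and the reward trades click costs against decision quality.  The
state-action value function

    Q(b, click n) = −cost + Σ_v P(v) · V(b ∪ {n: v})
    Q(b, ⊥)       = max_path E[ path payoff | b ]
    V(b)          = max_c Q(b, c)

is computed **exactly by backward induction** over belief states.  The
optimal strategy is π*(b) = argmax_c Q(b, c), and the quality of any
observed operation is its regret

    loss(b, c) = max_c' Q(b, c') − Q(b, c).                         (loss)

The tutor converts regret into a **delay penalty** of `2 + a·loss(b, c)`
seconds (0 s for optimal operations), with *a* calibrated so that acting
without any planning costs exactly 42 s, and highlights the argmax clicks
with an instructional message.  Behavior is scored relative to chance and
optimality,

    relative_score(s) = 100 · (s − s̄_rand) / (s̄_opt − s̄_rand),     (score)

where s̄_opt is V(∅) when the environment is exactly solvable and otherwise
the Monte-Carlo performance of a threshold-optimized *goal-setting*
strategy (check final-step outcomes until one beats a threshold), and
s̄_rand is the expected payoff of a uniformly random path with no clicks.

The flagship preset is a three-step web whose reward variance grows with
depth (supports {−4,−2,+2,+4}, {−8,−4,+4,+8}, {−48,−24,+24,+48}, $1 per
click).  Its exact solution — 8 859 500 canonical belief states, solved in
under a minute via exchangeable-branch symmetry — shows that the optimal
strategy plans *backward*: every optimal first click inspects a potential
final destination, and uncovering the best possible reward (+48) ends
deliberation immediately.

## Worked example

```python
from cogtutor import (Belief, TERMINATE, FeedbackConfig, calibrate_scaling,
                      click, metacognitive_feedback, optimal_computations,
                      preset_env, solve)

env = preset_env("training_3step_small")   # reduced 2-branch three-step web
q = solve(env)
print(round(q.root_value, 4))              # 34.8677
print(sorted(c.node for c in optimal_computations(q, Belief.empty())))
#  ['d3_0', 'd3_1', 'd3_2', 'd3_3']        # all final-step nodes
print(optimal_computations(q, Belief({"d3_0": 48.0})))
#  {⊥}                                     # +48 found: stop planning

cfg = calibrate_scaling(env, q, FeedbackConfig())
ev = metacognitive_feedback(q, Belief.empty(), TERMINATE, cfg)
print(ev.delay)                            # 42.0  (acting without planning)
ev = metacognitive_feedback(q, Belief.empty(), click("d1_0"), cfg)
print(round(ev.delay, 2), sorted(ev.highlighted))
#  2.77 ['d3_0', 'd3_1', 'd3_2', 'd3_3']
print(ev.message)
#  You should have inspected one of the highlighted nodes.
```

`V(∅) = 34.8677` is the expected payoff of the best possible planning
strategy in this reduced environment (a non-planner expects 0).  The
penalized first click on an immediate node costs 2.77 s — its regret of
0.674 scaled by the calibrated factor on top of the 2-s base — while the
tutor highlights the final-step nodes an optimal planner would inspect.

The `examples/` directory holds one short script per capability
(strategy discovery, calibrated feedback, score normalization, a full
synthetic experiment); each prints the numbers it computes and what they
mean.  A thin CLI mirrors the library for shell use:
`tutor solve`, `tutor simulate`, `tutor feedback`, `tutor score`,
`tutor fixtures` (see `tutor --help`).

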