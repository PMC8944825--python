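"""Generate calibrated metacognitive feedback for planning operations.

Every operation c in belief b is charged its regret loss(b,c) =
max_c' Q(b,c') − Q(b,c), converted to a delay of 2 + a·loss seconds. The
scaling factor a is calibrated so that acting without any planning costs
exactly 42 s.
"""

from cogtutor import (
    Belief,
    FeedbackConfig,
    TERMINATE,
    calibrate_scaling,
    click,
    metacognitive_feedback,
    preset_env,
    solve,
)

env = preset_env("training_3step_small")
q = solve(env)
cfg = calibrate_scaling(env, q, FeedbackConfig())
print(f"calibrated scaling: a = {cfg.scaling_a:.3f} s per unit of loss")

cases = [
    (Belief.empty(), TERMINATE, "moving without planning at all"),
    (Belief.empty(), click("d1_0"), "first click on an immediate (step-1) node"),
    (Belief.empty(), click("d3_0"), "first click on a final-step node"),
    (Belief({"d3_0": 48.0}), click("d2_0"), "clicking on after uncovering +48"),
]
for belief, c, desc in cases:
    ev = metacognitive_feedback(q, belief, c, cfg)
    print(f"\n{desc}:")
    print(f"  loss {ev.loss:6.3f}  ->  delay {ev.delay:5.2f} s   message: {ev.message!r}")
    if ev.highlighted:
        print(f"  highlighted (what the optimal strategy would inspect): "
              f"{sorted(ev.highlighted)}")
print("\nOptimal operations cost nothing; the worst operation (not planning)")
print("costs the full 42 s, and everything in between scales with its regret.")
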