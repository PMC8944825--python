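"""Discover the optimal planning strategy for a three-step web.

Solves the metalevel MDP of a reduced three-step training environment
(2 branches, supports {−4,−2,+2,+4} / {−8,−4,+4,+8} / {−48,−24,+24,+48},
$1 per click) exactly by backward induction, then inspects the solution.
"""

from cogtutor import Belief, TERMINATE, optimal_computations, preset_env, solve

env = preset_env("training_3step_small")
q = solve(env)

print(f"environment: {env.name}, {env.graph.n_reward_nodes()} concealed rewards")
print(f"V(empty belief) = {q.root_value:.4f}")
print("  -> expected payoff of the best possible planning strategy,")
print("     net of click costs (a non-planner expects 0).")

best = optimal_computations(q, Belief.empty())
print(f"\noptimal first computations: {sorted(c.node for c in best)}")
print("  -> all are final-step nodes: the optimal strategy plans backward,")
print("     evaluating potential final destinations first.")

for v in (48.0, -48.0):
    b = Belief({"d3_0": v})
    opts = optimal_computations(q, b)
    label = "terminate and take that path" if opts == {TERMINATE} else \
        f"keep clicking {sorted(c.node for c in opts if c.is_click)}"
    print(f"\nafter observing {v:+.0f} on a final node: {label}")
print("  -> the best possible reward (+48) ends deliberation immediately;")
print("     a bad draw means the search continues elsewhere.")
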