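"""Score behavior on the chance-0 / optimal-100 scale.

The relative score maps a raw trial payoff s to
100·(s − s̄_rand)/(s̄_opt − s̄_rand).  In solvable environments s̄_opt is the
exact V(empty); in the five-step Gaussian transfer environment it is
approximated by the threshold-optimized goal-setting strategy.
"""

from cogtutor import (
    OptimalPolicy,
    evaluate_policy,
    preset_env,
    relative_score,
    score_norm,
    solve,
)

env = preset_env("training_3step_small")
q = solve(env)
norm = score_norm(env, q=q)
print(f"{env.name}: s_opt = {norm.s_opt:.4f} (exact), s_rand = {norm.s_rand:.1f} (closed form)")
print(f"relative_score(s_opt)  = {relative_score(norm.s_opt, norm):.1f}")
print(f"relative_score(s_rand) = {relative_score(norm.s_rand, norm):.1f}")

res = evaluate_policy(OptimalPolicy(q), env, n=3000, seed=0)
print(f"\n3000 optimal-policy rollouts: mean raw {res.mean:.3f} ± {res.se:.3f}"
      f"  ->  {relative_score(res.mean, norm):.1f} relative points")

transfer = preset_env("transfer_5step")
tnorm = score_norm(transfer, mode="goal_setting_approx", n_sim=2000, seed=1)
print(f"\n{transfer.name} (Gaussian rewards, too large to solve exactly):")
print(f"  goal-setting upper anchor s_opt ≈ {tnorm.s_opt:.2f}, "
      f"chance anchor s_rand ≈ {tnorm.s_rand:.2f}")
print("  -> the same 0-100 scale works where backward induction cannot.")
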