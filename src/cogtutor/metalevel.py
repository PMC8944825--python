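"""The metalevel MDP of planning and its exact solution.

Planning in a Mouselab-MDP environment is itself a sequential decision
problem: the *state* is the planner's belief (the set of node rewards
observed so far), the *actions* are computations — inspect one unobserved
node, or terminate deliberation and act — and the reward trades the click
fee against the expected payoff of the final path choice.  The state-action
value function

    Q(b, click n)  = −cost + Σ_v P(v) · V(b ∪ {n: v})
    Q(b, ⊥)        = max_path E[path payoff | b]
    V(b)           = max_c Q(b, c)

is computed exactly by backward induction over belief states (observation
count strictly increases, so the belief graph is a DAG).  The regret of a
computation, ``loss(b, c) = max_c' Q(b, c') − Q(b, c)``, is the quantity the
tutor's feedback is built from.

Two exact backends are provided: a generic memoized recursion over
canonicalized beliefs, and a fast vectorized layered DP for trees whose
root branches are structurally identical (see :mod:`cogtutor.fastsolve`).
A deliberately naive :func:`brute_force_oracle` exists for cross-checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Mapping

from .environments import (
    ROOT,
    EnvConfig,
    enumerate_paths,
    expected_path_value,
)

__all__ = [
    "Belief",
    "Computation",
    "TERMINATE",
    "click",
    "MetaQ",
    "CoverageError",
    "UnsupportedEnvironmentError",
    "legal_computations",
    "update_belief",
    "termination_value",
    "solve",
    "compute_loss",
    "optimal_computations",
    "canonicalize",
    "brute_force_oracle",
    "TIE_TOL",
]

TIE_TOL = 1e-9


class CoverageError(KeyError):
    """A belief was queried that the solved table does not cover."""


class UnsupportedEnvironmentError(ValueError):
    """Exact solution requested for an environment it cannot handle."""


class Belief(Mapping):
    """Immutable knowledge state: node id → observed reward value.

    Nodes absent from the mapping are unobserved and carry their prior.
    """

    __slots__ = ("_obs", "_hash")

    def __init__(self, observations: Mapping[str, float] | None = None):
        self._obs = dict(observations) if observations else {}
        self._hash: int | None = None

    @classmethod
    def empty(cls) -> "Belief":
        return cls()

    def observe(self, node: str, value: float) -> "Belief":
        """Return a new belief with one additional observation."""
        if node in self._obs:
            raise ValueError(f"node {node} is already observed")
        new = Belief.__new__(Belief)
        new._obs = {**self._obs, node: float(value)}
        new._hash = None
        return new

    def get(self, node: str, default=None):
        return self._obs.get(node, default)

    def __getitem__(self, node: str) -> float:
        return self._obs[node]

    def __iter__(self) -> Iterator[str]:
        return iter(self._obs)

    def __len__(self) -> int:
        return len(self._obs)

    def __contains__(self, node) -> bool:
        return node in self._obs

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(frozenset(self._obs.items()))
        return self._hash

    def __eq__(self, other) -> bool:
        return isinstance(other, Belief) and self._obs == other._obs

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}: {v:+g}" for n, v in sorted(self._obs.items()))
        return f"Belief({{{inner}}})"


@dataclass(frozen=True, order=True)
class Computation:
    """One planning operation: inspect a node, or terminate (⊥)."""

    kind: str  # "click" | "terminate"
    node: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "click" and self.node is None:
            raise ValueError("click computation needs a target node")
        if self.kind == "terminate" and self.node is not None:
            raise ValueError("terminate carries no node")
        if self.kind not in ("click", "terminate"):
            raise ValueError(f"unknown computation kind {self.kind!r}")

    @property
    def is_click(self) -> bool:
        return self.kind == "click"

    def __repr__(self) -> str:
        return f"click({self.node})" if self.is_click else "⊥"


TERMINATE = Computation(kind="terminate")


def click(node: str) -> Computation:
    return Computation(kind="click", node=node)


def legal_computations(env: EnvConfig, belief: Belief) -> set[Computation]:
    """One click per unobserved reward node, plus terminate."""
    comps = {click(n) for n in env.graph.reward_nodes() if n not in belief}
    comps.add(TERMINATE)
    return comps


def update_belief(belief: Belief, c: Computation, value: float) -> Belief:
    """Apply a click's observed outcome; the input belief is unchanged."""
    if not c.is_click:
        raise ValueError("only click computations update the belief")
    return belief.observe(c.node, value)


def termination_value(env: EnvConfig, belief: Belief) -> float:
    """Expected payoff of acting now: best path under observed values / prior means."""
    return max(expected_path_value(env, path, belief) for path in enumerate_paths(env.graph))


def canonicalize(env: EnvConfig, belief: Belief):
    """Canonical key identifying beliefs up to permutation of exchangeable subtrees.

    Sibling subtrees with identical topology (reward specs are depth-keyed,
    hence automatically identical for same-shaped siblings) may be swapped
    without changing the value function; the key sorts them recursively.
    """
    children = env.graph.children

    def key(node: str):
        sub = tuple(sorted(key(kid) for kid in children.get(node, ())))
        if node == ROOT:
            return sub
        v = belief.get(node)
        obs = (0,) if v is None else (1, v)  # sortable encoding of "unobserved"
        return (obs, sub)

    return key(ROOT)


# --------------------------------------------------------------------------
# Solved tables


class MetaQ:
    """Exactly solved metalevel state-action values for one environment.

    Stores V(b) for every belief reachable from the empty belief (i.e. all
    beliefs); Q(b, c) is recovered from V of the successor beliefs, so the
    invariant Q(b, ⊥) = termination value holds by construction.
    """

    def __init__(self, env: EnvConfig, backend):
        self.env = env
        self._backend = backend

    # -- core queries ------------------------------------------------------

    def value(self, belief: Belief) -> float:
        """V(b) = max_c Q(b, c)."""
        return self._backend.value_of(belief)

    def q(self, belief: Belief, c: Computation) -> float:
        if not c.is_click:
            return termination_value(self.env, belief)
        if c.node in belief:
            raise ValueError(f"click on already-observed node {c.node}")
        spec = self.env.spec_for(c.node)
        total = -self.env.click_cost
        for v, p in zip(spec.support, spec.probs):
            total += p * self._backend.value_of(belief.observe(c.node, v))
        return total

    @property
    def root_value(self) -> float:
        """V at the empty belief: expected payoff of the optimal planning strategy."""
        return self.value(Belief.empty())

    def loss(self, belief: Belief, c: Computation) -> float:
        return compute_loss(self, belief, c)

    def optimal_computations(self, belief: Belief) -> set[Computation]:
        return optimal_computations(self, belief)

    def greedy_computation(self, belief: Belief) -> Computation:
        """Deterministic optimal choice: terminate beats clicks at ties, then
        smallest node id — the full argmax set is unaffected by this rule."""
        best = self.optimal_computations(belief)
        if TERMINATE in best:
            return TERMINATE
        return min(best, key=lambda c: c.node)

    # -- serialization (generic backend only) ------------------------------

    def to_json(self, max_states: int = 200_000) -> str:
        states = getattr(self._backend, "stored_states", None)
        if states is None:
            raise UnsupportedEnvironmentError(
                "only generic-backend tables serialize to JSON; the fast array "
                "backend is held in memory")
        if len(states) > max_states:
            raise UnsupportedEnvironmentError(
                f"table too large to serialize ({len(states)} states)")
        values = {}
        for key, belief in states.items():
            qs = {"terminate": self.q(belief, TERMINATE)}
            for c in sorted(legal_computations(self.env, belief)):
                if c.is_click:
                    qs[f"click:{c.node}"] = self.q(belief, c)
            values[json.dumps(_jsonable(key))] = qs
        doc = {"env": self.env.name, "env_hash": self.env.content_hash(), "values": values}
        return json.dumps(doc)

    @classmethod
    def from_json(cls, env: EnvConfig, text: str) -> "MetaQ":
        doc = json.loads(text)
        if doc.get("env_hash") != env.content_hash():
            raise ValueError("Q-table does not match this environment configuration")
        table = {_unjsonable(json.loads(k)): max(qs.values())
                 for k, qs in doc["values"].items()}
        return cls(env, _KeyedBackend(env, table))


def _jsonable(key):
    if isinstance(key, tuple):
        return [_jsonable(k) for k in key]
    return key


def _unjsonable(key):
    if isinstance(key, list):
        return tuple(_unjsonable(k) for k in key)
    return key


class _KeyedBackend:
    """V(b) lookup through canonical belief keys (dict-backed)."""

    def __init__(self, env: EnvConfig, table: dict, reps: dict | None = None):
        self.env = env
        self._table = table
        # canonical key -> one representative Belief (for serialization)
        self.stored_states = reps

    def value_of(self, belief: Belief) -> float:
        key = canonicalize(self.env, belief)
        try:
            return self._table[key]
        except KeyError:
            raise CoverageError(
                f"belief {belief!r} is not covered by this solved table") from None


def compute_loss(q: MetaQ, belief: Belief, c: Computation) -> float:
    """Regret of computation ``c``: max_c' Q(b, c') − Q(b, c).  Nonnegative;
    zero exactly on the argmax set."""
    legal = legal_computations(q.env, belief)
    if c not in legal:
        raise ValueError(f"computation {c!r} is not legal in {belief!r}")
    best = max(q.q(belief, cc) for cc in legal)
    return max(0.0, best - q.q(belief, c))


def optimal_computations(q: MetaQ, belief: Belief) -> set[Computation]:
    """All computations within the tie tolerance of the max Q; never empty."""
    legal = legal_computations(q.env, belief)
    qs = {c: q.q(belief, c) for c in legal}
    best = max(qs.values())
    return {c for c, v in qs.items() if v >= best - TIE_TOL}


# --------------------------------------------------------------------------
# Solvers


def _check_discrete(env: EnvConfig) -> None:
    if not env.is_discrete:
        raise UnsupportedEnvironmentError(
            "exact backward induction needs discrete reward supports; Gaussian "
            "environments are handled by the goal-setting approximation "
            "(cogtutor.scoring.score_norm with mode='goal_setting_approx')")


def solve(env: EnvConfig, method: str = "auto") -> MetaQ:
    """Solve the metalevel MDP exactly by backward induction.

    ``method``: ``"fast"`` (vectorized layered DP; requires structurally
    identical root branches), ``"generic"`` (memoized recursion over
    canonical beliefs; any tree), or ``"auto"``.
    """
    _check_discrete(env)
    if method not in ("auto", "fast", "generic"):
        raise ValueError(f"unknown solve method {method!r}")
    if method in ("auto", "fast"):
        from . import fastsolve

        if fastsolve.branches_identical(env):
            return MetaQ(env, fastsolve.solve_fast(env))
        if method == "fast":
            raise UnsupportedEnvironmentError(
                "fast solver requires structurally identical root branches")
    return MetaQ(env, _solve_generic(env))


def _solve_generic(env: EnvConfig, canonical: bool = True) -> _KeyedBackend:
    """Depth-first backward induction with memoization over belief keys."""
    table: dict = {}
    reps: dict = {}
    cost = env.click_cost
    nodes = env.graph.reward_nodes()
    specs = {n: env.spec_for(n) for n in nodes}

    def value(belief: Belief) -> float:
        key = canonicalize(env, belief) if canonical else frozenset(belief.items())
        cached = table.get(key)
        if cached is not None:
            return cached
        best = termination_value(env, belief)
        for n in nodes:
            if n in belief:
                continue
            spec = specs[n]
            qc = -cost
            for v, p in zip(spec.support, spec.probs):
                qc += p * value(belief.observe(n, v))
            if qc > best:
                best = qc
        table[key] = best
        reps[key] = belief
        return best

    value(Belief.empty())
    return _KeyedBackend(env, table, reps)


def solve_generic_uncanonicalized(env: EnvConfig) -> MetaQ:
    """Generic solver with raw (frozenset) belief keys — no symmetry lumping.

    Exponentially slower than :func:`solve`; used to validate that
    canonicalization does not change the value function.
    """
    _check_discrete(env)
    backend = _solve_generic(env, canonical=False)

    class _RawBackend:
        stored_states = None

        def value_of(self, belief: Belief) -> float:
            try:
                return backend._table[frozenset(belief.items())]
            except KeyError:
                raise CoverageError(f"belief {belief!r} not covered") from None

    return MetaQ(env, _RawBackend())


def brute_force_oracle(env: EnvConfig, max_nodes: int = 8) -> MetaQ:
    """Independent oracle: plain recursion on raw beliefs, no canonicalization.

    Deliberately naive (its own path enumeration and recursion, sharing no
    code with :func:`solve`); refuses environments with more than
    ``max_nodes`` reward-bearing nodes.  Intended for tests only.
    """
    _check_discrete(env)
    nodes = sorted(n for n in env.graph.depth_of if n != ROOT)
    if len(nodes) > max_nodes:
        raise UnsupportedEnvironmentError(
            f"brute-force oracle limited to {max_nodes} reward nodes; env has {len(nodes)}")
    cost = env.click_cost
    support = {n: env.spec_for(n).support for n in nodes}
    probs = {n: env.spec_for(n).probs for n in nodes}
    means = {n: env.spec_for(n).mean for n in nodes}

    # own path enumeration by walking child links
    paths: list[tuple[str, ...]] = []
    stack = [(ROOT, ())]
    while stack:
        node, acc = stack.pop()
        kids = env.graph.children.get(node, ())
        if not kids:
            if node != ROOT:
                paths.append(acc)
            continue
        for kid in kids:
            stack.append((kid, acc + (kid,)))

    @lru_cache(maxsize=None)
    def best_path_value(obs: frozenset) -> float:
        d = dict(obs)
        return max(sum(d.get(n, means[n]) for n in path) for path in paths)

    @lru_cache(maxsize=None)
    def V(obs: frozenset) -> float:
        best = best_path_value(obs)
        observed = {n for n, _ in obs}
        for n in nodes:
            if n in observed:
                continue
            qc = -cost
            for v, p in zip(support[n], probs[n]):
                qc += p * V(obs | {(n, float(v))})
            best = max(best, qc)
        return best

    class _OracleBackend:
        stored_states = None

        def value_of(self, belief: Belief) -> float:
            return V(frozenset(belief.items()))

    return MetaQ(env, _OracleBackend())
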