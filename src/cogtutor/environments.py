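"""Mouselab-MDP task environments.

A task is a rooted tree ("web") whose non-root nodes each conceal a reward
drawn from a per-depth distribution.  The agent may pay a fixed fee to
inspect (click) any node before committing to a root-to-leaf path; the trial
payoff is the sum of realized rewards along the chosen path minus the total
inspection cost.  The presets reproduce the environments used to train and
test far-sighted planning: a three-step web whose reward variance grows with
depth, a variance-flat variant, and a five-step Gaussian transfer web.
"""

from __future__ import annotations

import functools
import hashlib
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RewardSpec",
    "TaskGraph",
    "EnvConfig",
    "GroundTruth",
    "preset_env",
    "training_env",
    "sample_ground_truth",
    "enumerate_paths",
    "trial_score",
    "PRESET_NAMES",
]

ROOT = "root"


class ConfigurationError(ValueError):
    """Raised for malformed or unknown environment configurations."""


@dataclass(frozen=True)
class RewardSpec:
    """Reward distribution attached to one tree depth.

    ``discrete`` holds an explicit support with probabilities; ``gaussian``
    holds a mean and standard deviation.  Values are in money units.
    """

    kind: str  # "discrete" | "gaussian"
    support: tuple[float, ...] = ()
    probs: tuple[float, ...] = ()
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "discrete":
            if not self.support:
                raise ConfigurationError("discrete RewardSpec needs a nonempty support")
            if len(self.probs) != len(self.support):
                raise ConfigurationError("support and probs length mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-12:
                raise ConfigurationError("probabilities must sum to 1")
            object.__setattr__(self, "mean", float(np.dot(self.support, self.probs)))
        elif self.kind == "gaussian":
            if not self.sd > 0:
                raise ConfigurationError("gaussian RewardSpec needs sd > 0")
        else:
            raise ConfigurationError(f"unknown RewardSpec kind {self.kind!r}")

    @classmethod
    def discrete(cls, support: Sequence[float], probs: Sequence[float] | None = None) -> "RewardSpec":
        support = tuple(float(v) for v in support)
        if probs is None:
            probs = (1.0 / len(support),) * len(support)
        return cls(kind="discrete", support=support, probs=tuple(float(p) for p in probs))

    @classmethod
    def gaussian(cls, mean: float, sd: float) -> "RewardSpec":
        return cls(kind="gaussian", mean=float(mean), sd=float(sd))

    @property
    def is_discrete(self) -> bool:
        return self.kind == "discrete"

    def variance(self) -> float:
        if self.kind == "gaussian":
            return self.sd**2
        s = np.asarray(self.support)
        p = np.asarray(self.probs)
        return float(np.dot(p, (s - self.mean) ** 2))


@dataclass(frozen=True, eq=False)
class TaskGraph:
    """Rooted tree of task states.

    Reward-bearing nodes have depth >= 1 and stable ids ``d{depth}_{index}``;
    the root (id ``root``, depth 0) carries no reward and cannot be clicked.
    All leaves share the same depth.
    """

    depth_of: Mapping[str, int]
    children: Mapping[str, tuple[str, ...]]
    branching: tuple[int, ...]

    def __post_init__(self) -> None:
        parents: dict[str, str] = {}
        for parent, kids in self.children.items():
            for kid in kids:
                if kid in parents:
                    raise ConfigurationError(f"node {kid} has two parents")
                parents[kid] = parent
        for node in self.depth_of:
            if node != ROOT and node not in parents:
                raise ConfigurationError(f"node {node} unreachable from root")
        leaf_depths = {self.depth_of[n] for n in self.leaves()}
        if len(leaf_depths) != 1:
            raise ConfigurationError("all leaves must share the same depth")

    @classmethod
    def from_branching(cls, branching: Sequence[int]) -> "TaskGraph":
        """Build the tree whose depth-d nodes each have ``branching[d]`` children."""
        branching = tuple(int(b) for b in branching)
        if not branching or any(b < 1 for b in branching):
            raise ConfigurationError("branching profile must be positive integers")
        depth_of = {ROOT: 0}
        children: dict[str, tuple[str, ...]] = {}
        frontier = [ROOT]
        counter = 0
        for depth, width in enumerate(branching, start=1):
            counter = 0
            nxt: list[str] = []
            for parent in frontier:
                kids = []
                for _ in range(width):
                    node = f"d{depth}_{counter}"
                    counter += 1
                    depth_of[node] = depth
                    kids.append(node)
                children[parent] = tuple(kids)
                nxt.extend(kids)
            frontier = nxt
        for leaf in frontier:
            children[leaf] = ()
        return cls(depth_of=depth_of, children=children, branching=branching)

    @property
    def max_depth(self) -> int:
        return max(self.depth_of.values())

    def reward_nodes(self) -> list[str]:
        return sorted((n for n in self.depth_of if n != ROOT), key=_node_key)

    def leaves(self) -> list[str]:
        return sorted((n for n, kids in self.children.items() if not kids and n != ROOT), key=_node_key)

    def n_reward_nodes(self) -> int:
        return len(self.depth_of) - 1


def _node_key(node: str) -> tuple[int, int]:
    # "d3_11" -> (3, 11); keeps ordering numeric rather than lexicographic.
    d, i = node[1:].split("_")
    return int(d), int(i)


@dataclass(frozen=True, eq=False)
class EnvConfig:
    """A fully specified planning environment."""

    graph: TaskGraph
    reward_by_depth: Mapping[int, RewardSpec]
    click_cost: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.click_cost < 0:
            raise ConfigurationError("click_cost must be >= 0")
        for depth in range(1, self.graph.max_depth + 1):
            if depth not in self.reward_by_depth:
                raise ConfigurationError(f"no RewardSpec for depth {depth}")

    def spec_for(self, node: str) -> RewardSpec:
        return self.reward_by_depth[self.graph.depth_of[node]]

    @property
    def is_discrete(self) -> bool:
        return all(s.is_discrete for s in self.reward_by_depth.values())

    def to_json(self) -> str:
        rewards = []
        for depth in sorted(self.reward_by_depth):
            spec = self.reward_by_depth[depth]
            if spec.is_discrete:
                rewards.append({"depth": depth, "kind": "discrete",
                                "support": list(spec.support), "probs": list(spec.probs)})
            else:
                rewards.append({"depth": depth, "kind": "gaussian",
                                "mean": spec.mean, "sd": spec.sd})
        doc = {"name": self.name, "branching": list(self.graph.branching),
               "rewards": rewards, "click_cost": self.click_cost}
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EnvConfig":
        doc = json.loads(text)
        for key in ("name", "branching", "rewards", "click_cost"):
            if key not in doc:
                raise ConfigurationError(f"environment config missing field {key!r}")
        specs: dict[int, RewardSpec] = {}
        for entry in doc["rewards"]:
            if entry["kind"] == "discrete":
                specs[int(entry["depth"])] = RewardSpec.discrete(entry["support"], entry.get("probs"))
            elif entry["kind"] == "gaussian":
                specs[int(entry["depth"])] = RewardSpec.gaussian(entry["mean"], entry["sd"])
            else:
                raise ConfigurationError(f"unknown reward kind {entry['kind']!r}")
        return cls(graph=TaskGraph.from_branching(doc["branching"]),
                   reward_by_depth=specs, click_cost=float(doc["click_cost"]),
                   name=str(doc["name"]))

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class GroundTruth:
    """One realization of every concealed reward."""

    rewards: Mapping[str, float]

    def __getitem__(self, node: str) -> float:
        return self.rewards[node]


_TRAINING_SUPPORTS = {1: (-4, -2, 2, 4), 2: (-8, -4, 4, 8), 3: (-48, -24, 24, 48)}


def training_env(branching: Sequence[int] = (3, 1, 2), name: str | None = None) -> EnvConfig:
    """Three-step increasing-variance web with $1 click cost.

    The per-step supports are {−4,−2,+2,+4}, {−8,−4,+4,+8}, {−48,−24,+24,+48};
    ``branching`` reshapes the tree (e.g. ``[2,1,2]`` for a reduced variant
    with identical reward structure).
    """
    if len(branching) != 3:
        raise ConfigurationError("training environments are three-step")
    return EnvConfig(
        graph=TaskGraph.from_branching(branching),
        reward_by_depth={d: RewardSpec.discrete(s) for d, s in _TRAINING_SUPPORTS.items()},
        click_cost=1.0,
        name=name or ("training_3step" if tuple(branching) == (3, 1, 2) else f"training_{'-'.join(map(str, branching))}"),
    )


def _preset_training_small() -> EnvConfig:
    return training_env((2, 1, 2), name="training_3step_small")


def _preset_constant() -> EnvConfig:
    spec = RewardSpec.discrete((-10, -5, 5, 10))
    return EnvConfig(graph=TaskGraph.from_branching((3, 1, 2)),
                     reward_by_depth={1: spec, 2: spec, 3: spec},
                     click_cost=1.0, name="constant_3step")


def _preset_transfer() -> EnvConfig:
    specs = {i: RewardSpec.gaussian(0.0, 2.0 ** (i - 1)) for i in range(1, 5)}
    specs[5] = RewardSpec.gaussian(0.0, 2.0**5)
    return EnvConfig(graph=TaskGraph.from_branching((3, 1, 1, 1, 2)),
                     reward_by_depth=specs, click_cost=3.0, name="transfer_5step")


def _preset_toy2() -> EnvConfig:
    return EnvConfig(graph=TaskGraph.from_branching((2,)),
                     reward_by_depth={1: RewardSpec.discrete((-1, 1))},
                     click_cost=0.25, name="toy2")


_PRESETS = {
    "training_3step": training_env,
    "training_3step_small": _preset_training_small,
    "constant_3step": _preset_constant,
    "transfer_5step": _preset_transfer,
    "toy2": _preset_toy2,
}

PRESET_NAMES = tuple(_PRESETS)


def preset_env(name: str) -> EnvConfig:
    """Return a named preset environment (see :data:`PRESET_NAMES`)."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None


def sample_ground_truth(env: EnvConfig, seed: int) -> GroundTruth:
    """Draw one independent reward per node from its depth's distribution.

    Draws are counter-based: node ``i`` uses the stream seeded by
    ``(seed, i)``, so each node's value is independent of enumeration order.
    """
    rewards: dict[str, float] = {}
    for idx, node in enumerate(env.graph.reward_nodes()):
        spec = env.spec_for(node)
        rng = np.random.default_rng((int(seed), idx))
        if spec.is_discrete:
            rewards[node] = float(rng.choice(spec.support, p=spec.probs))
        else:
            rewards[node] = float(rng.normal(spec.mean, spec.sd))
    return GroundTruth(rewards=rewards)


@functools.lru_cache(maxsize=64)
def enumerate_paths(graph: TaskGraph) -> list[tuple[str, ...]]:
    """All root-to-leaf move sequences (reward nodes only), in node-id order."""
    paths: list[tuple[str, ...]] = []

    def walk(node: str, acc: list[str]) -> None:
        kids = graph.children.get(node, ())
        if not kids:
            paths.append(tuple(acc))
            return
        for kid in sorted(kids, key=_node_key):
            acc.append(kid)
            walk(kid, acc)
            acc.pop()

    walk(ROOT, [])
    return paths


def trial_score(env: EnvConfig, truth: GroundTruth, path: Sequence[str], n_clicks: int) -> float:
    """Realized payoff: path reward sum minus click fees."""
    if n_clicks < 0:
        raise ValueError("n_clicks must be >= 0")
    if tuple(path) not in set(enumerate_paths(env.graph)):
        raise ValueError(f"path {tuple(path)} is not a root-to-leaf path of this graph")
    return float(sum(truth[node] for node in path) - env.click_cost * n_clicks)


def expected_path_value(env: EnvConfig, path: Iterable[str],
                        observations: Mapping[str, float] | None = None) -> float:
    """Expected sum along ``path``: observed values where known, prior means elsewhere."""
    obs = observations or {}
    total = 0.0
    for node in path:
        total += obs[node] if node in obs else env.spec_for(node).mean
    return total
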