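"""Seasons Optimization (SO): a population metaheuristic over box-bounded reals.

The population (a *forest*) of candidate vectors (*trees*) is updated each
generation by four seasonal operators — renew (spring), competition (summer),
seeding (autumn) and resistance (winter) — under a fixed budget of strength
(fitness) evaluations.  The optimizer MAXIMIZES: callers minimizing an error
supply ``strength = -error``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Bounds",
    "SOConfig",
    "CandidateTree",
    "Forest",
    "BudgetExhausted",
    "init_forest",
    "normalized_strength",
    "renew_phase",
    "competition_phase",
    "competition_index",
    "seeding_phase",
    "resistance_phase",
    "optimize",
    "load_so_config",
]

#: Floor applied to pairwise distances before the inverse-square crowding term.
DISTANCE_FLOOR = 1e-12


class BudgetExhausted(RuntimeError):
    """Raised internally when the strength-evaluation budget is spent."""


@dataclass(frozen=True)
class Bounds:
    """Box constraints ``lower[j] <= x[j] <= upper[j]``."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or upper.shape != lower.shape:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if np.any(lower > upper):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass(frozen=True)
class SOConfig:
    """Operator rates and budget for one SO run.

    ``resistance_rate`` defaults to ``seeding_rate`` (the printed winter rate
    reduces algebraically to the seeding rate) but may be overridden.
    ``growth_scale`` sets the sd of the competition growth step as a fraction
    of each variable's range.  ``literal_growth`` switches the competition
    update to the origin-dependent literal form (whole position divided by
    the crowding factor) instead of damping only the increment.
    """

    population_size: int = 50
    fe_budget: int = 3000
    renew_rate: float = 0.4
    competition_rate: float = 0.3
    seeding_rate: float = 0.3
    resistance_rate: float | None = None
    asymmetry_index: float = 0.5
    growth_scale: float = 0.01
    literal_growth: bool = False
    rng_seed: int | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.fe_budget < self.population_size:
            raise ValueError("fe_budget must cover at least initialization")
        if not (0.0 <= self.renew_rate <= 1.0):
            raise ValueError("renew_rate must lie in [0, 1]")
        if not (0.0 < self.competition_rate <= 1.0):
            raise ValueError("competition_rate must lie in (0, 1]")
        if not (0.0 <= self.seeding_rate <= 1.0):
            raise ValueError("seeding_rate must lie in [0, 1]")
        if self.resistance_rate is not None and not (0.0 <= self.resistance_rate <= 1.0):
            raise ValueError("resistance_rate must lie in [0, 1]")
        if not (0.0 <= self.asymmetry_index <= 1.0):
            raise ValueError("asymmetry_index must lie in [0, 1]")
        if self.growth_scale <= 0:
            raise ValueError("growth_scale must be positive")

    @property
    def effective_resistance_rate(self) -> float:
        return self.seeding_rate if self.resistance_rate is None else self.resistance_rate

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SOConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown SOConfig fields: {sorted(unknown)}")
        return cls(**dict(mapping))


def load_so_config(path) -> SOConfig:
    """Read an :class:`SOConfig` from a YAML or JSON mapping file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping of SOConfig fields")
    return SOConfig.from_mapping(data)


@dataclass
class CandidateTree:
    """One candidate solution: a position vector and its strength."""

    position: np.ndarray
    strength: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)

    @property
    def evaluated(self) -> bool:
        return self.strength is not None

    def copy(self) -> "CandidateTree":
        return CandidateTree(self.position.copy(), self.strength)


@dataclass
class Forest:
    """The SO population plus cross-generation bookkeeping."""

    trees: list[CandidateTree]
    seed_count: int = 0
    generation: int = 0
    best_so_far: CandidateTree | None = None
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    fe_used: int = 0

    def __len__(self) -> int:
        return len(self.trees)

    def strengths(self) -> np.ndarray:
        if any(not t.evaluated for t in self.trees):
            raise ValueError("forest contains unevaluated trees")
        return np.array([t.strength for t in self.trees], dtype=float)

    def best(self) -> CandidateTree:
        return max(self.trees, key=lambda t: t.strength)

    def _update_best(self) -> None:
        cur = self.best()
        if self.best_so_far is None or cur.strength > self.best_so_far.strength:
            self.best_so_far = cur.copy()


def _evaluate(forest: Forest, tree: CandidateTree, strength_fn: Callable) -> None:
    """Evaluate a tree's strength, counting one FE; non-finite -> -inf + warning."""
    s = float(strength_fn(tree.position))
    forest.fe_used += 1
    if not math.isfinite(s):
        warnings.warn("strength function returned a non-finite value; "
                      "candidate assigned worst-possible strength")
        s = -math.inf
    tree.strength = s


def init_forest(bounds: Bounds, config: SOConfig, strength_fn: Callable,
                seeds: Sequence[np.ndarray] = ()) -> Forest:
    """Uniform-random initial forest of N evaluated trees.

    ``seeds`` optionally replaces the first trees with caller-supplied
    positions (clipped to bounds) so a deterministic warm start can be
    injected into the population.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, d = config.population_size, bounds.dim
    positions = bounds.lower + rng.random((n, d)) * bounds.span
    for i, seed_pos in enumerate(seeds):
        if i >= n:
            break
        positions[i] = bounds.clip(np.asarray(seed_pos, dtype=float))
    forest = Forest(trees=[CandidateTree(p) for p in positions], rng=rng)
    for tree in forest.trees:
        _evaluate(forest, tree, strength_fn)
    forest._update_best()
    return forest


def normalized_strength(forest: Forest) -> np.ndarray:
    """Minimum-shifted strength over the raw strength sum (as printed).

    tau_i = (S_i - min_k S_k) / sum_k S_k; all zeros when the denominator
    vanishes.  Note the denominator is the *unshifted* sum, so tau is
    scale-dependent and may be negative for negative strengths.
    """
    if len(forest) == 0:
        raise ValueError("empty forest")
    s = forest.strengths()
    denom = s.sum()
    if denom == 0.0 or not np.isfinite(denom):
        return np.zeros_like(s)
    with np.errstate(invalid="ignore"):
        tau = (s - s.min()) / denom
    tau[~np.isfinite(tau)] = 0.0
    return tau


def renew_phase(forest: Forest, bounds: Bounds, config: SOConfig,
                strength_fn: Callable) -> Forest:
    """Spring: add ceil(p_r * A) uniform-random seedlings (skipped at y=0)."""
    if forest.generation == 0:
        return forest
    n_new = math.ceil(config.renew_rate * forest.seed_count)
    for _ in range(n_new):
        pos = bounds.lower + forest.rng.random(bounds.dim) * bounds.span
        tree = CandidateTree(pos)
        forest.trees.append(tree)
        _check_budget(forest, config)
        _evaluate(forest, tree, strength_fn)
    forest._update_best()
    return forest


def competition_index(position: np.ndarray, strength_j: float,
                      neighbor_positions: np.ndarray,
                      neighbor_strengths: np.ndarray,
                      asymmetry_index: float) -> float:
    """Crowding term Lambda_j = sum_k S_k * Delta_{j,k}^{-2} * lambda_{j,k}.

    Delta is the Euclidean distance to neighbor k (floored at
    ``DISTANCE_FLOOR``); lambda is 1 when the neighbor is at least as strong,
    else 1 - gamma.
    """
    if len(neighbor_positions) == 0:
        return 0.0
    deltas = np.linalg.norm(np.asarray(neighbor_positions, float) - position, axis=1)
    deltas = np.maximum(deltas, DISTANCE_FLOOR)
    lam = np.where(np.asarray(neighbor_strengths, float) >= strength_j,
                   1.0, 1.0 - asymmetry_index)
    return float(np.sum(neighbor_strengths * deltas ** -2 * lam))


def competition_phase(forest: Forest, bounds: Bounds, config: SOConfig,
                      strength_fn: Callable) -> Forest:
    """Summer: cored (strongest) trees perturb their nearest neighbors.

    The N_c strongest trees are cored.  Each cored tree i recruits
    Z_i = ceil(tau_i * (n - N_c)) nearest non-cored neighbors; every neighbor
    takes a Gaussian growth step damped by the crowding index of its zone and
    is re-evaluated; finally the cored tree is replaced by its strongest
    neighbor whenever that neighbor is at least as strong.
    """
    n = len(forest)
    tau = normalized_strength(forest)
    order = np.argsort(-forest.strengths(), kind="stable")
    n_c = min(math.ceil(config.competition_rate * n), n)
    cored_idx = order[:n_c]
    free_idx = order[n_c:]
    n_g = n - n_c
    sd = config.growth_scale * bounds.span

    for i in cored_idx:
        cored = forest.trees[i]
        z_i = math.ceil(tau[i] * n_g)
        z_i = max(0, min(z_i, len(free_idx)))
        if z_i == 0:
            continue
        dists = np.array([np.linalg.norm(forest.trees[j].position - cored.position)
                          for j in free_idx])
        nearest = free_idx[np.argsort(dists, kind="stable")[:z_i]]
        zone = [forest.trees[j] for j in nearest]
        for j, neighbor in zip(nearest, zone):
            others = [t for t in zone if t is not neighbor] + [cored]
            lam = competition_index(
                neighbor.position, neighbor.strength,
                np.array([t.position for t in others]),
                np.array([t.strength for t in others]),
                config.asymmetry_index)
            theta = forest.rng.normal(0.0, sd)
            if config.literal_growth:
                new_pos = bounds.clip((neighbor.position + theta) / (lam + 1.0))
            else:
                new_pos = bounds.clip(neighbor.position + theta / (lam + 1.0))
            _check_budget(forest, config)
            moved = CandidateTree(new_pos)
            _evaluate(forest, moved, strength_fn)
            neighbor.position = moved.position
            neighbor.strength = moved.strength
        star = max(zone, key=lambda t: t.strength)
        if cored.strength <= star.strength:
            cored.position = star.position.copy()
            cored.strength = star.strength
    forest._update_best()
    return forest


def seeding_phase(forest: Forest, bounds: Bounds, config: SOConfig,
                  strength_fn: Callable) -> Forest:
    """Autumn: the fittest trees each spawn one mutated copy.

    ceil(p_s * N) fittest trees are selected; each copy has m (uniform in
    1..D-1, or 1 when D == 1) components shifted by +-r with r uniform in
    the component's bounds, clipped, evaluated and appended.  The number of
    copies becomes the seed stock consumed by next spring's renew.
    """
    n_seed = math.ceil(config.seeding_rate * config.population_size)
    n_seed = min(n_seed, len(forest))
    produced = 0
    if n_seed > 0:
        order = np.argsort(-forest.strengths(), kind="stable")[:n_seed]
        d = bounds.dim
        for i in order:
            pos = forest.trees[i].position.copy()
            m = 1 if d == 1 else int(forest.rng.integers(1, d))
            comps = forest.rng.choice(d, size=m, replace=False)
            for j in comps:
                sign = 1.0 if forest.rng.random() < 0.5 else -1.0
                r = forest.rng.uniform(bounds.lower[j], bounds.upper[j])
                pos[j] += sign * r
            tree = CandidateTree(bounds.clip(pos))
            forest.trees.append(tree)
            _check_budget(forest, config)
            _evaluate(forest, tree, strength_fn)
            produced += 1
    forest.seed_count = produced
    forest._update_best()
    return forest


def resistance_phase(forest: Forest, config: SOConfig) -> Forest:
    """Winter: cull the weakest trees and trim back to capacity N.

    Removes ceil(p_w * N) weakest (never emptying the forest), then keeps
    the N strongest, and advances the generation counter.  Costs no FEs.
    """
    n_cap = config.population_size
    n_remove = math.ceil(config.effective_resistance_rate * n_cap)
    order = list(np.argsort(-forest.strengths(), kind="stable"))
    keep = order[:max(1, len(forest) - n_remove)]
    keep = keep[:n_cap]
    forest.trees = [forest.trees[i] for i in keep]
    forest.generation += 1
    forest._update_best()
    return forest


def _check_budget(forest: Forest, config: SOConfig) -> None:
    if forest.fe_used >= config.fe_budget:
        raise BudgetExhausted


def optimize(strength_fn: Callable, bounds: Bounds, config: SOConfig,
             seeds: Sequence[np.ndarray] = ()) -> tuple[CandidateTree, pd.DataFrame]:
    """Run SO to exhaustion of the FE budget; return best tree and trace.

    The trace has one row per completed stage (initialization, then each
    full seasonal cycle) with columns ``generation``, ``best_strength`` and
    ``fe_used``.  Fully reproducible for a fixed ``config.rng_seed``.
    """
    forest = init_forest(bounds, config, strength_fn, seeds=seeds)
    rows = [(0, forest.best_so_far.strength, forest.fe_used)]
    while forest.fe_used < config.fe_budget:
        exhausted = False
        try:
            renew_phase(forest, bounds, config, strength_fn)
            competition_phase(forest, bounds, config, strength_fn)
            seeding_phase(forest, bounds, config, strength_fn)
        except BudgetExhausted:
            forest.trees = [t for t in forest.trees if t.evaluated]
            exhausted = True
        resistance_phase(forest, config)
        rows.append((forest.generation, forest.best_so_far.strength, forest.fe_used))
        if exhausted:
            break
    trace = pd.DataFrame(rows, columns=["generation", "best_strength", "fe_used"])
    return forest.best_so_far.copy(), trace
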