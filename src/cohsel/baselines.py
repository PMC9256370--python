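"""GA and binary-PSO baselines for wrapper feature selection.

Both optimize the same fitness as the ant colony (accuracy + size term)
through the same evaluator interface, so results are directly
comparable. The GA follows the reference settings: binary chromosomes,
two-point crossover applied with probability 0.8, per-chromosome
mutation probability 0.2 (one uniformly chosen bit flipped), tournament
selection of size 2, one elite. The PSO is the standard binary variant:
real velocities, sigmoid transfer, inertia decayed 0.9 -> 0.4,
c1 = c2 = 2, velocities clamped to +/-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colony import AntSolution, Evaluator, FitnessConfig, SearchResult, fitness

__all__ = ["GAConfig", "PSOConfig", "ga_select", "pso_select"]


@dataclass
class GAConfig:
    pop_size: int = 20
    n_gen: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    tournament_size: int = 2
    elitism: int = 1
    fitness_mode: str = "fitness"   # "fitness" (accuracy + size term) or "accuracy"
    patience_stop: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2")


@dataclass
class PSOConfig:
    swarm_size: int = 20
    n_iter: int = 50
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_clamp: float = 4.0
    fitness_mode: str = "fitness"
    patience_stop: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm size must be >= 2")


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All-zero subsets are illegal; set one random bit."""
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


class _Scorer:
    """Shared evaluate-and-cache logic for both baselines."""

    def __init__(self, X, y, fc: FitnessConfig, mode: str, evaluator: Evaluator):
        self.X, self.y, self.fc, self.mode = X, y, fc, mode
        self.evaluator = evaluator
        self.cache: dict[bytes, float] = {}
        self.evaluations = 0

    def __call__(self, mask: np.ndarray) -> AntSolution:
        key = mask.tobytes()
        if key in self.cache:
            acc = self.cache[key]
        else:
            acc = float(self.evaluator(mask, self.X, self.y))
            self.cache[key] = acc
            self.evaluations += 1
        sol = AntSolution.from_mask(mask, acc, self.fc)
        if self.mode == "accuracy":
            sol.fitness = acc
        return sol


def _record(history, t, best, pop_fit):
    history.append({
        "iteration": t,
        "best_fitness": best.fitness,
        "iter_best_fitness": float(np.max(pop_fit)),
        "mean_fitness": float(np.mean(pop_fit)),
    })


def ga_select(
    X: np.ndarray, y, config: GAConfig, fc: FitnessConfig, evaluator: Evaluator
) -> SearchResult:
    X = np.asarray(X, float)
    y = np.asarray(y)
    rng = np.random.default_rng(config.seed)
    n = X.shape[1]
    score = _Scorer(X, y, fc, config.fitness_mode, evaluator)
    pop = [
        _repair(rng.random(n) < 0.5, rng) for _ in range(config.pop_size)
    ]
    sols = [score(m) for m in pop]
    best = max(sols, key=lambda s: s.fitness)
    history: list[dict] = []
    stagnation = 0
    _record(history, 0, best, [s.fitness for s in sols])
    for t in range(1, config.n_gen):
        ranked = sorted(sols, key=lambda s: s.fitness, reverse=True)
        nxt: list[np.ndarray] = [ranked[i].subset.copy()
                                 for i in range(config.elitism)]
        while len(nxt) < config.pop_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(len(sols), size=config.tournament_size)
                winner = max(contenders, key=lambda i: sols[i].fitness)
                parents.append(sols[winner].subset.copy())
            a, b = parents
            if rng.random() < config.crossover_prob and n > 2:
                i, j = np.sort(rng.choice(n, size=2, replace=False))
                a[i:j], b[i:j] = b[i:j].copy(), a[i:j].copy()
            for child in (a, b):
                if rng.random() < config.mutation_prob:
                    flip = rng.integers(n)
                    child[flip] = ~child[flip]
                nxt.append(_repair(child, rng))
        pop = nxt[: config.pop_size]
        sols = [score(m) for m in pop]
        gen_best = max(sols, key=lambda s: s.fitness)
        if gen_best.fitness > best.fitness + 1e-12:
            best = gen_best
            stagnation = 0
        else:
            stagnation += 1
        _record(history, t, best, [s.fitness for s in sols])
        if stagnation >= config.patience_stop:
            break
    return SearchResult(best, history, score.evaluations, method="ga")


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def pso_select(
    X: np.ndarray, y, config: PSOConfig, fc: FitnessConfig, evaluator: Evaluator
) -> SearchResult:
    X = np.asarray(X, float)
    y = np.asarray(y)
    rng = np.random.default_rng(config.seed)
    n = X.shape[1]
    score = _Scorer(X, y, fc, config.fitness_mode, evaluator)
    vel = rng.uniform(-1, 1, size=(config.swarm_size, n))
    pos = np.stack([_repair(rng.random(n) < 0.5, rng)
                    for _ in range(config.swarm_size)])
    sols = [score(pos[i]) for i in range(config.swarm_size)]
    pbest = [s for s in sols]
    best = max(sols, key=lambda s: s.fitness)
    history: list[dict] = []
    stagnation = 0
    _record(history, 0, best, [s.fitness for s in sols])
    for t in range(1, config.n_iter):
        frac = t / (config.n_iter - 1) if config.n_iter > 1 else 0.0
        w = config.inertia_start + frac * (config.inertia_end - config.inertia_start)
        r1 = rng.random((config.swarm_size, n))
        r2 = rng.random((config.swarm_size, n))
        pb = np.stack([p.subset for p in pbest]).astype(float)
        gb = best.subset.astype(float)
        vel = (w * vel
               + config.c1 * r1 * (pb - pos.astype(float))
               + config.c2 * r2 * (gb[None, :] - pos.astype(float)))
        vel = np.clip(vel, -config.v_clamp, config.v_clamp)
        pos = rng.random((config.swarm_size, n)) < _sigmoid(vel)
        sols = []
        for i in range(config.swarm_size):
            pos[i] = _repair(pos[i], rng)
            s = score(pos[i])
            sols.append(s)
            if s.fitness > pbest[i].fitness:
                pbest[i] = s
        iter_best = max(sols, key=lambda s: s.fitness)
        if iter_best.fitness > best.fitness + 1e-12:
            best = iter_best
            stagnation = 0
        else:
            stagnation += 1
        _record(history, t, best, [s.fitness for s in sols])
        if stagnation >= config.patience_stop:
            break
    return SearchResult(best, history, score.evaluations, method="pso")
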