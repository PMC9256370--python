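"""Ant-colony wrapper feature selection (standard ACO and improved IACO).

Ants build feature subsets by sequential roulette selection with
probability P(j) ∝ tau_j^sigma * eta_j^v over the not-yet-chosen
features, where tau is the learned pheromone level and eta a per-feature
Fisher-discriminant heuristic. Each subset is scored by a wrapper
evaluator (a classifier trained on the candidate subset) and turned into
a fitness

    f(A) = m * J(A) + n / |A|

that rewards accuracy J and small subsets. Pheromone evaporates at rate
rho and good subsets deposit delta * f(A) on their features; levels are
clamped to [tau_min, tau_max] (max-min style) to delay stagnation.

The improved variant (IACO) varies the heuristic parameters during the
run: sigma and v are interpolated linearly from exploration-heavy to
exploitation-heavy values, and the evaporation rate is temporarily
doubled while the best fitness stagnates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FitnessConfig",
    "ColonyConfig",
    "PheromoneState",
    "AntSolution",
    "SearchResult",
    "search_space_size",
    "fitness",
    "heuristic_desirability",
    "construct_subset",
    "update_pheromone",
    "iaco_schedule",
    "run_colony",
]

#: evaluator signature: (subset mask, X, y) -> classification accuracy J
Evaluator = Callable[[np.ndarray, np.ndarray, np.ndarray], float]


@dataclass(frozen=True)
class FitnessConfig:
    """Weights of the accuracy and subset-size terms of the fitness."""

    m_weight: float = 0.92
    n_weight: float = 0.78

    def __post_init__(self) -> None:
        if not (0 <= self.m_weight <= 1 and 0 <= self.n_weight <= 1):
            raise ValueError("fitness weights must lie in [0, 1]")


@dataclass
class ColonyConfig:
    n_ants: int = 20
    n_iter: int = 50
    sigma: float = 1.0           # pheromone exponent
    v: float = 1.0               # heuristic exponent
    rho: float = 0.2             # evaporation rate
    delta: float = 1.0           # deposit scale
    subset_size_range: tuple[int, int] = (10, 35)
    tau_min: float = 0.1
    tau_max: float = 5.0
    tau_init: float = 1.0
    iaco: bool = False
    sigma_start: float = 1.0
    sigma_end: float = 2.0
    v_start: float = 2.0
    v_end: float = 0.5
    stagnation_patience: int = 5   # iterations before the rho boost kicks in
    patience_stop: int = 10        # stagnant iterations before stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.v < 0:
            raise ValueError("exponents sigma, v must be >= 0")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        k_min, k_max = self.subset_size_range
        if not 1 <= k_min <= k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if not 0 < self.tau_min <= self.tau_max:
            raise ValueError("need 0 < tau_min <= tau_max")


@dataclass
class PheromoneState:
    tau: np.ndarray
    tau_min: float = 0.1
    tau_max: float = 5.0
    iteration: int = 0

    @classmethod
    def initial(cls, n_features: int, cfg: ColonyConfig) -> "PheromoneState":
        return cls(np.full(n_features, float(cfg.tau_init)), cfg.tau_min, cfg.tau_max)


@dataclass
class AntSolution:
    subset: np.ndarray           # boolean mask over features
    accuracy: float
    fitness: float
    n_selected: int

    @classmethod
    def from_mask(cls, mask: np.ndarray, accuracy: float,
                  fc: FitnessConfig) -> "AntSolution":
        k = int(mask.sum())
        return cls(mask, float(accuracy), fitness(accuracy, k, fc), k)


@dataclass
class SearchResult:
    best: AntSolution
    history: list[dict]          # per iteration: best_so_far, iter best/mean
    evaluations: int
    method: str = "aco"

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def search_space_size(x: int) -> int:
    """Number of possible feature subsets of an x-feature set (2^x)."""
    if x < 0:
        raise ValueError("feature count must be >= 0")
    return 2**x


def fitness(accuracy: float, n_selected: int, fc: FitnessConfig = FitnessConfig()) -> float:
    """f(A) = m * J(A) + n / |A|."""
    if n_selected < 1:
        raise ValueError("subset must contain at least one feature")
    if not 0 <= accuracy <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    return fc.m_weight * accuracy + fc.n_weight / n_selected


def heuristic_desirability(X: np.ndarray, y: Sequence) -> np.ndarray:
    """Per-feature Fisher discriminant ratio, rescaled to (0, 1].

    eta_j = (mu1_j - mu2_j)^2 / (s1_j^2 + s2_j^2 + eps), sample variances.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("heuristic needs exactly two classes")
    A, B = X[y == classes[0]], X[y == classes[1]]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each class needs >= 2 samples")
    num = (A.mean(axis=0) - B.mean(axis=0)) ** 2
    den = A.var(axis=0, ddof=1) + B.var(axis=0, ddof=1) + 1e-12
    eta = num / den
    top = eta.max()
    if top <= 0:
        return np.ones_like(eta)
    return eta / top


def construct_subset(
    ph: PheromoneState,
    eta: np.ndarray,
    cfg: ColonyConfig,
    rng: np.random.Generator,
    sigma: float | None = None,
    v: float | None = None,
    k: int | None = None,
) -> np.ndarray:
    """Draw one ant's subset by sequential weighted roulette.

    The target size k is uniform on subset_size_range unless given.
    ``sigma``/``v`` override the config exponents (used by the IACO
    schedule). Deterministic given the rng state.
    """
    n = ph.tau.size
    if eta.size != n:
        raise ValueError("eta and tau lengths differ")
    k_min, k_max = cfg.subset_size_range
    if k is None:
        if k_max > n:
            raise ValueError("k_max exceeds the number of features")
        k = int(rng.integers(k_min, k_max + 1))
    s = cfg.sigma if sigma is None else sigma
    w_exp = cfg.v if v is None else v
    weights = ph.tau**s * eta**w_exp
    mask = np.zeros(n, dtype=bool)
    remaining = np.arange(n)
    for _ in range(k):
        w = weights[remaining]
        tot = w.sum()
        if tot <= 0:
            p = np.full(remaining.size, 1.0 / remaining.size)
        else:
            p = w / tot
        assert abs(p.sum() - 1.0) < 1e-9
        pick = remaining[rng.choice(remaining.size, p=p)]
        mask[pick] = True
        remaining = remaining[remaining != pick]
    return mask


def update_pheromone(
    ph: PheromoneState,
    solutions: Sequence[AntSolution],
    cfg: ColonyConfig,
    rho: float | None = None,
) -> PheromoneState:
    """tau_j <- (1 - rho) tau_j + sum_r delta * f(A_r) [j in A_r], clamped.

    An explicit ``rho`` may be 0 (pure deposit); colony runs always use
    a strictly positive evaporation rate.
    """
    r = cfg.rho if rho is None else rho
    if not 0 <= r <= 1:
        raise ValueError("rho must be in [0, 1]")
    tau = (1.0 - r) * ph.tau
    for sol in solutions:
        tau = tau + np.where(sol.subset, cfg.delta * sol.fitness, 0.0)
    tau = np.clip(tau, ph.tau_min, ph.tau_max)
    return PheromoneState(tau, ph.tau_min, ph.tau_max, ph.iteration + 1)


def iaco_schedule(
    cfg: ColonyConfig, t: int, stagnation: int
) -> tuple[float, float, float]:
    """Dynamic (sigma_t, v_t, rho_t) for iteration t of an IACO run."""
    if not 0 <= t < cfg.n_iter:
        raise ValueError("iteration out of range")
    frac = t / (cfg.n_iter - 1) if cfg.n_iter > 1 else 0.0
    sigma_t = cfg.sigma_start + frac * (cfg.sigma_end - cfg.sigma_start)
    v_t = cfg.v_start + frac * (cfg.v_end - cfg.v_start)
    rho_t = cfg.rho
    if stagnation >= cfg.stagnation_patience:
        rho_t = min(2.0 * cfg.rho, 1.0)
    return sigma_t, v_t, rho_t


def run_colony(
    X: np.ndarray,
    y: Sequence,
    cfg: ColonyConfig,
    fc: FitnessConfig,
    evaluator: Evaluator,
) -> SearchResult:
    """Run the colony; returns the best-ever subset and the full history.

    Re-evaluations of an already-scored subset are served from a cache,
    so ``evaluations`` counts distinct classifier trainings.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed)
    eta = heuristic_desirability(X, y)
    ph = PheromoneState.initial(X.shape[1], cfg)
    cache: dict[bytes, float] = {}
    best: AntSolution | None = None
    history: list[dict] = []
    evaluations = 0
    stagnation = 0
    for t in range(cfg.n_iter):
        if cfg.iaco:
            sigma_t, v_t, rho_t = iaco_schedule(cfg, t, stagnation)
        else:
            sigma_t, v_t, rho_t = cfg.sigma, cfg.v, cfg.rho
        ants: list[AntSolution] = []
        for _ in range(cfg.n_ants):
            mask = construct_subset(ph, eta, cfg, rng, sigma=sigma_t, v=v_t)
            key = mask.tobytes()
            if key in cache:
                acc = cache[key]
            else:
                try:
                    acc = float(evaluator(mask, X, y))
                except Exception as exc:
                    sel = np.flatnonzero(mask).tolist()
                    raise RuntimeError(f"evaluator failed on subset {sel}") from exc
                cache[key] = acc
                evaluations += 1
            ants.append(AntSolution.from_mask(mask, acc, fc))
        iter_best = max(ants, key=lambda a: a.fitness)
        if best is None or iter_best.fitness > best.fitness + 1e-12:
            best = iter_best
            stagnation = 0
        else:
            stagnation += 1
        ph = update_pheromone(ph, ants, cfg, rho=rho_t)
        history.append({
            "iteration": t,
            "best_fitness": best.fitness,
            "iter_best_fitness": iter_best.fitness,
            "mean_fitness": float(np.mean([a.fitness for a in ants])),
            "sigma": sigma_t, "v": v_t, "rho": rho_t,
        })
        if stagnation >= cfg.patience_stop:
            break
    assert best is not None
    return SearchResult(best, history, evaluations,
                        method="iaco" if cfg.iaco else "aco")
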