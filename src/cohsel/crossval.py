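"""Nested cross-validation around wrapper feature selection.

Protocol: the cohort is split into 6 stratified outer folds. For each
outer cycle the remaining 5 folds are re-split into 5 stratified inner
splits; on each inner split the feature-selection method searches
subsets with an evaluator that trains an SVM on the 4 inner-training
folds and scores accuracy on the verification fold. The 5 inner winners
are ranked by fitness (accuracy + subset-size term, so smaller subsets
break accuracy ties), the top subset is refit on the whole outer
training set, and only then evaluated once on the untouched outer test
fold. Feature standardization is always fit on training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .baselines import GAConfig, PSOConfig, ga_select, pso_select
from .coherence import CoherenceFeatureMatrix
from .colony import (AntSolution, ColonyConfig, FitnessConfig, fitness,
                     run_colony)
from .svm import KernelSpec, SVMModel, decision_values, train

__all__ = [
    "PipelineConfig", "StandardizedSVM", "CVReport",
    "stratified_folds", "metrics", "inner_select", "run_nested_cv",
    "compare_methods", "FS_METHODS",
]

FS_METHODS = ("none", "ga", "pso", "aco", "iaco")


@dataclass
class PipelineConfig:
    """Everything the nested-CV pipeline needs besides the data."""

    kernel: KernelSpec = field(default_factory=KernelSpec)
    C: float = 10.0
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    colony: ColonyConfig = field(default_factory=ColonyConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    n_outer: int = 6
    n_inner: int = 5
    seed: int = 0
    positive_label: str | None = None


@dataclass
class StandardizedSVM:
    """SVM plus the feature subset and train-fold standardization it
    was fit with; applies both before predicting."""

    mask: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    model: SVMModel

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float)[:, self.mask] - self.mean) / self.sd
        return decision_values(self.model, Z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1.0, -1.0)


@dataclass
class CVReport:
    fs_method: str
    positive_label: str
    folds: list[dict]                 # per outer fold
    mean_accuracy: float
    mean_sensitivity: float
    mean_auc: float
    global_best_fold: int
    global_best: StandardizedSVM
    feature_names: list[str]

    def selected_features(self, fold: int | None = None) -> list[str]:
        mask = (self.global_best.mask if fold is None
                else self.folds[fold]["mask"])
        return [n for n, m in zip(self.feature_names, mask) if m]

    def to_dict(self) -> dict:
        return {
            "fs_method": self.fs_method,
            "positive_label": self.positive_label,
            "mean_accuracy": self.mean_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_auc": self.mean_auc,
            "global_best_fold": self.global_best_fold,
            "global_best_features": self.selected_features(),
            "folds": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in f.items() if k != "model"}
                for f in self.folds
            ],
        }


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Partition indices into k stratified folds with sizes differing by
    at most one subject overall.

    Within each class the (seeded-shuffled) members are split into k
    chunks of near-equal size; chunk-to-fold assignment is rotated by
    the running remainder so that the oversized chunks of different
    classes land on different folds.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has fewer than {k} members")
        rng.shuffle(idx)
        chunks = np.array_split(idx, k)
        for j, chunk in enumerate(chunks):
            folds[(j + offset) % k].extend(chunk.tolist())
        offset += idx.size % k
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def metrics(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, AUC) from decision values and +/-1 truth.

    Accuracy thresholds at zero (ties to +1); sensitivity is the
    true-positive rate of the +1 class; AUC is the Mann-Whitney
    statistic with ties counted one half.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, float)
    pos = truth > 0
    if not pos.any() or pos.all():
        raise ValueError("AUC undefined: truth contains a single class")
    pred = np.where(scores >= 0, 1.0, -1.0)
    acc = float((pred == truth).mean())
    sens = float((pred[pos] == 1.0).mean())
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    auc = float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return acc, sens, auc


def _labels_to_pm(labels, positive: str) -> np.ndarray:
    return np.where(np.asarray(labels) == positive, 1.0, -1.0)


def _fit_standardized(X, y_pm, mask, kernel, C) -> StandardizedSVM:
    Xs = X[:, mask]
    mean = Xs.mean(axis=0)
    sd = Xs.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    model = train((Xs - mean) / sd, y_pm, kernel, C)
    return StandardizedSVM(np.asarray(mask, bool), mean, sd, model)


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def _split_evaluator(X_val, y_val, kernel, C):
    """Wrapper evaluator: train on the data handed in by the search,
    score accuracy on the closed-over verification fold."""

    def evaluate(mask, X_tr, y_tr) -> float:
        fitted = _fit_standardized(X_tr, y_tr, mask, kernel, C)
        return float((fitted.predict(X_val) == y_val).mean())

    return evaluate


def _run_fs(method, X, y_pm, cfg: PipelineConfig, evaluator, seed):
    if method in ("aco", "iaco"):
        col = replace(cfg.colony, iaco=(method == "iaco"), seed=seed)
        if col.subset_size_range[1] > X.shape[1]:
            col = replace(col, subset_size_range=(
                min(col.subset_size_range[0], X.shape[1]), X.shape[1]))
        return run_colony(X, y_pm, col, cfg.fitness, evaluator)
    if method == "ga":
        return ga_select(X, y_pm, replace(cfg.ga, seed=seed), cfg.fitness, evaluator)
    if method == "pso":
        return pso_select(X, y_pm, replace(cfg.pso, seed=seed), cfg.fitness, evaluator)
    raise ValueError(f"unknown feature-selection method {method!r}")


def inner_select(
    train_X: np.ndarray,
    train_y_pm: np.ndarray,
    fs_method: str,
    cfg: PipelineConfig,
    cycle_seed: int,
) -> tuple[StandardizedSVM, np.ndarray, list[dict]]:
    """Inner 5-fold model selection within one outer training set.

    Returns the winning model refit on the whole training set, its
    subset mask, and the per-split records.
    """
    if fs_method not in FS_METHODS:
        raise ValueError(f"fs_method must be one of {FS_METHODS}")
    n_feat = train_X.shape[1]
    seed = cycle_seed
    for attempt in range(5):
        splits = stratified_folds(train_y_pm, cfg.n_inner, seed + attempt)
        ok = all(
            len(np.unique(train_y_pm[np.setdiff1d(np.arange(len(train_y_pm)), s)])) == 2
            for s in splits
        )
        if ok:
            break
        warnings.warn("degenerate inner split; re-stratifying with next seed")
    records: list[dict] = []
    for i, val_idx in enumerate(splits):
        tr_idx = np.setdiff1d(np.arange(len(train_y_pm)), val_idx)
        X_tr, y_tr = train_X[tr_idx], train_y_pm[tr_idx]
        X_val, y_val = train_X[val_idx], train_y_pm[val_idx]
        evaluator = _split_evaluator(X_val, y_val, cfg.kernel, cfg.C)
        if fs_method == "none":
            mask = np.ones(n_feat, dtype=bool)
            acc = evaluator(mask, X_tr, y_tr)
            sol = AntSolution.from_mask(mask, acc, cfg.fitness)
            records.append({"split": i, "mask": mask, "accuracy": acc,
                            "fitness": sol.fitness, "evaluations": 1})
        else:
            res = _run_fs(fs_method, X_tr, y_tr, cfg,
                          evaluator, _derived_seed(cycle_seed, i))
            records.append({"split": i, "mask": res.best.subset,
                            "accuracy": res.best.accuracy,
                            "fitness": res.best.fitness,
                            "evaluations": res.evaluations})
    winner = max(records, key=lambda r: r["fitness"])
    mask = winner["mask"]
    refit = _fit_standardized(train_X, train_y_pm, mask, cfg.kernel, cfg.C)
    return refit, np.asarray(mask, bool), records


def run_nested_cv(
    features: CoherenceFeatureMatrix,
    fs_method: str = "iaco",
    cfg: PipelineConfig | None = None,
) -> CVReport:
    """Full nested-CV evaluation of one feature-selection method."""
    cfg = cfg or PipelineConfig()
    labels = np.asarray(features.labels)
    uniq = list(dict.fromkeys(features.labels))
    if len(uniq) != 2:
        raise ValueError("nested CV needs exactly two classes")
    positive = cfg.positive_label or uniq[0]
    if positive not in uniq:
        raise ValueError(f"positive label {positive!r} not present")
    X = features.values
    y_pm = _labels_to_pm(labels, positive)
    outer = stratified_folds(labels, cfg.n_outer, cfg.seed)
    fold_rows: list[dict] = []
    for o, test_idx in enumerate(outer):
        tr_idx = np.setdiff1d(np.arange(len(y_pm)), test_idx)
        # leakage guard: no outer-test row may reach selection/training
        test_hashes = {X[i].tobytes() for i in test_idx}
        assert not any(X[i].tobytes() in test_hashes for i in tr_idx), \
            "outer test rows leaked into the training matrix"
        model, mask, records = inner_select(
            X[tr_idx], y_pm[tr_idx], fs_method, cfg,
            _derived_seed(cfg.seed, o))
        scores = model.decision(X[test_idx])
        acc, sens, auc = metrics(scores, y_pm[test_idx])
        fold_rows.append({
            "fold": o,
            "test_idx": test_idx,
            "mask": np.asarray(mask, bool),
            "n_selected": int(np.sum(mask)),
            "accuracy": acc,
            "sensitivity": sens,
            "auc": auc,
            "scores": scores,
            "truth": y_pm[test_idx],
            "fitness": fitness(acc, int(np.sum(mask)), cfg.fitness),
            "inner": [{"split": r["split"], "accuracy": r["accuracy"],
                       "fitness": r["fitness"]} for r in records],
            "model": model,
        })
    best_fold = int(np.argmax([f["fitness"] for f in fold_rows]))
    return CVReport(
        fs_method=fs_method,
        positive_label=positive,
        folds=fold_rows,
        mean_accuracy=float(np.mean([f["accuracy"] for f in fold_rows])),
        mean_sensitivity=float(np.mean([f["sensitivity"] for f in fold_rows])),
        mean_auc=float(np.mean([f["auc"] for f in fold_rows])),
        global_best_fold=best_fold,
        global_best=fold_rows[best_fold]["model"],
        feature_names=list(features.feature_names),
    )


def compare_methods(
    features: CoherenceFeatureMatrix,
    cfg: PipelineConfig | None = None,
    methods: tuple[str, ...] = FS_METHODS,
) -> "pd.DataFrame":
    """Run every selection method through nested CV; one summary row
    each: method, subset size (median over outer folds), sensitivity,
    accuracy (%), fitness of the aggregate, AUC."""
    import pandas as pd

    cfg = cfg or PipelineConfig()
    rows = []
    reports = {}
    for method in methods:
        rep = run_nested_cv(features, method, cfg)
        reports[method] = rep
        n_feat = int(np.median([f["n_selected"] for f in rep.folds]))
        rows.append({
            "method": method,
            "n_features": n_feat,
            "sensitivity": round(rep.mean_sensitivity, 3),
            "accuracy": round(100 * rep.mean_accuracy, 2),
            "fitness": round(fitness(rep.mean_accuracy, n_feat, cfg.fitness), 3),
            "auc": round(rep.mean_auc, 3),
        })
    df = pd.DataFrame(rows)
    df.attrs["reports"] = reports
    return df
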