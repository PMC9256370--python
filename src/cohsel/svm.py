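"""Soft-margin SVM with linear, polynomial and RBF kernels.

The dual problem

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j q_i q_j K(p_i, p_j)
    s.t.   sum_i a_i q_i = 0,   0 <= a_i <= C

is solved by scikit-learn's SMO backend; the contract here is the dual
optimum, not the solver. Decision values are recomputed from the
extracted support vectors as f(p) = sum_i a_i q_i K(p_i, p) + b, which
keeps prediction independent of the backend and serializable.

Defaults: RBF width such that gamma = 1/(2 sigma^2) = 0.2, penalty
C = 10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = ["KernelSpec", "SVMModel", "kernel_eval", "kernel_matrix",
           "train", "decision_values", "predict"]

#: RBF width sigma such that gamma = 1/(2 sigma^2) = 0.2
DEFAULT_RBF_WIDTH = float(np.sqrt(1.0 / (2 * 0.2)))
DEFAULT_C = 10.0


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "rbf"            # linear | polynomial | rbf
    width: float = DEFAULT_RBF_WIDTH
    degree: int = 3
    coef: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "rbf"):
            raise ValueError(f"unknown kernel {self.kind!r}")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.width**2)


def kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ")
    if spec.kind == "linear":
        return A @ B.T
    if spec.kind == "polynomial":
        return (A @ B.T + spec.coef) ** spec.degree
    d2 = (
        (A**2).sum(axis=1)[:, None]
        + (B**2).sum(axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    return np.exp(-np.maximum(d2, 0.0) * spec.gamma)


def kernel_eval(spec: KernelSpec, p: np.ndarray, q: np.ndarray) -> float:
    """Kernel value for a single pair of feature vectors."""
    return float(kernel_matrix(spec, p[None, :], q[None, :])[0, 0])


@dataclass
class SVMModel:
    support_vectors: np.ndarray
    alphas: np.ndarray               # a_i >= 0
    sv_labels: np.ndarray            # q_i in {-1, +1}
    bias: float
    C: float
    kernel: KernelSpec
    n_iter: int = 0
    classes: tuple = (-1, 1)

    def __post_init__(self) -> None:
        if (self.alphas < -1e-9).any() or (self.alphas > self.C + 1e-6).any():
            raise ValueError("alphas outside [0, C]")
        bal = float(np.dot(self.alphas, self.sv_labels))
        if abs(bal) > 1e-6 * max(1.0, self.alphas.sum()):
            raise ValueError(f"dual equality constraint violated: {bal}")

    def to_json(self) -> str:
        return json.dumps({
            "support_vectors": self.support_vectors.tolist(),
            "alphas": self.alphas.tolist(),
            "sv_labels": self.sv_labels.tolist(),
            "bias": self.bias,
            "C": self.C,
            "kernel": {"kind": self.kernel.kind, "width": self.kernel.width,
                       "degree": self.kernel.degree, "coef": self.kernel.coef},
            "n_iter": self.n_iter,
        })

    @classmethod
    def from_json(cls, text: str) -> "SVMModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["support_vectors"], float),
            np.asarray(d["alphas"], float),
            np.asarray(d["sv_labels"], float),
            float(d["bias"]),
            float(d["C"]),
            KernelSpec(**d["kernel"]),
            int(d.get("n_iter", 0)),
        )


def train(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec = KernelSpec(),
    C: float = DEFAULT_C,
) -> SVMModel:
    """Fit the soft-margin dual for labels in {-1, +1}."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1} with both classes present")
    if C <= 0:
        raise ValueError("C must be positive")
    params = {"C": C, "tol": 1e-4}
    if spec.kind == "linear":
        svc = SVC(kernel="linear", **params)
    elif spec.kind == "polynomial":
        svc = SVC(kernel="poly", degree=spec.degree, gamma=1.0,
                  coef0=spec.coef, **params)
    else:
        svc = SVC(kernel="rbf", gamma=spec.gamma, **params)
    svc.fit(X, y)
    n_iter = int(np.asarray(svc.n_iter_).max())
    if n_iter < 0:
        raise RuntimeError(f"SMO failed to converge after {abs(n_iter)} iterations")
    dual = svc.dual_coef_[0]                      # a_i * q_i
    # sklearn orders classes ascending; dual_coef rows follow that order.
    return SVMModel(
        support_vectors=X[svc.support_],
        alphas=np.abs(dual),
        sv_labels=np.sign(dual),
        bias=float(svc.intercept_[0]),
        C=C,
        kernel=spec,
        n_iter=n_iter,
    )


def decision_values(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """f(p) = sum_i a_i q_i K(p_i, p) + b, evaluated with our kernels."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError("feature dimension differs from training")
    K = kernel_matrix(model.kernel, X, model.support_vectors)
    return K @ (model.alphas * model.sv_labels) + model.bias


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Sign of the decision value; ties (exactly 0) go to +1."""
    f = decision_values(model, X)
    return np.where(f >= 0, 1.0, -1.0)
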