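"""Maximum-margin classifiers and a small feed-forward network.

The SVM solves the soft-margin dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.   0 <= a_i <= C,  sum_i a_i y_i = 0

by sequential minimal optimization: repeatedly pick a KKT-violating pair
and solve its two-variable subproblem in closed form.  Each pair step
maximizes the restricted dual exactly, so the dual objective never
decreases.  Multiclass problems are handled one-vs-one with majority
voting (ties broken by class order).  Kernels: linear and RBF with the
scale convention gamma = 1 / (n_features * Var(X)).

The neural network is a 3-layer perceptron (input, one hidden layer of 10
logistic units, softmax output) trained by full-batch gradient descent on
the cross-entropy loss.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class KernelSpec:
    """Kernel for the SVM: ``linear`` or ``rbf``.

    ``gamma=None`` means the data-scale default 1/(n_features * Var(X)),
    resolved at training time and stored on the model.
    """

    kind: str = "linear"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError("kernel kind must be 'linear' or 'rbf'")
        if self.gamma is not None and not self.gamma > 0:
            raise ValueError("gamma must be positive")


def default_gamma(X: np.ndarray) -> float:
    """The 'scale' convention: 1 / (n_features * variance of all entries)."""
    X = np.asarray(X, dtype=float)
    var = X.var()
    if var <= 0:
        var = 1.0
    return 1.0 / (X.shape[1] * var)


def kernel_matrix(A, B, spec: KernelSpec, gamma: float | None = None) -> np.ndarray:
    """Gram matrix K[i, j] = phi(A_i, B_j)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if spec.kind == "linear":
        return A @ B.T
    g = gamma if gamma is not None else spec.gamma
    if g is None:
        raise ValueError("rbf kernel needs a resolved gamma")
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    return np.exp(-g * np.maximum(d2, 0.0))


@dataclass
class BinarySVM:
    """One binary subproblem: support vectors and duals for classes (neg, pos)."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i for the support vectors
    bias: float
    objective_history: list = field(default_factory=list)

    def decision(self, X, spec: KernelSpec, gamma: float | None) -> np.ndarray:
        K = kernel_matrix(X, self.support_vectors, spec, gamma)
        return K @ self.dual_coef + self.bias


@dataclass
class SVMModel:
    classes: tuple
    kernel: KernelSpec
    gamma: float | None  # resolved value actually used (None for linear)
    C: float
    binaries: dict  # (i, j) class-index pair -> BinarySVM
    scheme: str = "one_vs_one"

    def to_json(self) -> dict:
        return {
            "type": "svm",
            "classes": list(self.classes),
            "kernel": {"kind": self.kernel.kind, "gamma": self.kernel.gamma},
            "gamma": self.gamma,
            "C": self.C,
            "scheme": self.scheme,
            "binaries": {
                f"{i},{j}": {
                    "support_vectors": b.support_vectors.tolist(),
                    "dual_coef": b.dual_coef.tolist(),
                    "bias": b.bias,
                }
                for (i, j), b in self.binaries.items()
            },
        }

    @classmethod
    def from_json(cls, d: dict) -> "SVMModel":
        binaries = {}
        for key, b in d["binaries"].items():
            i, j = (int(v) for v in key.split(","))
            binaries[(i, j)] = BinarySVM(
                np.asarray(b["support_vectors"], float),
                np.asarray(b["dual_coef"], float),
                float(b["bias"]),
            )
        return cls(
            tuple(d["classes"]),
            KernelSpec(d["kernel"]["kind"], d["kernel"]["gamma"]),
            d["gamma"],
            float(d["C"]),
            binaries,
            d.get("scheme", "one_vs_one"),
        )


def _smo_binary(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float,
    max_passes: int = 5,
    max_iter: int = 10_000,
    record_objective: bool = False,
):
    """Platt-style SMO on a precomputed Gram matrix; y in {-1, +1}.

    Deterministic: examples are scanned in index order and the partner is
    the maximal-|E_i - E_j| example (lowest index on ties).  Returns
    (alpha, b, objective_history).
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    b = 0.0
    # E_i = f(x_i) - y_i, maintained incrementally
    E = -y.astype(float)
    history: list[float] = []

    def objective() -> float:
        ay = alpha * y
        return alpha.sum() - 0.5 * ay @ K @ ay

    if record_objective:
        history.append(objective())

    def take_step(i: int, j: int) -> bool:
        nonlocal b, E
        if i == j:
            return False
        Ei, Ej = E[i], E[j]
        ai_old, aj_old = alpha[i], alpha[j]
        if y[i] != y[j]:
            L, H = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
        else:
            L, H = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
        if H - L < 1e-12:
            return False
        eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
        if eta >= 0:
            return False
        aj = np.clip(aj_old - y[j] * (Ei - Ej) / eta, L, H)
        if abs(aj - aj_old) < 1e-10:
            return False
        ai = ai_old + y[i] * y[j] * (aj_old - aj)
        alpha[i], alpha[j] = ai, aj
        b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] - y[j] * (aj - aj_old) * K[i, j]
        b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] - y[j] * (aj - aj_old) * K[j, j]
        if 0 < ai < C:
            b_new = b1
        elif 0 < aj < C:
            b_new = b2
        else:
            b_new = 0.5 * (b1 + b2)
        E += (
            y[i] * (ai - ai_old) * K[i]
            + y[j] * (aj - aj_old) * K[j]
            + (b_new - b)
        )
        b = b_new
        if record_objective:
            history.append(objective())
        return True

    passes = 0
    it = 0
    while passes < max_passes and it < max_iter:
        num_changed = 0
        for i in range(n):
            it += 1
            Ei = E[i]
            if not (
                (y[i] * Ei < -tol and alpha[i] < C)
                or (y[i] * Ei > tol and alpha[i] > 0)
            ):
                continue
            # Platt's partner hierarchy: maximal |E_i - E_j| first, then the
            # remaining examples in index order (deterministic)
            gaps = np.abs(Ei - E)
            gaps[i] = -1.0
            if take_step(i, int(np.argmax(gaps))):
                num_changed += 1
                continue
            for j in range(n):
                if take_step(i, j):
                    num_changed += 1
                    break
        passes = passes + 1 if num_changed == 0 else 0
    return alpha, b, history


def train_svm(
    X,
    y,
    kernel: KernelSpec = KernelSpec(),
    C: float = 1.0,
    tol: float = 1e-3,
    seed: int = 0,
    class_order=None,
    record_objective: bool = False,
) -> SVMModel:
    """Train a (multiclass) SVM by one-vs-one SMO.

    ``seed`` is accepted for interface symmetry; the solver itself is
    deterministic.  ``class_order`` fixes the label ordering used for
    voting tie-breaks (defaults to first appearance in ``y``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if C <= 0:
        raise ValueError("C must be positive")
    classes = tuple(class_order) if class_order is not None else tuple(dict.fromkeys(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    gamma = None
    if kernel.kind == "rbf":
        gamma = kernel.gamma if kernel.gamma is not None else default_gamma(X)
    binaries = {}
    for i, j in itertools.combinations(range(len(classes)), 2):
        sel = (y == classes[i]) | (y == classes[j])
        Xs = X[sel]
        ys = np.where(y[sel] == classes[j], 1.0, -1.0)  # pos = higher index
        K = kernel_matrix(Xs, Xs, kernel, gamma)
        alpha, b, hist = _smo_binary(K, ys, C, tol, record_objective=record_objective)
        sv = alpha > 1e-10
        binaries[(i, j)] = BinarySVM(Xs[sv], alpha[sv] * ys[sv], b, hist)
    return SVMModel(classes, kernel, gamma, C, binaries)


@dataclass
class Prediction:
    labels: np.ndarray
    scores: np.ndarray  # decision values (SVM votes) or class probabilities


def predict_svm(model: SVMModel, X) -> Prediction:
    """One-vs-one voting; ties broken by class order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    first = next(iter(model.binaries.values()))
    if first.support_vectors.size and X.shape[1] != first.support_vectors.shape[1]:
        raise ValueError(
            f"dimension mismatch: model expects {first.support_vectors.shape[1]}, got {X.shape[1]}"
        )
    n_classes = len(model.classes)
    votes = np.zeros((X.shape[0], n_classes))
    for (i, j), bin_svm in model.binaries.items():
        f = bin_svm.decision(X, model.kernel, model.gamma)
        votes[:, j] += f > 0
        votes[:, i] += f <= 0
    idx = np.argmax(votes, axis=1)  # argmax takes the lowest index on ties
    labels = np.asarray(model.classes, dtype=object)[idx]
    return Prediction(labels, votes)


def decision_values(model: SVMModel, X, pair=(0, 1)) -> np.ndarray:
    """Raw decision function of one binary subproblem (positive = second class)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.binaries[pair].decision(X, model.kernel, model.gamma)


@dataclass
class NNModel:
    """3-layer perceptron: input -> 10 logistic hidden units -> softmax."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    classes: tuple
    seed: int = 0

    def to_json(self) -> dict:
        return {
            "type": "nn",
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "classes": list(self.classes),
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, d: dict) -> "NNModel":
        return cls(
            np.asarray(d["w1"], float),
            np.asarray(d["b1"], float),
            np.asarray(d["w2"], float),
            np.asarray(d["b2"], float),
            tuple(d["classes"]),
            int(d.get("seed", 0)),
        )


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: NNModel, X):
    h = _sigmoid(X @ model.w1 + model.b1)
    return h, _softmax(h @ model.w2 + model.b2)


def train_nn(
    X,
    y,
    hidden: int = 10,
    epochs: int = 500,
    learning_rate: float = 0.5,
    seed: int = 0,
    class_order=None,
) -> NNModel:
    """Train the perceptron by full-batch gradient descent on cross-entropy.

    Deterministic given ``seed`` (weight initialization is the only
    randomness).  Aborts on a non-finite loss.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    classes = tuple(class_order) if class_order is not None else tuple(dict.fromkeys(y))
    cidx = {c: k for k, c in enumerate(classes)}
    T = np.zeros((X.shape[0], len(classes)))
    T[np.arange(X.shape[0]), [cidx[c] for c in y]] = 1.0
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    model = NNModel(
        rng.normal(0, 1.0 / np.sqrt(p), (p, hidden)),
        np.zeros(hidden),
        rng.normal(0, 1.0 / np.sqrt(hidden), (hidden, len(classes))),
        np.zeros(len(classes)),
        classes,
        seed,
    )
    n = X.shape[0]
    for _ in range(epochs):
        h, prob = _forward(model, X)
        loss = -np.sum(T * np.log(np.clip(prob, 1e-300, None))) / n
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: loss={loss}")
        g_out = (prob - T) / n
        g_w2 = h.T @ g_out
        g_b2 = g_out.sum(axis=0)
        g_h = g_out @ model.w2.T * h * (1.0 - h)
        g_w1 = X.T @ g_h
        g_b1 = g_h.sum(axis=0)
        model.w1 -= learning_rate * g_w1
        model.b1 -= learning_rate * g_b1
        model.w2 -= learning_rate * g_w2
        model.b2 -= learning_rate * g_b2
    return model


def predict_nn(model: NNModel, X) -> Prediction:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.w1.shape[0]:
        raise ValueError(
            f"dimension mismatch: model expects {model.w1.shape[0]}, got {X.shape[1]}"
        )
    _, prob = _forward(model, X)
    idx = np.argmax(prob, axis=1)
    labels = np.asarray(model.classes, dtype=object)[idx]
    return Prediction(labels, prob)
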