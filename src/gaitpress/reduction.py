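"""Dimensionality reduction: variance-target PCA and multiclass LDA.

PCA keeps the minimal number of leading principal components whose
cumulative explained-variance ratio reaches a target (90% by default).
LDA maximizes the ratio of projected between-class to within-class scatter,

    J(W) = (W^T S_B W) / (W^T S_W W),

solved as the generalized symmetric eigenproblem ``S_B w = lambda S_W w``
with a small ridge on ``S_W`` for singular cases; the output dimension is
at most C-1 (3 for the four gait classes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Sign convention: each row's largest-magnitude entry is positive."""
    out = components.copy()
    for i, row in enumerate(out):
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            out[i] = -row
    return out


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # (n_components, p), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int

    def to_json(self) -> dict:
        return {
            "type": "pca",
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components": self.n_components,
        }

    @classmethod
    def from_json(cls, d: dict) -> "PCAModel":
        return cls(
            np.asarray(d["mean"], float),
            np.asarray(d["components"], float),
            np.asarray(d["explained_variance_ratio"], float),
            int(d["n_components"]),
        )


@dataclass
class LDAModel:
    scalings: np.ndarray  # (p, d) projection matrix W
    class_means: np.ndarray  # (C, p) in the input space
    classes: tuple
    mean: np.ndarray  # overall mean, subtracted before projecting

    @property
    def d(self) -> int:
        return self.scalings.shape[1]

    def to_json(self) -> dict:
        return {
            "type": "lda",
            "scalings": self.scalings.tolist(),
            "class_means": self.class_means.tolist(),
            "classes": list(self.classes),
            "mean": self.mean.tolist(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "LDAModel":
        return cls(
            np.asarray(d["scalings"], float),
            np.asarray(d["class_means"], float),
            tuple(d["classes"]),
            np.asarray(d["mean"], float),
        )


def fit_pca(X, variance_target: float = 0.9) -> PCAModel:
    """Fit PCA on the rows of X, keeping components up to the variance target.

    Centers X, eigendecomposes the (n-1)-denominator sample covariance and
    keeps the minimal leading set whose cumulative explained-variance ratio
    reaches ``variance_target``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 samples")
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD route: numerically stabler than forming the covariance
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    ratios = var / total if total > 0 else np.zeros_like(var)
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(var))
    return PCAModel(mean, _fix_signs(vt[:k]), ratios[:k], k)


def _scatter_matrices(X, y):
    classes = list(dict.fromkeys(y))  # first-appearance order
    mean = X.mean(axis=0)
    p = X.shape[1]
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    means = []
    for c in classes:
        Xc = X[np.asarray(y) == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        mu = Xc.mean(axis=0)
        means.append(mu)
        d = Xc - mu
        s_w += d.T @ d
        dm = (mu - mean)[:, None]
        s_b += Xc.shape[0] * (dm @ dm.T)
    return np.array(means), tuple(classes), mean, s_b, s_w


def fit_lda(X, y, d: int | None = None, ridge: float = 1e-6) -> LDAModel:
    """Fit multiclass LDA maximizing the scatter-ratio objective.

    ``d`` defaults to C-1.  ``S_W`` is regularized with
    ``ridge * trace(S_W)/p * I`` so the generalized eigenproblem stays
    well-posed when features outnumber samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have matching first dimensions")
    means, classes, mean, s_b, s_w = _scatter_matrices(X, y)
    n_classes = len(classes)
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if d is None:
        d = n_classes - 1
    if not 1 <= d <= n_classes - 1:
        raise ValueError(f"d must be in [1, {n_classes - 1}]")
    p = X.shape[1]
    tr = np.trace(s_w)
    s_w_reg = s_w + (ridge * (tr / p if tr > 0 else 1.0)) * np.eye(p)
    evals, evecs = linalg.eigh(s_b, s_w_reg)
    order = np.argsort(evals)[::-1][:d]
    W = _fix_signs(evecs[:, order].T).T  # (p, d)
    return LDAModel(W, means, classes, mean)


def transform(model, X) -> np.ndarray:
    """Project rows of X with a fitted PCA or LDA model."""
    X = np.asarray(X, dtype=float)
    one = X.ndim == 1
    if one:
        X = X[None]
    if isinstance(model, PCAModel):
        if X.shape[1] != model.mean.size:
            raise ValueError(
                f"dimension mismatch: model expects {model.mean.size}, got {X.shape[1]}"
            )
        Z = (X - model.mean) @ model.components.T
    elif isinstance(model, LDAModel):
        if X.shape[1] != model.scalings.shape[0]:
            raise ValueError(
                f"dimension mismatch: model expects {model.scalings.shape[0]}, got {X.shape[1]}"
            )
        Z = (X - model.mean) @ model.scalings
    else:
        raise TypeError(f"unknown model type {type(model)!r}")
    return Z[0] if one else Z


def inverse_transform(model: PCAModel, Z) -> np.ndarray:
    """Map PCA scores back to the input space (exact for full rank)."""
    Z = np.asarray(Z, dtype=float)
    return Z @ model.components + model.mean
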