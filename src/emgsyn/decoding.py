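"""Single-trial LDA decoding of task parameters with leave-one-out CV."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    """V x V decoding outcome: raw counts and row-stochastic fractions D."""

    counts: np.ndarray
    class_labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def V(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    @property
    def D(self) -> np.ndarray:
        """Row-normalized fractions; all-zero rows stay zero."""
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        return np.divide(
            self.counts, row, out=np.zeros_like(self.counts, dtype=float),
            where=row > 0,
        )

    @property
    def percent_correct(self) -> float:
        if self.n_trials == 0:
            return float("nan")
        return 100.0 * float(np.trace(self.counts)) / self.n_trials


@dataclass
class DecodingResult:
    percent_correct: float
    confusion: ConfusionMatrix
    task_parameter: str | None = None
    info: object | None = field(default=None, repr=False)


def synergy_features(model, index: int, mode: str) -> np.ndarray:
    """Per-trial activation-coefficient features of one synergy.

    ``temporal`` mode returns the L x N slice A[:, index, :] (how synergy
    ``index`` combines with every spatial synergy); ``spatial`` mode the
    L x K slice A[:, :, index]; ``full`` the flattened L x (K*N) matrix.
    """
    A = model.A if hasattr(model, "A") else np.asarray(model)
    L, K, N = A.shape
    if mode == "temporal":
        if not 0 <= index < K:
            raise IndexError(f"temporal index {index} out of range for K={K}")
        return A[:, index, :]
    if mode == "spatial":
        if not 0 <= index < N:
            raise IndexError(f"spatial index {index} out of range for N={N}")
        return A[:, :, index]
    if mode == "full":
        return A.reshape(L, K * N)
    raise ValueError(f"mode must be 'temporal', 'spatial' or 'full', got {mode!r}")


def chance_level(V: int) -> float:
    """Chance percent-correct of a V-class discrimination (100/V)."""
    if V < 2:
        raise ValueError("need at least 2 classes")
    return 100.0 / V


def decode_loocv(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int | None = None,
    *,
    condition_threshold: float = 1e8,
    shrinkage: float = 1e-3,
    task_parameter: str | None = None,
) -> DecodingResult:
    """Leave-one-out LDA decoding of discrete labels from trial features.

    For each trial a linear discriminant (shared pooled covariance,
    empirical class priors) is trained on the remaining trials and
    predicts the held-out label.  Deterministic: prediction ties resolve
    to the lowest class index; ``seed`` is accepted for interface
    compatibility but unused.  When the pooled covariance is
    ill-conditioned (condition number above ``condition_threshold``) a
    ridge ``shrinkage * trace/d`` is added.  Trials whose class has a
    single member are skipped with a warning.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size > 1:
        X = X.T
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have one row per trial")
    classes, y_idx = np.unique(y, return_inverse=True)
    V = classes.size
    if V < 2:
        raise ValueError("need at least 2 distinct classes")
    L, d = X.shape
    n_c = np.bincount(y_idx, minlength=V)
    if np.any(n_c[y_idx] < 2):
        warnings.warn(
            "classes with a single trial cannot be cross-validated; "
            "their trials are skipped",
            stacklevel=2,
        )

    sums = np.zeros((V, d))
    np.add.at(sums, y_idx, X)
    sq = np.zeros((V, d, d))
    for c in range(V):
        Xc = X[y_idx == c]
        sq[c] = Xc.T @ Xc
    scatter_c = sq - np.einsum("ci,cj->cij", sums, sums) / np.maximum(n_c, 1)[:, None, None]
    S_full = scatter_c.sum(axis=0)

    dof_full = max(L - V, 1)
    sigma_full = S_full / dof_full
    lam = 0.0
    cond = np.linalg.cond(sigma_full) if d > 0 else 0.0
    if not np.isfinite(cond) or cond > condition_threshold:
        lam = shrinkage * np.trace(sigma_full) / d
        if lam <= 0:
            lam = shrinkage
    ridge = lam * np.eye(d)

    means_base = sums / np.maximum(n_c, 1)[:, None]
    counts = np.zeros((V, V), dtype=int)
    dof = max(L - 1 - V, 1)
    for l in range(L):
        c = y_idx[l]
        if n_c[c] < 2:
            continue
        x = X[l]
        s_c = sums[c] - x
        m = n_c[c] - 1
        # remove trial l from its class scatter
        S = (
            S_full
            - scatter_c[c]
            + (sq[c] - np.outer(x, x) - np.outer(s_c, s_c) / m)
        )
        sigma = S / dof + ridge
        means = means_base.copy()
        means[c] = s_c / m
        priors = n_c.astype(float)
        priors[c] -= 1
        priors /= L - 1
        W = np.linalg.solve(sigma, means.T)  # d x V
        scores = x @ W - 0.5 * np.einsum("dv,dv->v", means.T, W) + np.log(priors)
        counts[c, int(np.argmax(scores))] += 1

    confusion = ConfusionMatrix(counts=counts, class_labels=classes)
    return DecodingResult(
        percent_correct=confusion.percent_correct,
        confusion=confusion,
        task_parameter=task_parameter,
    )
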