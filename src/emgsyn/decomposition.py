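"""Space-by-time non-negative decomposition of single-trial EMG.

Each trial matrix is approximated as ``W_t @ A_l @ W_s`` with non-negative
temporal synergies W_t (T x K), spatial synergies W_s (N x M) and
trial-specific coefficients A_l (K x N).  The fit minimizes the total
squared Frobenius reconstruction error by cyclic multiplicative updates of
the three blocks (W_t, then all A_l, then W_s), each of which is a
standard non-negative least-squares descent step, with multi-restart to
escape local minima.  Model order (K, N) is selected by a decoding-gain
permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from emgsyn.dataset import EMGDataset
from emgsyn.decoding import decode_loocv

_EPS = 1e-12


@dataclass
class SpaceByTimeModel:
    """Fitted factors: W_t (T x K), W_s (N x M), A (L x K x N).

    Synergies follow the unit-norm convention (columns of W_t and rows of
    W_s have unit Euclidean norm; scale lives in A), which makes synergy
    comparison across fits and subjects well-posed.
    """

    W_t: np.ndarray
    W_s: np.ndarray
    A: np.ndarray
    seed: int | None = None
    restarts: int = 1
    objective: float = np.nan
    converged: bool = True
    n_iter: int = 0

    @property
    def K(self) -> int:
        return self.W_t.shape[1]

    @property
    def N(self) -> int:
        return self.W_s.shape[0]

    def reconstruct(self) -> np.ndarray:
        """(L, T, M) reconstruction of every trial."""
        return np.einsum("tk,lkn,nm->ltm", self.W_t, self.A, self.W_s, optimize=True)


@dataclass
class FitResult:
    model: SpaceByTimeModel
    vaf: float
    reconstruction_error: float
    objective_trace: np.ndarray = field(repr=False, default=None)


def _objective(X: np.ndarray, W_t: np.ndarray, A: np.ndarray, W_s: np.ndarray) -> float:
    R = np.einsum("tk,lkn,nm->ltm", W_t, A, W_s, optimize=True)
    return float(np.sum((X - R) ** 2))


def _fit_once(
    X: np.ndarray,
    K: int,
    N: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    L, T, M = X.shape
    W_t = rng.uniform(size=(T, K))
    W_s = rng.uniform(size=(N, M))
    A = rng.uniform(size=(L, K, N))
    # scale A so the initial reconstruction matches the data magnitude
    R = np.einsum("tk,lkn,nm->ltm", W_t, A, W_s, optimize=True)
    denom = float(np.sum(R * R))
    if denom > 0:
        A *= max(float(np.sum(X * R)) / denom, _EPS)

    trace = [_objective(X, W_t, A, W_s)]
    converged = False
    for _ in range(max_iter):
        # W_t update
        G_s = W_s @ W_s.T
        numer = np.einsum("ltm,nm,lkn->tk", X, W_s, A, optimize=True)
        B = np.einsum("lkn,nj,lij->ki", A, G_s, A, optimize=True)
        W_t *= numer / (W_t @ B + _EPS)
        # A update (all trials at once)
        G_t = W_t.T @ W_t
        numer = np.einsum("tk,ltm,nm->lkn", W_t, X, W_s, optimize=True)
        denom = np.einsum("ki,lin,nj->lkj", G_t, A, G_s, optimize=True)
        A *= numer / (denom + _EPS)
        # W_s update
        G_t = W_t.T @ W_t
        numer = np.einsum("lkn,tk,ltm->nm", A, W_t, X, optimize=True)
        C = np.einsum("lki,kj,ljn->in", A, G_t, A, optimize=True)
        W_s *= numer / (C @ W_s + _EPS)

        trace.append(_objective(X, W_t, A, W_s))
        prev, cur = trace[-2], trace[-1]
        if prev - cur <= tol * max(prev, _EPS):
            converged = True
            break
    return W_t, A, W_s, np.array(trace), converged


def _normalize(W_t: np.ndarray, A: np.ndarray, W_s: np.ndarray):
    """Push synergy scale into A (unit-norm columns of W_t, rows of W_s)."""
    nt = np.linalg.norm(W_t, axis=0)
    ns = np.linalg.norm(W_s, axis=1)
    nt_safe = np.where(nt > 0, nt, 1.0)
    ns_safe = np.where(ns > 0, ns, 1.0)
    W_t = W_t / nt_safe
    W_s = W_s / ns_safe[:, None]
    A = A * nt_safe[None, :, None] * ns_safe[None, None, :]
    return W_t, A, W_s


def fit_space_by_time(
    data: EMGDataset,
    K: int,
    N: int,
    restarts: int = 50,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
) -> FitResult:
    """Fit the three-factor model; best of ``restarts`` random initializations.

    Restart seeds are derived from the master seed by counter, so the fit
    is deterministic given ``seed``.  A non-converged best restart is
    returned with ``model.converged = False`` and a warning.
    """
    X = np.asarray(data.trials, dtype=float)
    if not np.all(np.isfinite(X)) or np.any(X < 0):
        raise ValueError("data must be finite and non-negative")
    L, T, M = X.shape
    if not 1 <= K <= T:
        raise ValueError(f"K must be in [1, T={T}], got {K}")
    if not 1 <= N <= M:
        raise ValueError(f"N must be in [1, M={M}], got {N}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    seeds = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    for r in range(restarts):
        rng = np.random.default_rng(seeds[r])
        W_t, A, W_s, trace, converged = _fit_once(X, K, N, rng, tol, max_iter)
        if best is None or trace[-1] < best[3][-1]:
            best = (W_t, A, W_s, trace, converged)
    W_t, A, W_s, trace, converged = best
    if not converged:
        warnings.warn(
            f"best restart did not converge within {max_iter} iterations",
            stacklevel=2,
        )
    W_t, A, W_s = _normalize(W_t, A, W_s)
    model = SpaceByTimeModel(
        W_t=W_t,
        W_s=W_s,
        A=A,
        seed=seed,
        restarts=restarts,
        objective=float(trace[-1]),
        converged=converged,
        n_iter=len(trace) - 1,
    )
    try:
        vaf = compute_vaf(model, data)
    except ValueError:  # zero total variance (e.g. a single trial)
        vaf = np.nan
    return FitResult(
        model=model,
        vaf=vaf,
        reconstruction_error=float(trace[-1]),
        objective_trace=trace,
    )


def compute_vaf(model: SpaceByTimeModel, data: EMGDataset) -> float:
    """Variance accounted for: 1 - total error / total variance.

    Total error is the summed squared Frobenius norm of the residuals;
    total variance is the summed squared deviation of each trial from the
    mean trial pattern.
    """
    X = np.asarray(data.trials, dtype=float)
    R = model.reconstruct()
    if X.shape != R.shape:
        raise ValueError(f"model reconstructs {R.shape}, data is {X.shape}")
    m_bar = X.mean(axis=0)
    total_var = float(np.sum((X - m_bar) ** 2))
    if total_var == 0:
        raise ValueError("all trials identical: total variance is zero, VAF undefined")
    return 1.0 - float(np.sum((X - R) ** 2)) / total_var


def match_components(W_ref: np.ndarray, W_fit: np.ndarray, axis: int = 1):
    """Optimally pair fitted components with reference ones by correlation.

    ``axis=1`` treats columns as components (temporal synergies), ``axis=0``
    rows (spatial synergies).  Returns (ref_idx, fit_idx, correlations)
    from a Hungarian assignment maximizing total correlation.
    """
    if axis == 1:
        ref, fit = W_ref.T, W_fit.T
    else:
        ref, fit = W_ref, W_fit
    n_ref, n_fit = ref.shape[0], fit.shape[0]
    corr = np.zeros((n_ref, n_fit))
    for i in range(n_ref):
        for j in range(n_fit):
            a, b = ref[i], fit[j]
            sa, sb = a.std(), b.std()
            if sa > 0 and sb > 0:
                corr[i, j] = float(np.corrcoef(a, b)[0, 1])
    ref_idx, fit_idx = linear_sum_assignment(-corr)
    return ref_idx, fit_idx, corr[ref_idx, fit_idx]


def decoding_gain_pvalue(
    features: np.ndarray,
    added_columns: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 200,
    seed: int | None = None,
    baseline: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value for the decoding gain contributed by added coefficients.

    The null is built by shuffling, across trials, only the
    ``added_columns`` slice of ``features`` (all other columns untouched),
    which destroys any trial-to-label association carried by the added
    component while preserving its marginal distribution.  The observed
    statistic is the gain of full-feature LOOCV accuracy over ``baseline``
    (the accuracy of the model without the added component); it is
    compared against the mean-centered permutation distribution, which
    guards against the null being miscentered when the enlarged fit
    redistributes task information across components.  With
    ``baseline=None`` the null mean itself is the baseline.  One-sided
    p-value with +1 correction.  Returns (p, observed_percent_correct,
    null_percents).
    """
    features = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    observed = decode_loocv(features, labels).percent_correct
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(features.shape[0])
        shuffled = features.copy()
        shuffled[:, added_columns] = features[perm][:, added_columns]
        null[b] = decode_loocv(shuffled, labels).percent_correct
    center = null.mean()
    gain = observed - (center if baseline is None else baseline)
    p = (1.0 + np.sum(null - center >= gain)) / (n_perm + 1.0)
    return float(p), float(observed), null


def _added_component_index(W_small: np.ndarray, W_big: np.ndarray, axis: int) -> int:
    """Index of the component of the larger fit not matched to the smaller one."""
    _, fit_idx, _ = match_components(W_small, W_big, axis=axis)
    n_big = W_big.shape[axis] if axis == 1 else W_big.shape[0]
    unmatched = sorted(set(range(n_big)) - set(fit_idx.tolist()))
    return unmatched[0]


def select_model_order(
    data: EMGDataset,
    Kmax: int = 10,
    Nmax: int = 10,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed: int | None = None,
    *,
    restarts: int = 50,
    tol: float = 1e-8,
    max_iter: int = 500,
    label_parameter: str = "movement_id",
) -> tuple[int, int]:
    """Smallest (K, N) beyond which adding a synergy gives no significant decoding gain.

    The (K, N) grid is scanned by total K+N then lexicographically.  A
    candidate is accepted when neither (K+1, N) nor (K, N+1) improves
    LOOCV decoding of the task labels significantly under the permutation
    null that shuffles only the added component's coefficients.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if Kmax < 1 or Nmax < 1:
        raise ValueError("grid bounds must be >= 1")
    labels = data.label_values(label_parameter)
    master = np.random.SeedSequence(seed)
    fit_seed, perm_seed = (s.generate_state(1)[0] for s in master.spawn(2))

    cache: dict[tuple[int, int], SpaceByTimeModel] = {}

    def fitted(K: int, N: int) -> SpaceByTimeModel:
        if (K, N) not in cache:
            cache[(K, N)] = fit_space_by_time(
                data,
                K,
                N,
                restarts=restarts,
                tol=tol,
                max_iter=max_iter,
                seed=int(fit_seed) + 1000 * K + N,
            ).model
        return cache[(K, N)]

    def increment_significant(K: int, N: int, grow_temporal: bool, counter: int) -> bool:
        small = fitted(K, N)
        big = fitted(K + 1, N) if grow_temporal else fitted(K, N + 1)
        if grow_temporal:
            added = _added_component_index(small.W_t, big.W_t, axis=1)
            cols = np.arange(added * big.N, (added + 1) * big.N)
        else:
            added = _added_component_index(small.W_s, big.W_s, axis=0)
            cols = np.arange(added, big.K * big.N, big.N)
        feats = big.A.reshape(big.A.shape[0], -1)
        baseline = decode_loocv(
            small.A.reshape(small.A.shape[0], -1), labels
        ).percent_correct
        p, _, _ = decoding_gain_pvalue(
            feats, cols, labels, n_perm=n_perm,
            seed=int(perm_seed) + counter, baseline=baseline,
        )
        return p <= alpha

    candidates = sorted(
        ((K, N) for K in range(1, Kmax + 1) for N in range(1, Nmax + 1)),
        key=lambda kn: (kn[0] + kn[1], kn),
    )
    counter = 0
    for K, N in candidates:
        significant = False
        if K + 1 <= Kmax:
            counter += 1
            significant |= increment_significant(K, N, True, counter)
        if not significant and N + 1 <= Nmax:
            counter += 1
            significant |= increment_significant(K, N, False, counter)
        if not significant:
            return K, N
    warnings.warn(
        "grid exhausted without a decoding plateau; returning grid boundary",
        stacklevel=2,
    )
    return Kmax, Nmax
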