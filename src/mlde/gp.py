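"""Gaussian-process regression on variant feature vectors.

The model is a zero-mean GP with a squared-exponential kernel and i.i.d.
Gaussian observation noise,

    k(x, x') = sigma_f^2 * exp(-||x - x'||^2 / (2 * l^2)),
    y ~ N(0, K + sigma_n^2 I),

fit by the standard Cholesky route: factor K + sigma_n^2 I = L L^T, get
the weight vector alpha by two triangular solves, and read the log
marginal likelihood off the factor,

    log p(y) = -1/2 y^T alpha - sum_i log L_ii - n/2 log 2 pi.

Predictions are mean k_*^T alpha and latent variance
k(x_*, x_*) - v^T v with v = solve(L, k_*).  Hyperparameters
(sigma_f^2, l, sigma_n^2) can be given explicitly or optimized by
multi-start gradient-based maximization of the log marginal likelihood
in log-parameter space.

Cross-validation follows the screening practice of this kind of
sequence-activity campaign: seeded shuffled k-fold (10 splits by
default), hyperparameters re-optimized per fold, held-out performance
scored by the coefficient of determination R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, cho_solve, solve_triangular
from scipy.optimize import minimize

from .encoding import TrainingMatrix

_LOG_BOUNDS = {
    "sigma_f2": (np.log(1e-8), np.log(1e3)),
    "length_scale": (np.log(1e-2), np.log(1e3)),
    "sigma_n2": (np.log(1e-8), np.log(1e3)),
}

_JITTER_START = 1e-10
_JITTER_MAX = 1e-6


@dataclass(frozen=True)
class GPHyperparameters:
    """Kernel hyperparameters: signal variance, length scale, noise variance."""

    sigma_f2: float = 1.0
    length_scale: float = 1.0
    sigma_n2: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_f2 < 0 or self.sigma_n2 < 0:
            raise ValueError("variances must be >= 0")
        if self.length_scale <= 0:
            raise ValueError("length scale must be > 0")


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at 0."""
    aa = np.sum(A * A, axis=1)[:, None]
    bb = np.sum(B * B, axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * A @ B.T, 0.0)


def se_kernel(A: np.ndarray, B: np.ndarray, hyper: GPHyperparameters) -> np.ndarray:
    """Squared-exponential kernel matrix between two point sets."""
    return hyper.sigma_f2 * np.exp(-0.5 * _sqdist(A, B) / hyper.length_scale**2)


@dataclass
class GPModel:
    """Fitted GP state: training data, Cholesky factor, weights, evidence."""

    X: np.ndarray
    y: np.ndarray
    hyper: GPHyperparameters
    L: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)
    log_marginal_likelihood: float = float("nan")
    jitter: float = 0.0
    variant_names: tuple[str, ...] | None = None


def _chol_with_jitter(Ky: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor, escalating a diagonal jitter if needed."""
    try:
        return cholesky(Ky, lower=True), 0.0
    except np.linalg.LinAlgError:
        pass
    jitter = _JITTER_START
    while jitter <= _JITTER_MAX:
        try:
            L = cholesky(Ky + jitter * np.eye(Ky.shape[0]), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"kernel matrix not positive definite even with jitter up to {_JITTER_MAX:g}"
    )


def _lml_and_grad(
    log_theta: np.ndarray, D2: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood and its gradient in log-parameters."""
    n = y.size
    sf2, ell, sn2 = np.exp(log_theta)
    Kse = sf2 * np.exp(-0.5 * D2 / ell**2)
    Ky = Kse + sn2 * np.eye(n)
    try:
        L, _ = _chol_with_jitter(Ky)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(3)
    alpha = cho_solve((L, True), y)
    lml = -0.5 * float(y @ alpha) - float(np.sum(np.log(np.diag(L)))) - 0.5 * n * np.log(2 * np.pi)
    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # d lml / dK = W / 2
    # derivatives of K wrt log-parameters
    dK_dlog_sf2 = Kse
    dK_dlog_ell = Kse * (D2 / ell**2)
    grad = 0.5 * np.array(
        [
            np.sum(W * dK_dlog_sf2),
            np.sum(W * dK_dlog_ell),
            sn2 * np.trace(W),
        ]
    )
    return -lml, -grad


def _optimize_hyperparameters(
    X: np.ndarray, y: np.ndarray, seed: int, restarts: int
) -> GPHyperparameters:
    D2 = _sqdist(X, X)
    rng = np.random.default_rng(seed)
    bounds = [_LOG_BOUNDS["sigma_f2"], _LOG_BOUNDS["length_scale"], _LOG_BOUNDS["sigma_n2"]]

    # data-driven default start: signal at the label variance, length scale
    # at the median pairwise distance, noise at a tenth of the variance
    var_y = max(float(np.var(y)), 1e-6)
    off_diag = D2[np.triu_indices_from(D2, k=1)]
    med = float(np.sqrt(np.median(off_diag))) if off_diag.size else 1.0
    med = med if med > 0 else 1.0
    starts = [np.log([var_y, med, 0.1 * var_y])]
    for _ in range(restarts):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            _lml_and_grad,
            x0,
            args=(D2, y),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    sf2, ell, sn2 = np.exp(best.x)
    return GPHyperparameters(sigma_f2=float(sf2), length_scale=float(ell), sigma_n2=float(sn2))


def _coerce_xy(matrix) -> tuple[np.ndarray, np.ndarray, tuple[str, ...] | None]:
    if isinstance(matrix, TrainingMatrix):
        return matrix.X, matrix.y, matrix.variant_names
    X, y = matrix
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float), None


def fit_gp(
    matrix,
    hyperparameters: GPHyperparameters | str = "optimize",
    seed: int = 0,
    restarts: int = 5,
) -> GPModel:
    """Fit the GP to a training matrix (or an ``(X, y)`` pair).

    With ``hyperparameters="optimize"`` the log marginal likelihood is
    maximized over (sigma_f^2, l, sigma_n^2) by L-BFGS with analytic
    gradients from ``restarts`` seeded random starts plus one
    data-driven start.
    """
    X, y, names = _coerce_xy(matrix)
    X = np.atleast_2d(X)
    if X.shape[0] < 1:
        raise ValueError("need at least one training point")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")

    if isinstance(hyperparameters, str):
        if hyperparameters != "optimize":
            raise ValueError(f"unknown hyperparameter mode {hyperparameters!r}")
        if X.shape[0] < 2:
            raise ValueError("hyperparameter optimization needs n >= 2")
        hyper = _optimize_hyperparameters(X, y, seed=seed, restarts=restarts)
    else:
        hyper = hyperparameters

    K = se_kernel(X, X, hyper)
    Ky = K + hyper.sigma_n2 * np.eye(X.shape[0])
    L, jitter = _chol_with_jitter(Ky)
    alpha = cho_solve((L, True), y)
    lml = (
        -0.5 * float(y @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * y.size * np.log(2 * np.pi)
    )
    return GPModel(
        X=X, y=y, hyper=hyper, L=L, alpha=alpha,
        log_marginal_likelihood=lml, jitter=jitter, variant_names=names,
    )


def predict(model: GPModel, candidates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and latent variance per candidate row.

    Variances are clipped to zero from tiny negative round-off (beyond
    -1e-10 would indicate a numerical fault and raises).
    """
    Xs = np.atleast_2d(np.asarray(candidates, dtype=float))
    if Xs.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"candidate dimensionality {Xs.shape[1]} does not match "
            f"training dimensionality {model.X.shape[1]}"
        )
    Ks = se_kernel(model.X, Xs, model.hyper)  # n x m
    mean = Ks.T @ model.alpha
    v = solve_triangular(model.L, Ks, lower=True)
    var = model.hyper.sigma_f2 - np.sum(v * v, axis=0)
    if np.any(var < -1e-10):
        raise FloatingPointError(f"negative predictive variance {var.min():g}")
    return mean, np.maximum(var, 0.0)


@dataclass(frozen=True)
class CVReport:
    """Per-fold and mean held-out R^2 of a seeded shuffled k-fold run."""

    fold_r2: tuple[float, ...]       # NaN for folds with undefined R^2
    mean_r2: float
    assignments: tuple[tuple[int, ...], ...]
    seed: int
    flags: tuple[str, ...] = ()

    @property
    def n_folds(self) -> int:
        return len(self.fold_r2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold": range(len(self.fold_r2)), "r_squared": self.fold_r2}
        )


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination; NaN when the truth has no variance."""
    y_true = np.asarray(y_true, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def cross_validate(
    matrix,
    k: int = 10,
    seed: int = 0,
    hyperparameters: GPHyperparameters | str = "optimize",
    restarts: int = 2,
) -> CVReport:
    """Seeded shuffled k-fold cross-validation with per-fold refitting.

    Each fold is held out in turn; the GP is refit (hyperparameters
    re-optimized unless given explicitly) on the remainder and scored by
    held-out R^2.  Folds whose held-out labels have zero variance get an
    undefined R^2, reported as NaN, flagged, and excluded from the mean.
    """
    X, y, _ = _coerce_xy(matrix)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need n >= k folds, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [np.sort(chunk) for chunk in np.array_split(order, k)]

    scores: list[float] = []
    flags: list[str] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = fit_gp(
            (X[train_idx], y[train_idx]),
            hyperparameters=hyperparameters,
            seed=seed + i,
            restarts=restarts,
        )
        pred, _ = predict(model, X[test_idx])
        r2 = r_squared(y[test_idx], pred)
        if np.isnan(r2):
            flags.append(f"fold {i}: zero label variance, R^2 undefined")
        scores.append(r2)

    valid = [s for s in scores if not np.isnan(s)]
    mean = float(np.mean(valid)) if valid else float("nan")
    return CVReport(
        fold_r2=tuple(scores),
        mean_r2=mean,
        assignments=tuple(tuple(int(j) for j in f) for f in folds),
        seed=seed,
        flags=tuple(flags),
    )


def rank_candidates(
    model: GPModel,
    candidates: pd.DataFrame | tuple[Sequence[str], np.ndarray],
) -> pd.DataFrame:
    """Rank candidates by descending predictive mean.

    Ties are broken lexicographically by variant name.  ``candidates``
    is either a DataFrame of features indexed by variant name or a
    ``(names, X)`` pair.  Returns a DataFrame with columns
    ``predicted_mean``, ``predicted_variance`` and ``rank`` (1-based).
    """
    if isinstance(candidates, pd.DataFrame):
        names = [str(i) for i in candidates.index]
        X = candidates.to_numpy(dtype=float)
    else:
        names, X = candidates
        names = [str(n) for n in names]
        X = np.asarray(X, dtype=float)
    if len(names) != X.shape[0]:
        raise ValueError("one name per candidate row required")
    mean, var = predict(model, X)
    df = pd.DataFrame(
        {"variant_name": names, "predicted_mean": mean, "predicted_variance": var}
    )
    df = df.sort_values(
        by=["predicted_mean", "variant_name"], ascending=[False, True], kind="mergesort"
    ).set_index("variant_name")
    df["rank"] = np.arange(1, len(df) + 1)
    return df
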