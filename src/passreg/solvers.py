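"""Weighted-l1 penalized linear and logistic regression.

Per-coefficient penalty factors (0 = unpenalized, +inf = excluded) on top of a
global level ``lambda``; regularization paths with warm starts; BIC and
cross-validated selection.  Objectives:

linear:    (1/n) sum_i (y_i - b - x_i'w)^2        + lam * sum_j f_j |w_j|
logistic:  (1/n) sum_i [-y_i eta_i + log(1+e^eta)] + lam * sum_j f_j |w_j|

When ``standardize=True`` (default) penalized columns are scaled to unit
sample standard deviation internally, which is equivalent to replacing the
factor f_j by f_j * sd_j in the original coordinates; coefficients are always
returned on the original scale.  Unpenalized columns are never rescaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._cd import _logistic_cd, _wls_cd

__all__ = [
    "PenaltySpec",
    "SolverFit",
    "SelectionReport",
    "fit_l1_linear",
    "fit_l1_logistic",
    "lambda_max",
    "default_lambda_grid",
    "select_by_bic",
    "select_by_cv",
    "stratified_folds",
    "logistic_loss",
]

MAX_PASSES = 100_000
TOL = 1e-7


def logistic_loss(y, eta):
    """Negative log-likelihood terms -y*eta + log(1 + e^eta), elementwise."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return np.logaddexp(0.0, eta) - y * eta


@dataclass
class PenaltySpec:
    """Global penalty level plus one factor per penalizable coefficient."""

    lam: float
    factors: np.ndarray

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if np.any(self.factors < 0):
            raise ValueError("penalty factors must be nonnegative")


@dataclass
class SolverFit:
    intercept: float
    coefs: np.ndarray
    objective: float
    converged: bool
    kkt_violation: float
    n_passes: int = 0


@dataclass
class SelectionReport:
    grid: list
    criterion_values: np.ndarray
    chosen_index: int
    fold_seed: Optional[int] = None
    extras: dict = field(default_factory=dict)

    @property
    def chosen(self):
        return self.grid[self.chosen_index]


def _as_design(X):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite entries")
    return X


def _prepare(X, factors, standardize):
    """Scale penalized finite-factor columns to unit SD; return (Xs, scales)."""
    scales = np.ones(X.shape[1])
    if standardize:
        penalized = np.isfinite(factors) & (factors > 0)
        if penalized.any():
            sd = X[:, penalized].std(axis=0)
            sd[sd == 0] = 1.0
            scales[penalized] = sd
    Xs = np.asfortranarray(X / scales)
    return Xs, scales


def _kkt_violation(Xs, grad, w_scaled, lam, factors):
    """Max stationarity violation on the (possibly standardized) problem."""
    viol = 0.0
    for j in range(Xs.shape[1]):
        f = factors[j]
        if np.isinf(f):
            continue
        if w_scaled[j] != 0.0:
            v = abs(grad[j] + lam * f * np.sign(w_scaled[j]))
        else:
            v = max(abs(grad[j]) - lam * f, 0.0)
        viol = max(viol, v)
    return viol


def _linear_objective(X, y, w, b, lam, factors):
    r = y - b - X @ w
    finite = np.isfinite(factors)
    pen = lam * np.sum(factors[finite] * np.abs(w[finite]))
    return float(np.mean(r**2) + pen)


def _logistic_objective_np(X, y, w, b, lam, factors):
    eta = b + X @ w
    finite = np.isfinite(factors)
    pen = lam * np.sum(factors[finite] * np.abs(w[finite]))
    return float(np.mean(logistic_loss(y, eta)) + pen)


def fit_l1_linear(
    X,
    y,
    penalty: PenaltySpec,
    standardize: bool = True,
    tol: float = TOL,
    max_passes: int = MAX_PASSES,
    warm_start: Optional[np.ndarray] = None,
) -> SolverFit:
    X = _as_design(X)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite entries")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    factors = penalty.factors
    if factors.shape[0] != X.shape[1]:
        raise ValueError("factors length must equal number of columns")
    Xs, scales = _prepare(X, factors, standardize)
    w = np.zeros(X.shape[1]) if warm_start is None else warm_start * scales
    v = np.full(X.shape[0], 2.0)  # v=2 makes the WLS objective (1/n) sum (.)^2
    b, passes = _wls_cd(Xs, y, v, penalty.lam, factors, w, 0.0, tol, max_passes)
    r = y - b - Xs @ w
    grad = -(2.0 / X.shape[0]) * (Xs.T @ r)
    kkt = _kkt_violation(Xs, grad, w, penalty.lam, factors)
    coefs = w / scales
    obj = _linear_objective(X, y, coefs, b, penalty.lam, factors * scales)
    return SolverFit(float(b), coefs, obj, passes < max_passes, kkt, passes)


def fit_l1_logistic(
    X,
    y,
    penalty: PenaltySpec,
    standardize: bool = True,
    tol: float = TOL,
    max_passes: int = MAX_PASSES,
    warm_start: Optional[np.ndarray] = None,
    allow_fractional: bool = False,
) -> SolverFit:
    X = _as_design(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if allow_fractional:
        if np.any((y < 0) | (y > 1)):
            raise ValueError("fractional responses must lie in [0, 1]")
    else:
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("y must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("y contains a single class (separation)")
    factors = penalty.factors
    if factors.shape[0] != X.shape[1]:
        raise ValueError("factors length must equal number of columns")
    Xs, scales = _prepare(X, factors, standardize)
    w = np.zeros(X.shape[1]) if warm_start is None else warm_start * scales
    b, passes, status = _logistic_cd(
        Xs, y, penalty.lam, factors, w, 0.0, tol, 200, max_passes
    )
    if status == 2 or (status == 1 and float(np.max(np.abs(w), initial=0.0)) > 30.0):
        warnings.warn(
            "logistic fit hit the divergence guard (near-perfect separation); "
            "coefficient norms are capped by the solver",
            RuntimeWarning,
        )
    eta = b + Xs @ w
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    grad = (Xs.T @ (mu - y)) / X.shape[0]
    kkt = _kkt_violation(Xs, grad, w, penalty.lam, factors)
    coefs = w / scales
    obj = _logistic_objective_np(X, y, coefs, b, penalty.lam, factors * scales)
    return SolverFit(float(b), coefs, obj, status == 0, kkt, passes)


def _null_fit(X, y, factors, family, standardize):
    """Fit with penalized coordinates excluded, unpenalized ones free."""
    restricted = np.where(factors == 0.0, 0.0, np.inf)
    spec = PenaltySpec(1.0, restricted)
    if family == "linear":
        return fit_l1_linear(X, y, spec, standardize=standardize)
    return fit_l1_logistic(X, y, spec, standardize=standardize, allow_fractional=True)


def lambda_max(X, y, factors, family: str = "linear", standardize: bool = True) -> float:
    """Smallest lambda at which every penalized coefficient is exactly zero.

    Computed from the KKT conditions at the fit that includes only the
    unpenalized columns (and the intercept).
    """
    X = _as_design(X)
    y = np.asarray(y, dtype=float)
    factors = np.asarray(factors, dtype=float)
    penalized = np.isfinite(factors) & (factors > 0)
    if not penalized.any():
        raise ValueError("lambda_max undefined: no penalized coordinate")
    fit = _null_fit(X, y, factors, family, standardize)
    Xs, _ = _prepare(X, factors, standardize)
    n = X.shape[0]
    if family == "linear":
        r = y - fit.intercept - X @ fit.coefs
        grad = np.abs(2.0 / n * (Xs.T @ r))
    else:
        eta = fit.intercept + X @ fit.coefs
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = np.abs((Xs.T @ (mu - y)) / n)
    return float(np.max(grad[penalized] / factors[penalized]))


def default_lambda_grid(
    lam_max: float, family: str = "linear", n_lambda: int = 100
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to a family-specific floor."""
    ratio = 0.001 if family == "linear" else 0.01
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def fit_path(
    X,
    y,
    lambdas: Sequence[float],
    factors,
    family: str = "logistic",
    standardize: bool = True,
    tol: float = TOL,
    allow_fractional: bool = False,
):
    """Warm-started fits along a descending lambda grid.

    Returns (intercepts, coef_matrix) with coef_matrix of shape (p, len(lambdas)),
    coefficients on the original scale.
    """
    X = _as_design(X)
    y = np.asarray(y, dtype=float)
    factors = np.asarray(factors, dtype=float)
    p = X.shape[1]
    L = len(lambdas)
    intercepts = np.zeros(L)
    coefs = np.zeros((p, L))
    # standardize once; warm starts stay on the scaled problem
    Xs, scales = _prepare(X, factors, standardize)
    w = np.zeros(p)
    b = 0.0
    v = np.full(X.shape[0], 2.0)
    for k, lam in enumerate(lambdas):
        if family == "linear":
            b, _ = _wls_cd(Xs, y, v, float(lam), factors, w, b, tol, MAX_PASSES)
        else:
            b, _, status = _logistic_cd(Xs, y, float(lam), factors, w, b, tol,
                                        100, MAX_PASSES)
        intercepts[k] = b
        coefs[:, k] = w / scales
        if family == "logistic" and k + 1 < L:
            # freeze the path once the training fit saturates (near-perfect
            # fit or the separation guard): smaller lambdas add nothing
            train_loss = float(np.mean(logistic_loss(y, b + Xs @ w)))
            if train_loss < 1e-3 or status == 2:
                intercepts[k + 1:] = b
                coefs[:, k + 1:] = coefs[:, [k]]
                break
    return intercepts, coefs


def select_by_bic(
    X,
    y,
    factors,
    grid: Sequence[float],
    family: str = "linear",
    standardize: bool = True,
    tol: float = TOL,
) -> SelectionReport:
    """BIC selection along a descending penalty grid.

    Linear family: BIC = N log(RSS/N) + df log N, df = number of nonzero
    coefficients.  Logistic: BIC = 2 * sum ell + df log N.  Ties go to the
    larger penalty (grids are descending, so the earliest minimizer).
    """
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("empty grid")
    if any(grid[i] < grid[i + 1] for i in range(len(grid) - 1)):
        raise ValueError("grid must be descending")
    X = _as_design(X)
    y = np.asarray(y, dtype=float)
    intercepts, coefs = fit_path(X, y, grid, factors, family, standardize, tol)
    N = X.shape[0]
    crit = np.empty(len(grid))
    for k in range(len(grid)):
        eta = intercepts[k] + X @ coefs[:, k]
        df = int(np.count_nonzero(coefs[:, k]))
        if family == "linear":
            rss = float(np.sum((y - eta) ** 2))
            if rss <= 0:
                warnings.warn("zero residual sum of squares in BIC", RuntimeWarning)
                crit[k] = -np.inf
            else:
                crit[k] = N * np.log(rss / N) + df * np.log(N)
        else:
            crit[k] = 2.0 * float(np.sum(logistic_loss(y, eta))) + df * np.log(N)
    chosen = int(np.argmin(crit))  # first minimizer = largest lambda
    return SelectionReport(
        grid=grid,
        criterion_values=crit,
        chosen_index=chosen,
        extras={"intercepts": intercepts, "coefs": coefs},
    )


def stratified_folds(y, k_folds: int, seed: int, stratify: bool = True):
    """Seeded fold assignment; stratified round-robin over classes when asked.

    Returns an integer array of fold labels in {0, ..., k_folds-1}.
    """
    y = np.asarray(y)
    n = y.shape[0]
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify:
        classes = np.unique(y)
        offset = 0
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            assignment[idx] = (np.arange(idx.size) + offset) % k_folds
            offset += idx.size
    else:
        idx = rng.permutation(n)
        assignment[idx] = np.arange(n) % k_folds
    return assignment


def select_by_cv(
    X,
    y,
    candidates: Sequence[dict],
    k_folds: int,
    seed: int,
    family: str = "logistic",
    loss: str = "deviance",
    standardize: bool = True,
    tol: float = TOL,
    y_train=None,
) -> SelectionReport:
    """K-fold cross-validated selection over arbitrary (lambda, factors) candidates.

    Each candidate is a dict with keys ``lam`` and ``factors`` plus optional
    ``tie`` (tuple used for tie-breaking: the lexicographically largest tuple
    among loss minimizers wins).  Candidates sharing the same ``factors``
    object and listed in descending ``lam`` order are warm-started.

    ``y_train`` optionally supplies a different (possibly fractional) training
    response per candidate (dict key ``y``), while held-out loss is always
    measured against ``y``.  Folds are stratified by ``y`` for the logistic
    family.
    """
    X = _as_design(X)
    y = np.asarray(y, dtype=float)
    if family == "logistic":
        counts = np.unique(y, return_counts=True)[1]
        if counts.min() < k_folds:
            raise ValueError(
                "cannot stratify: the rarest class has fewer members than folds"
            )
    folds = stratified_folds(y, k_folds, seed, stratify=family == "logistic")
    L = len(candidates)
    losses = np.zeros((k_folds, L))
    from sklearn.metrics import roc_auc_score

    for f in range(k_folds):
        tr = folds != f
        te = ~tr
        Xtr, Xte, yte = X[tr], X[te], y[te]
        warm = None
        prev_key = None
        saturated = False
        for k, cand in enumerate(candidates):
            factors = cand["factors"]
            ytr = cand["y"][tr] if "y" in cand else y[tr]
            key = (id(factors), id(cand.get("y")))
            if key != prev_key:
                # warm starts and saturation only persist within one path
                warm = None
                saturated = False
                prev_key = key
            if saturated:
                # deeper lambdas on a saturated path refit the same model
                losses[f, k] = losses[f, k - 1]
                continue
            spec = PenaltySpec(float(cand["lam"]), factors)
            if family == "linear":
                fit = fit_l1_linear(
                    Xtr, ytr, spec, standardize=standardize, tol=tol, warm_start=warm
                )
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    fit = fit_l1_logistic(
                        Xtr, ytr, spec, standardize=standardize, tol=tol,
                        warm_start=warm, allow_fractional=True,
                    )
                train_eta = fit.intercept + Xtr @ fit.coefs
                if (float(np.mean(logistic_loss(ytr, train_eta))) < 1e-3
                        or np.sum(fit.coefs**2) > 1e8):
                    saturated = True
            warm = fit.coefs
            eta = fit.intercept + Xte @ fit.coefs
            if family == "linear":
                losses[f, k] = float(np.mean((y[te] - eta) ** 2))
            elif loss == "auc":
                losses[f, k] = 1.0 - roc_auc_score(yte, eta)
            else:
                losses[f, k] = float(np.mean(logistic_loss(yte, eta)))
    mean_loss = losses.mean(axis=0)
    best = np.min(mean_loss)
    minimizers = np.flatnonzero(mean_loss == best)
    if minimizers.size > 1:
        # the candidate whose tie tuple is lexicographically largest wins
        ties = [candidates[i].get("tie", (candidates[i]["lam"],)) for i in minimizers]
        chosen = int(minimizers[max(range(len(ties)), key=lambda i: ties[i])])
    else:
        chosen = int(minimizers[0])
    return SelectionReport(
        grid=list(candidates),
        criterion_values=mean_loss,
        chosen_index=chosen,
        fold_seed=seed,
        extras={"fold_losses": losses},
    )
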