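"""Comparison estimators: supervised LASSO/ALASSO, the prior-based
semi-supervised fit (ssprior), two prior-LASSO variants, and the
extreme-tail unsupervised LASSO with its semi-supervised variant."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .data import LabeledSet, ModelCoefficients
from .solvers import (
    SelectionReport,
    default_lambda_grid,
    fit_path,
    lambda_max,
    logistic_loss,
    select_by_cv,
    stratified_folds,
)
from .surrogate import SurrogateFit

__all__ = [
    "BenchmarkFit",
    "fit_lasso",
    "fit_alasso",
    "fit_ss_prior",
    "fit_plasso",
    "fit_ulasso",
    "fit_ss_ulasso",
]

ETA_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class BenchmarkFit:
    method: str
    coefficients: ModelCoefficients
    extras: dict = field(default_factory=dict)

    def predict_proba(self, S, X):
        return self.coefficients.predict_proba(S, X)

    def to_json(self) -> str:
        c = self.coefficients
        idx = np.flatnonzero(c.beta)
        return json.dumps(
            {
                "method": self.method,
                "zeta": c.zeta,
                "gamma": c.gamma,
                "p": int(c.beta.shape[0]),
                "beta": {int(j): float(c.beta[j]) for j in idx},
            }
        )


def _sx_design(labeled: LabeledSet):
    return np.column_stack([labeled.S, labeled.X])


def _cv_l1_logistic(D, y, factors, lambda_grid, n_lambda, k_folds, seed,
                    standardize, loss, tol=1e-7):
    if lambda_grid is None:
        lmax = lambda_max(D, y, factors, family="logistic", standardize=standardize)
        lambda_grid = default_lambda_grid(lmax, "logistic", n_lambda)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    candidates = [{"lam": float(l), "factors": factors} for l in lambda_grid]
    if len(candidates) > 1:
        # loose tolerance for fold fits (selection only); tight for the refit
        report = select_by_cv(D, y, candidates, k_folds=k_folds, seed=seed,
                              family="logistic", loss=loss,
                              standardize=standardize, tol=max(tol, 3e-5))
        chosen_index = report.chosen_index
    else:
        report, chosen_index = None, 0
    lam = candidates[chosen_index]["lam"]
    lams = [c["lam"] for c in candidates[: chosen_index + 1]]
    intercepts, coefs = fit_path(D, y, lams, factors, family="logistic",
                                 standardize=standardize, tol=tol)
    return float(intercepts[-1]), coefs[:, -1], lam, report


def fit_lasso(
    labeled: LabeledSet,
    lambda_grid=None,
    n_lambda: int = 100,
    k_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    loss: str = "deviance",
    tol: float = 1e-7,
) -> BenchmarkFit:
    """CV-tuned l1 logistic regression of Y on (S, X); only beta is penalized."""
    if labeled.Y.min() == labeled.Y.max():
        raise ValueError("labeled outcome has a single class")
    D = _sx_design(labeled)
    factors = np.concatenate([[0.0], np.ones(labeled.p)])
    b, w, lam, report = _cv_l1_logistic(
        D, labeled.Y, factors, lambda_grid, n_lambda, k_folds, seed,
        standardize, loss, tol
    )
    return BenchmarkFit(
        "lasso",
        ModelCoefficients(b, float(w[0]), w[1:].copy()),
        extras={"lambda": lam, "cv_report": report},
    )


def fit_alasso(
    labeled: LabeledSet,
    nu: float = 1.0,
    lambda_grid=None,
    n_lambda: int = 100,
    k_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    loss: str = "deviance",
) -> BenchmarkFit:
    """Adaptive LASSO: weights |beta_init|^(-nu) from a CV-tuned LASSO initializer."""
    init = fit_lasso(labeled, lambda_grid, n_lambda, k_folds, seed, standardize, loss)
    beta_init = init.coefficients.beta
    nz = beta_init != 0
    if not nz.any():
        warnings.warn(
            "LASSO initializer is empty; returning the intercept+surrogate model",
            RuntimeWarning,
        )
        zeta, coef, _ = _unpenalized_logistic(
            labeled.S[:, None], labeled.Y
        )
        return BenchmarkFit(
            "alasso",
            ModelCoefficients(zeta, float(coef[0]), np.zeros(labeled.p)),
            extras={"empty_init": True},
        )
    weights = np.full(labeled.p, np.inf)
    weights[nz] = np.abs(beta_init[nz]) ** (-nu)
    D = _sx_design(labeled)
    factors = np.concatenate([[0.0], weights])
    b, w, lam, report = _cv_l1_logistic(
        D, labeled.Y, factors, None, n_lambda, k_folds, seed, standardize, loss
    )
    return BenchmarkFit(
        "alasso",
        ModelCoefficients(b, float(w[0]), w[1:].copy()),
        extras={"lambda": lam, "nu": nu, "cv_report": report,
                "init_lambda": init.extras["lambda"]},
    )


def _unpenalized_logistic(D, y, ridge: float = 0.0):
    """Low-dimensional logistic MLE via BFGS; returns (intercept, coefs, converged)."""
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = D.shape

    def fg(theta):
        b, w = theta[0], theta[1:]
        eta = b + D @ w
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        f = float(np.mean(logistic_loss(y, eta))) + 0.5 * ridge * float(w @ w)
        g = np.empty(q + 1)
        g[0] = float(np.mean(mu - y))
        g[1:] = D.T @ (mu - y) / n + ridge * w
        return f, g

    res = minimize(fg, np.zeros(q + 1), jac=True, method="L-BFGS-B",
                   options={"gtol": 1e-9, "ftol": 1e-14, "maxiter": 5000})
    grad_norm = float(np.max(np.abs(fg(res.x)[1])))
    return float(res.x[0]), res.x[1:], grad_norm < 1e-5


def fit_ss_prior(labeled: LabeledSet, surrogate: SurrogateFit) -> BenchmarkFit:
    """Unpenalized 3-parameter logistic fit of Y on (1, S, X'alpha_hat).

    Valid when the surrogate direction recovers the direction of beta; the
    reported beta is rho_hat * alpha_hat.  Separation triggers a
    ridge-stabilized fallback.
    """
    xa = labeled.X @ surrogate.alpha
    D = np.column_stack([labeled.S, xa])
    zeta, coef, ok = _unpenalized_logistic(D, labeled.Y)
    if not ok or np.max(np.abs(coef)) > 50:
        warnings.warn("separation in the 3-parameter prior fit; using a small "
                      "ridge penalty", RuntimeWarning)
        zeta, coef, _ = _unpenalized_logistic(D, labeled.Y, ridge=1e-4)
    gamma, rho = float(coef[0]), float(coef[1])
    return BenchmarkFit(
        "ssprior",
        ModelCoefficients(zeta, gamma, rho * surrogate.alpha),
        extras={"rho": rho},
    )


def fit_plasso(
    labeled: LabeledSet,
    surrogate: SurrogateFit,
    variant: int,
    eta_grid: Sequence[float] = ETA_GRID,
    lambda_grid=None,
    n_lambda: int = 100,
    k_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    loss: str = "deviance",
) -> BenchmarkFit:
    """Prior LASSO: adds a pseudo-likelihood term on prior probabilities Y^p.

    variant 1 builds Y^p from a penalized logistic fit of Y on (S, X) with the
    l1 penalty imposed only on predictors outside the surrogate support;
    variant 2 uses the predicted probabilities of :func:`fit_ss_prior`.  The
    weight eta and level lambda are tuned jointly by shared-fold CV.  Since
    the logistic loss is linear in the response, the combined objective equals
    (1 + eta) times a logistic fit on the blended fractional response
    (Y + eta * Y^p) / (1 + eta) at level lambda / (1 + eta).
    """
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    D = _sx_design(labeled)
    y = labeled.Y
    n, p = labeled.n, labeled.p

    if variant == 1:
        q = surrogate.support.size
        if q >= n:
            raise ValueError(
                f"variant-1 prior model needs an unpenalized fit on the "
                f"surrogate support ({q} features) which is infeasible with "
                f"n={n} labeled rows"
            )
        on = np.zeros(p, dtype=bool)
        on[surrogate.support] = True
        prior_factors = np.concatenate([[0.0], np.where(on, 0.0, 1.0)])
        b0, w0, lam0, _ = _cv_l1_logistic(
            D, y, prior_factors, None, n_lambda, k_folds, seed, standardize, loss
        )
        yp = 1.0 / (1.0 + np.exp(-(b0 + D @ w0)))
        prior_extras = {"prior_lambda": lam0}
    else:
        ss = fit_ss_prior(labeled, surrogate)
        yp = ss.predict_proba(labeled.S, labeled.X)
        prior_extras = {"prior_rho": ss.extras["rho"]}

    factors = np.concatenate([[0.0], np.ones(p)])
    etas = sorted(eta_grid)
    blends, grids = {}, {}
    for eta in etas:
        yb = (y + eta * yp) / (1.0 + eta)
        blends[eta] = yb
        if lambda_grid is None:
            lmax_b = lambda_max(D, yb, factors, family="logistic",
                                standardize=standardize)
            grids[eta] = (1.0 + eta) * default_lambda_grid(lmax_b, "logistic",
                                                           n_lambda)
        else:
            grids[eta] = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    # shared folds: tune lambda within each eta by the held-out joint
    # (likelihood + eta * pseudo-likelihood) loss, then pick eta by the
    # held-out real-Y deviance at its tuned lambda
    folds = stratified_folds(y, k_folds, seed, stratify=True)
    L = max(len(grids[eta]) for eta in etas)
    joint_loss = {eta: np.zeros((k_folds, len(grids[eta]))) for eta in etas}
    real_loss = {eta: np.zeros((k_folds, len(grids[eta]))) for eta in etas}
    for f in range(k_folds):
        tr = folds != f
        te = ~tr
        for eta in etas:
            yb = blends[eta]
            lams = grids[eta] / (1.0 + eta)
            intercepts, coefs = fit_path(
                D[tr], yb[tr], lams, factors, family="logistic",
                standardize=standardize, allow_fractional=True, tol=3e-5,
            )
            eta_te = intercepts[None, :] + D[te] @ coefs
            real = logistic_loss(y[te][:, None], eta_te).mean(axis=0)
            joint = (1.0 + eta) * logistic_loss(yb[te][:, None], eta_te).mean(axis=0)
            joint_loss[eta][f] = joint
            real_loss[eta][f] = real
    lam_idx = {eta: int(np.argmin(joint_loss[eta].mean(axis=0))) for eta in etas}
    eta_scores = [real_loss[eta].mean(axis=0)[lam_idx[eta]] for eta in etas]
    eta_star = etas[int(np.argmin(eta_scores))]
    k_star = lam_idx[eta_star]
    lam_star = float(grids[eta_star][k_star])
    intercepts, coefs = fit_path(
        D, blends[eta_star], grids[eta_star][: k_star + 1] / (1.0 + eta_star),
        factors, family="logistic", standardize=standardize,
        allow_fractional=True,
    )
    b, w = float(intercepts[-1]), coefs[:, -1]
    report = SelectionReport(
        grid=[{"eta": e, "lambda": float(grids[e][lam_idx[e]])} for e in etas],
        criterion_values=np.asarray(eta_scores),
        chosen_index=etas.index(eta_star),
        fold_seed=seed,
    )
    return BenchmarkFit(
        f"plasso{variant}",
        ModelCoefficients(b, float(w[0]), w[1:].copy()),
        extras={"eta": eta_star, "lambda": lam_star, "cv_report": report,
                **prior_extras},
    )


def fit_ulasso(
    S,
    X,
    cu_quantile: float = 0.9,
    cl_quantile: float = 0.1,
    lambda_grid=None,
    n_lambda: int = 100,
    k_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    loss: str = "deviance",
) -> BenchmarkFit:
    """Unsupervised LASSO on the extreme tails of the surrogate.

    Thresholds (cu, cl) are set at the given S quantiles over all rows; an l1
    logistic regression of I(S > cu) on X is fitted on the subset with S > cu
    or S < cl.  Only the coefficient direction (in ``extras['beta_tilde']``)
    is meaningful; no (zeta, gamma) usable for Y|W prediction is produced.
    """
    if not 0 < cl_quantile < cu_quantile < 1:
        raise ValueError("need 0 < cl_quantile < cu_quantile < 1")
    S = np.asarray(S, dtype=float)
    X = np.asarray(X, dtype=float)
    cu = float(np.quantile(S, cu_quantile))
    cl = float(np.quantile(S, cl_quantile))
    mask = (S > cu) | (S < cl)
    if not mask.any():
        raise ValueError("tail subset is empty; adjust the quantiles")
    yb = (S[mask] > cu).astype(float)
    if yb.min() == yb.max():
        raise ValueError("tail subset has a single pseudo-class")
    Xt = X[mask]
    factors = np.ones(X.shape[1])
    b, w, lam, report = _cv_l1_logistic(
        Xt, yb, factors, lambda_grid, n_lambda, k_folds, seed, standardize, loss
    )
    return BenchmarkFit(
        "ulasso",
        ModelCoefficients(0.0, 0.0, w.copy()),
        extras={"beta_tilde": w.copy(), "cu": cu, "cl": cl,
                "n_subset": int(mask.sum()), "lambda": lam,
                "direction_only": True, "cv_report": report},
    )


def fit_ss_ulasso(labeled: LabeledSet, ulasso_fit: BenchmarkFit) -> BenchmarkFit:
    """Semi-supervised rescaling of the unsupervised direction: unpenalized
    logistic fit of Y on (1, S, X'beta_tilde), reporting beta as the scaled
    direction."""
    beta_tilde = ulasso_fit.extras["beta_tilde"]
    xb = labeled.X @ beta_tilde
    D = np.column_stack([labeled.S, xb])
    zeta, coef, ok = _unpenalized_logistic(D, labeled.Y)
    if not ok or np.max(np.abs(coef)) > 50:
        warnings.warn("separation in the ss-ulasso fit; using a small ridge "
                      "penalty", RuntimeWarning)
        zeta, coef, _ = _unpenalized_logistic(D, labeled.Y, ridge=1e-4)
    gamma, rho = float(coef[0]), float(coef[1])
    return BenchmarkFit(
        "ssulasso",
        ModelCoefficients(zeta, gamma, rho * beta_tilde),
        extras={"rho": rho},
    )
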