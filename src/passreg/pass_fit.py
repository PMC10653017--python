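"""The prior-adaptive semi-supervised (PASS) estimator.

Fits a penalized logistic phenotype model that shrinks the feature
coefficients beta toward a scalar multiple rho * alpha_hat of the surrogate
direction, with separate penalty levels on and off the surrogate support.
Computationally this is a weighted-l1 logistic regression on the augmented
covariates (S, X'alpha_hat, X) in the re-parametrization
beta = delta + rho * alpha_hat, with (intercept, S-coefficient, rho)
unpenalized, delta penalized at lambda1 on the support of alpha_hat and at
lambda2 = kappa * lambda1 off it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data import LabeledSet
from .solvers import (
    SelectionReport,
    default_lambda_grid,
    fit_path,
    lambda_max,
    logistic_loss,
    select_by_cv,
)
from .surrogate import SurrogateFit

__all__ = [
    "PassFit",
    "build_augmented_design",
    "resolve_factors",
    "fit_pass",
    "predict_pass",
    "pass_objective",
]

KAPPA_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class PassFit:
    """Fitted PASS model: beta = delta + rho * alpha of the surrogate fit."""

    zeta: float
    gamma: float
    rho: float
    delta: np.ndarray
    beta: np.ndarray
    lambda1: float
    kappa: float
    surrogate_ref: SurrogateFit
    cv_report: Optional[SelectionReport] = None
    extras: dict = field(default_factory=dict)

    @property
    def lambda2(self) -> float:
        return self.lambda1 * self.kappa

    def predict_proba(self, S, X):
        return predict_pass(self, S, X)

    def to_json(self) -> str:
        idx = np.flatnonzero(self.beta)
        return json.dumps(
            {
                "zeta": self.zeta,
                "gamma": self.gamma,
                "rho": self.rho,
                "p": int(self.beta.shape[0]),
                "beta": {int(j): float(self.beta[j]) for j in idx},
                "lambda1": self.lambda1,
                "kappa": self.kappa,
            }
        )


def build_augmented_design(labeled: LabeledSet, surrogate: SurrogateFit):
    """Augmented design [S, X'alpha, X_1..X_p] and its penalty-factor template.

    Template entries: 0 for the two unpenalized leading columns, 1 for
    features on the surrogate support, NaN marking the off-support slots to
    be filled with kappa (see :func:`resolve_factors`).
    """
    if surrogate.p != labeled.p:
        raise ValueError("surrogate and labeled feature dimensions disagree")
    xa = labeled.X @ surrogate.alpha
    if not np.any(surrogate.alpha):
        warnings.warn(
            "surrogate direction is zero: the X'alpha column is identically 0",
            RuntimeWarning,
        )
    D = np.column_stack([labeled.S, xa, labeled.X])
    template = np.empty(labeled.p + 2)
    template[:2] = 0.0
    on = np.zeros(labeled.p, dtype=bool)
    on[surrogate.support] = True
    template[2:] = np.where(on, 1.0, np.nan)
    return D, template


def resolve_factors(template: np.ndarray, kappa: float) -> np.ndarray:
    """Fill the kappa placeholders (NaN) of a penalty-factor template."""
    factors = template.copy()
    factors[np.isnan(factors)] = kappa
    return factors


def fit_pass(
    labeled: LabeledSet,
    surrogate: SurrogateFit,
    lambda1_grid: Optional[Sequence[float]] = None,
    kappa_grid: Sequence[float] = KAPPA_GRID,
    k_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    standardize: bool = True,
    loss: str = "deviance",
    tol: float = 1e-7,
) -> PassFit:
    """Fit PASS with (lambda1, kappa) chosen by stratified k-fold CV.

    For every kappa a descending lambda1 path is fitted with warm starts; the
    2-D grid is searched exhaustively with a shared fold split and the model
    is refitted on all labeled rows at the selected pair.  If the surrogate
    direction is zero the rho column is dropped and the fit reduces to the
    supervised LASSO at level lambda2 = kappa * lambda1.
    """
    if labeled.Y.min() == labeled.Y.max():
        raise ValueError("labeled outcome has a single class")
    degenerate = not np.any(surrogate.alpha)
    D, template = build_augmented_design(labeled, surrogate)
    y = labeled.Y

    if degenerate:
        # no usable direction: drop the zero X'alpha column, penalize all
        # features uniformly -> supervised LASSO at level kappa * lambda1
        D = np.delete(D, 1, axis=1)
        kappas = [1.0]
        templates = {1.0: np.concatenate([[0.0], np.ones(labeled.p)])}
    else:
        kappas = sorted(kappa_grid, reverse=True)
        templates = {k: resolve_factors(template, k) for k in kappas}

    candidates = []
    for kap in kappas:
        factors = templates[kap]
        if lambda1_grid is None:
            lmax = lambda_max(D, y, factors, family="logistic", standardize=standardize)
            grid = default_lambda_grid(lmax, "logistic", n_lambda)
        else:
            grid = np.sort(np.asarray(lambda1_grid, dtype=float))[::-1]
        for lam in grid:
            candidates.append(
                {"lam": float(lam), "factors": factors, "tie": (float(lam), kap),
                 "kappa": kap}
            )
    if len(candidates) > 1:
        # fold fits only steer selection; a looser tolerance does not move
        # the chosen grid point but cuts runtime substantially
        report = select_by_cv(
            D, y, candidates, k_folds=k_folds, seed=seed, family="logistic",
            loss=loss, standardize=standardize, tol=max(tol, 3e-5),
        )
        chosen = candidates[report.chosen_index]
    else:
        report = None
        chosen = candidates[0]
    lam1, kap = chosen["lam"], chosen["kappa"]
    factors = templates[kap]
    # refit on all labeled rows, warm-started down the chosen kappa's path
    path_lams = [c["lam"] for c in candidates if c["kappa"] == kap and c["lam"] >= lam1]
    intercepts, coefs = fit_path(
        D, y, sorted(path_lams, reverse=True), factors, family="logistic",
        standardize=standardize, tol=tol,
    )
    b = float(intercepts[-1])
    w = coefs[:, -1]
    if degenerate:
        gamma, rho, delta = float(w[0]), 0.0, w[1:].copy()
    else:
        gamma, rho, delta = float(w[0]), float(w[1]), w[2:].copy()
    beta = delta + rho * surrogate.alpha
    return PassFit(
        zeta=b, gamma=gamma, rho=rho, delta=delta, beta=beta,
        lambda1=lam1, kappa=kap, surrogate_ref=surrogate, cv_report=report,
        extras={"degenerate": degenerate},
    )


def predict_pass(fit: PassFit, S, X) -> np.ndarray:
    """Predicted probabilities sigma(zeta + gamma*S + X'beta)."""
    S = np.asarray(S, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != fit.beta.shape[0]:
        raise ValueError("feature dimension mismatch")
    if X.shape[0] != S.shape[0]:
        raise ValueError("S and X row counts disagree")
    eta = fit.zeta + fit.gamma * S + X @ fit.beta
    return 1.0 / (1.0 + np.exp(-eta))


def pass_objective(
    params,
    labeled: LabeledSet,
    surrogate: SurrogateFit,
    lambda1: float,
    lambda2: float,
) -> float:
    """Evaluate the PASS objective at params = (zeta, gamma, rho, beta):

    (1/n) sum ell(Y_i, zeta + gamma*S_i + X_i'beta)
        + lambda1 * ||(beta - rho*alpha)_A||_1 + lambda2 * ||beta_{A^c}||_1
    """
    zeta, gamma, rho, beta = params
    beta = np.asarray(beta, dtype=float)
    eta = zeta + gamma * labeled.S + labeled.X @ beta
    nll = float(np.mean(logistic_loss(labeled.Y, eta)))
    on = np.zeros(labeled.p, dtype=bool)
    on[surrogate.support] = True
    resid = beta - rho * surrogate.alpha
    pen = lambda1 * float(np.sum(np.abs(resid[on])))
    pen += lambda2 * float(np.sum(np.abs(beta[~on])))
    return nll + pen
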