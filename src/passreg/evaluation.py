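"""Prediction metrics and the replication harness for simulation comparisons."""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .benchmarks import (
    fit_alasso,
    fit_lasso,
    fit_plasso,
    fit_ss_prior,
    fit_ss_ulasso,
    fit_ulasso,
)
from .data import LabeledSet, ModelCoefficients
from .pass_fit import fit_pass
from .simulation import (
    MainScenarioSpec,
    MisspecScenarioSpec,
    SimulatedStudy,
    generate_main_study,
    generate_misspec_study,
    oracle_limit_coefficients,
    MAIN_SCENARIOS,
    MISSPEC_SCENARIOS,
)
from .solvers import logistic_loss
from .surrogate import fit_alpha, normalize_direction
from .data import pooled_surrogate_data

__all__ = [
    "EvalReport",
    "ExperimentConfig",
    "auc",
    "excess_risk",
    "mse_p",
    "bss",
    "evaluate_model",
    "run_experiment",
    "summarize",
]


def auc(scores, y) -> float:
    """Mann-Whitney AUC: P(random positive outscores a random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = y == 1
    n1 = int(pos.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def excess_risk(coefs: ModelCoefficients, test: LabeledSet,
                truth: ModelCoefficients) -> float:
    """Mean logistic loss of the fitted linear score minus that of the true
    (or limit) score, on the test set."""
    eta_hat = coefs.linear_predictor(test.S, test.X)
    eta_true = truth.linear_predictor(test.S, test.X)
    return float(np.mean(logistic_loss(test.Y, eta_hat))
                 - np.mean(logistic_loss(test.Y, eta_true)))


def mse_p(predicted_probs, true_probs) -> float:
    """Mean squared difference between predicted and true probabilities."""
    p_hat = np.asarray(predicted_probs, dtype=float)
    p_true = np.asarray(true_probs, dtype=float)
    if p_hat.shape != p_true.shape:
        raise ValueError("length mismatch")
    if np.any((p_hat < 0) | (p_hat > 1)) or np.any((p_true < 0) | (p_true > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p_hat - p_true) ** 2))


def bss(predicted_probs, y) -> float:
    """Brier skill score: 1 - Brier(model) / Brier(constant event rate)."""
    p_hat = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("BSS undefined: both classes must be present")
    brier = np.mean((y - p_hat) ** 2)
    base = np.mean((y - y.mean()) ** 2)
    return float(1.0 - brier / base)


@dataclass
class EvalReport:
    auc: float
    excess_risk: float
    mse_p: float
    bss: float
    n_test: int
    method: str = ""
    replication: int = 0
    seed: int = 0

    def to_rows(self):
        return [
            {"method": self.method, "replication": self.replication,
             "seed": self.seed, "metric": m, "value": getattr(self, a)}
            for m, a in (("AUC", "auc"), ("ER", "excess_risk"),
                         ("MSE-P", "mse_p"), ("BSS", "bss"))
        ]


def evaluate_model(coefs: ModelCoefficients, study: SimulatedStudy,
                   method: str = "", replication: int = 0,
                   seed: int = 0) -> EvalReport:
    test = study.test
    eta = coefs.linear_predictor(test.S, test.X)
    probs = expit(eta)
    er = excess_risk(coefs, test, study.truth) if study.truth is not None else np.nan
    msep = (mse_p(probs, study.test_true_probs)
            if study.test_true_probs is not None else np.nan)
    return EvalReport(
        auc=auc(eta, test.Y), excess_risk=er, mse_p=msep,
        bss=bss(probs, test.Y), n_test=test.n, method=method,
        replication=replication, seed=seed,
    )


@dataclass
class ExperimentConfig:
    scenario: str
    methods: Sequence[Union[str, dict]]
    p: int = 500
    N: int = 10000
    n_labeled: int = 100
    n_test: int = 10000
    replications: int = 20
    base_seed: int = 0
    k_folds: int = 10
    n_lambda: int = 100
    kappa_grid: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0)
    eta_grid: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
    nu: float = 1.0
    n_lambda_surrogate: int = 100
    mc_size_truth: int = 200_000

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be at least 1")
        if self.scenario not in MAIN_SCENARIOS + MISSPEC_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    def method_entries(self) -> List[dict]:
        out = []
        for m in self.methods:
            if isinstance(m, str):
                out.append({"method": m, "name": m, "n_labeled": self.n_labeled})
            else:
                entry = dict(m)
                entry.setdefault("name", entry["method"])
                entry.setdefault("n_labeled", self.n_labeled)
                out.append(entry)
        return out


SURROGATE_METHODS = {"pass", "ssprior", "plasso1", "plasso2"}


def _fit_method(entry, study, surrogate, config, seed):
    method = entry["method"]
    n_use = entry["n_labeled"]
    labeled = study.labeled
    if n_use > labeled.n:
        raise ValueError(f"method {entry['name']} wants {n_use} labels but the "
                         f"study has {labeled.n}")
    if n_use < labeled.n:
        labeled = labeled.subset(np.arange(n_use))
    kw = dict(k_folds=config.k_folds, seed=seed, n_lambda=config.n_lambda)
    if method == "pass":
        fit = fit_pass(labeled, surrogate, kappa_grid=config.kappa_grid, **kw)
        return ModelCoefficients(fit.zeta, fit.gamma, fit.beta), fit
    if method == "lasso":
        fit = fit_lasso(labeled, **kw)
    elif method == "alasso":
        fit = fit_alasso(labeled, nu=config.nu, **kw)
    elif method == "ssprior":
        fit = fit_ss_prior(labeled, surrogate)
    elif method in ("plasso1", "plasso2"):
        fit = fit_plasso(labeled, surrogate, variant=int(method[-1]),
                         eta_grid=config.eta_grid, **kw)
    elif method == "ulasso":
        S, X = pooled_surrogate_data(study.labeled, study.unlabeled)
        fit = fit_ulasso(S, X, **kw)
    elif method == "ssulasso":
        S, X = pooled_surrogate_data(study.labeled, study.unlabeled)
        ul = fit_ulasso(S, X, **kw)
        fit = fit_ss_ulasso(labeled, ul)
    else:
        raise ValueError(f"unknown method {method!r}")
    return fit.coefficients, fit


def run_experiment(config: ExperimentConfig, verbose: bool = False):
    """Run the scenario comparison: per replication, simulate a study, fit
    every configured method, and score it on the study's test set.

    Returns a tidy DataFrame with one row per (method, replication, metric).
    Failures in a single method/replication are flagged and the run continues.
    """
    entries = config.method_entries()
    n_gen = max([config.n_labeled] + [e["n_labeled"] for e in entries])
    is_misspec = config.scenario in MISSPEC_SCENARIOS
    truth = None
    if is_misspec:
        base_spec = MisspecScenarioSpec(config.scenario, p=config.p, N=config.N,
                                        n=n_gen, n_test=config.n_test,
                                        seed=config.base_seed)
        truth = oracle_limit_coefficients(base_spec, mc_size=config.mc_size_truth,
                                          seed=config.base_seed + 987_654_321)
    rows = []
    failures = []
    for r in range(config.replications):
        seed = config.base_seed + r
        if is_misspec:
            spec = MisspecScenarioSpec(config.scenario, p=config.p, N=config.N,
                                       n=n_gen, n_test=config.n_test, seed=seed)
            study = generate_misspec_study(spec, truth=truth)
        else:
            spec = MainScenarioSpec(config.scenario, p=config.p, N=config.N,
                                    n=n_gen, n_test=config.n_test, seed=seed)
            study = generate_main_study(spec)
        surrogate = None
        if any(e["method"] in SURROGATE_METHODS for e in entries):
            S, X = pooled_surrogate_data(study.labeled, study.unlabeled)
            surrogate = normalize_direction(
                fit_alpha(S, X, nu=config.nu, n_lambda=config.n_lambda_surrogate)
            )
        for entry in entries:
            t0 = time.perf_counter()
            try:
                coefs, _ = _fit_method(entry, study, surrogate, config, seed)
                report = evaluate_model(coefs, study, method=entry["name"],
                                        replication=r, seed=seed)
                rows.extend(report.to_rows())
            except Exception as exc:  # noqa: BLE001 - keep the run going
                warnings.warn(f"{entry['name']} failed in replication {r}: {exc}",
                              RuntimeWarning)
                failures.append({"method": entry["name"], "replication": r,
                                 "error": str(exc)})
            if verbose:
                print(f"rep {r} {entry['name']}: {time.perf_counter() - t0:.1f}s",
                      flush=True)
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    df.attrs["scenario"] = config.scenario
    return df


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and quartiles per method x metric."""
    return (
        results.groupby(["method", "metric"])["value"]
        .agg(["mean", "std", "min",
              ("q25", lambda s: s.quantile(0.25)),
              ("median", "median"),
              ("q75", lambda s: s.quantile(0.75)),
              "max", "count"])
        .reset_index()
    )
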