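"""Synthetic-data engine.

Main scenarios I-VI: zero-inflated count-like features from a correlated
Gaussian copula, a single-index surrogate, and a logistic outcome model.
Mis-specification scenarios i-iii: uniform features on a block-correlated
copula, a thresholded latent outcome, and a surrogate that may depend on X
given Y; the estimation target there is the population-limit coefficient
vector of the best logistic approximation, computed by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, ndtr

from .data import LabeledSet, ModelCoefficients, UnlabeledSet

__all__ = [
    "MainScenarioSpec",
    "MisspecScenarioSpec",
    "SimulatedStudy",
    "scenario_coefficients",
    "h_transform",
    "generate_main_study",
    "generate_misspec_study",
    "oracle_limit_coefficients",
]

A1 = np.array([0.5, 1.0, -0.8, 0.6, 0.2])
D1 = np.array([-0.05, -0.5, 1.4, 0.5, -0.6])
A2 = np.array([0.1, -0.2, -0.2, 0.2, 0.7])
D2 = np.array([0.02, 0.05, 0.02, -0.02, -0.05])
A3 = np.array([0.6, -0.4, 0.4, 0.5, -0.5])
D3 = np.array([0.3, 0.4, 0.6, -0.5, -0.5])

MAIN_SCENARIOS = ("I", "II", "III", "IV", "V", "VI")
MISSPEC_SCENARIOS = ("i", "ii", "iii")

ZETA0 = -4.0
GAMMA0 = 0.5


@dataclass
class MainScenarioSpec:
    scenario: str
    p: int = 500
    N: int = 10000
    n: int = 100
    n_test: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in MAIN_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.p < 20:
            raise ValueError("p must be at least 20 for the coefficient templates")
        if not 0 < self.n < self.N:
            raise ValueError("need 0 < n < N")


@dataclass
class MisspecScenarioSpec:
    scenario: str
    p: int = 500
    N: int = 10000
    n: int = 100
    n_test: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in MISSPEC_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.p < 20:
            raise ValueError("p must be at least 20")
        if not 0 < self.n < self.N:
            raise ValueError("need 0 < n < N")

    @property
    def mu(self) -> float:
        return {"i": 1.0, "ii": 1.5, "iii": 2.0}[self.scenario]

    @property
    def eta1(self) -> np.ndarray:
        out = np.zeros(self.p)
        if self.scenario == "ii":
            out[:5] = A3
        elif self.scenario == "iii":
            out[:15] = np.tile(A3, 3)
        return out

    @property
    def eta2(self) -> np.ndarray:
        out = np.zeros(self.p)
        if self.scenario == "ii":
            out[:5] = D3
        elif self.scenario == "iii":
            out[:15] = np.tile(D3, 3)
        return out


@dataclass
class SimulatedStudy:
    labeled: LabeledSet
    unlabeled: UnlabeledSet
    test: LabeledSet
    test_true_probs: np.ndarray
    truth: Optional[ModelCoefficients]
    alpha0: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)


def scenario_coefficients(scenario: str, p: int):
    """Exact coefficient templates (alpha0, beta0) for main scenarios I-VI."""
    if p < 20:
        raise ValueError("p must be at least 20")
    z = np.zeros

    def pad(v):
        out = np.zeros(p)
        out[: v.size] = v
        return out

    if scenario == "I":
        alpha = pad(np.concatenate([A1, A2]))
        beta = 1.5 * alpha
    elif scenario == "II":
        alpha = pad(np.concatenate([A1, A2]))
        beta = 1.5 * pad(np.concatenate([A1 + D1, A2 + D2]))
    elif scenario == "III":
        alpha = pad(np.concatenate([A1, A2, A2, A2]))
        beta = 1.5 * pad(np.concatenate([A1 + D1, A2 + D2]))
    elif scenario == "IV":
        alpha = pad(A1)
        beta = 1.5 * pad(np.concatenate([A1 + D1, A2 + D2]))
    elif scenario == "V":
        alpha = pad(np.concatenate([A1, A2]))
        beta = 1.5 * pad(np.concatenate([A2, A1]))
    elif scenario == "VI":
        alpha = pad(np.concatenate([A1, A2]))
        beta = 1.5 * pad(np.concatenate([A2, z(5), A1]))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return alpha, beta


def h_transform(t):
    """log(1 + [e^t]) with [.] the nearest integer (half-to-even)."""
    t = np.asarray(t, dtype=float)
    return np.log1p(np.rint(np.exp(t)))


def _ar1_normal(rng, rows, p, rho, scale):
    """Sample rows x p from N(0, scale^2 * R) with R_ij = rho^|i-j|."""
    e = rng.standard_normal((rows, p))
    z = np.empty_like(e)
    z[:, 0] = e[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        z[:, j] = rho * z[:, j - 1] + c * e[:, j]
    return scale * z


def generate_main_study(spec: MainScenarioSpec) -> SimulatedStudy:
    """Generate labeled/unlabeled/test splits for a main scenario.

    Z ~ N(0, Sigma) with sigma_ij = 4 * 0.5^|i-j|; X = h(Z) elementwise;
    S = h(1 + X'alpha0 + eps), eps ~ N(0, 2^2);
    Y ~ Bernoulli(sigma(-4 + 0.5 S + X'beta0)).
    """
    rng = np.random.default_rng(spec.seed)
    alpha0, beta0 = scenario_coefficients(spec.scenario, spec.p)
    rows = spec.N + spec.n_test
    Z = _ar1_normal(rng, rows, spec.p, 0.5, 2.0)
    X = h_transform(Z)
    S = h_transform(1.0 + X @ alpha0 + rng.normal(0.0, 2.0, rows))
    probs = expit(ZETA0 + GAMMA0 * S + X @ beta0)
    Y = (rng.random(rows) < probs).astype(float)
    names = [f"X{j + 1}" for j in range(spec.p)]
    lab = slice(0, spec.n)
    unl = slice(spec.n, spec.N)
    tst = slice(spec.N, rows)
    truth = ModelCoefficients(ZETA0, GAMMA0, beta0)
    return SimulatedStudy(
        labeled=LabeledSet(Y[lab], S[lab], X[lab], names),
        unlabeled=UnlabeledSet(S[unl], X[unl], names),
        test=LabeledSet(Y[tst], S[tst], X[tst], names),
        test_true_probs=probs[tst],
        truth=truth,
        alpha0=alpha0,
        provenance={"kind": "main", "scenario": spec.scenario, "seed": spec.seed,
                    "p": spec.p, "N": spec.N, "n": spec.n, "n_test": spec.n_test},
    )


Y_THRESHOLD_COEF = np.array([0.8, 1.0, -1.0, 0.8, 0.4])
ACTIVE_BLOCK = 20  # features beyond this block are independent of (Y, S)


def _misspec_draw(spec: MisspecScenarioSpec, rng, rows, p=None):
    p = spec.p if p is None else p
    z1 = _ar1_normal(rng, rows, min(ACTIVE_BLOCK, p), 0.5, 1.0)
    if p > ACTIVE_BLOCK:
        z2 = _ar1_normal(rng, rows, p - ACTIVE_BLOCK, 0.5, 1.0)
        Z = np.hstack([z1, z2])
    else:
        Z = z1
    X = 2.0 * ndtr(Z) - 1.0
    c = np.zeros(p)
    c[:5] = Y_THRESHOLD_COEF
    Y = (X @ c + rng.standard_normal(rows) >= 0).astype(float)
    S = (
        spec.mu * Y
        + X @ spec.eta1[:p]
        + Y * (X @ spec.eta2[:p])
        + rng.standard_normal(rows)
    )
    return X, S, Y


def generate_misspec_study(
    spec: MisspecScenarioSpec,
    truth: Optional[ModelCoefficients] = None,
    mc_size: int = 200_000,
) -> SimulatedStudy:
    """Generate a mis-specification study; the outcome model is not logistic.

    ``truth`` (the population-limit coefficients) is computed by Monte Carlo
    when not supplied; pass a precomputed value to amortize it across
    replications.
    """
    rng = np.random.default_rng(spec.seed)
    rows = spec.N + spec.n_test
    X, S, Y = _misspec_draw(spec, rng, rows)
    names = [f"X{j + 1}" for j in range(spec.p)]
    if truth is None:
        truth = oracle_limit_coefficients(spec, mc_size=mc_size,
                                          seed=spec.seed + 987_654_321)
    lab = slice(0, spec.n)
    unl = slice(spec.n, spec.N)
    tst = slice(spec.N, rows)
    probs = expit(truth.linear_predictor(S[tst], X[tst]))
    return SimulatedStudy(
        labeled=LabeledSet(Y[lab], S[lab], X[lab], names),
        unlabeled=UnlabeledSet(S[unl], X[unl], names),
        test=LabeledSet(Y[tst], S[tst], X[tst], names),
        test_true_probs=probs,
        truth=truth,
        provenance={"kind": "misspec", "scenario": spec.scenario,
                    "seed": spec.seed, "p": spec.p, "N": spec.N, "n": spec.n,
                    "n_test": spec.n_test},
    )


def oracle_limit_coefficients(
    spec: MisspecScenarioSpec, mc_size: int = 1_000_000, seed: int = 0
) -> ModelCoefficients:
    """Population-limit (zeta0, gamma0, beta0): the minimizer of the expected
    logistic loss of Y against (S, X), approximated by an unpenalized fit on a
    fresh Monte-Carlo sample.

    Only the leading block of features enters the generative model; features
    beyond it are independent of (Y, S, leading block), so their limit
    coefficients are exactly zero and the fit is restricted accordingly.
    """
    if mc_size < 100_000:
        raise ValueError("mc_size of at least 1e5 is required for a stable limit")
    rng = np.random.default_rng(seed)
    q = min(ACTIVE_BLOCK, spec.p)
    X, S, Y = _misspec_draw(spec, rng, mc_size, p=q)
    from .benchmarks import _unpenalized_logistic

    D = np.column_stack([S, X])
    zeta, coef, ok = _unpenalized_logistic(D, Y)
    if not ok:
        raise RuntimeError(
            "population-limit fit did not converge; increase mc_size"
        )
    beta = np.zeros(spec.p)
    beta[:q] = coef[1:]
    return ModelCoefficients(zeta, float(coef[0]), beta)
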