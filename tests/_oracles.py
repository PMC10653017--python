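"""Independent convex-optimization oracles used by the tests.

These solve the same objectives as the package solvers but through a generic
smooth reformulation (positive/negative splitting of l1 terms) handed to
scipy's L-BFGS-B, so they share no code path with the coordinate-descent
engine they certify.
"""

import numpy as np
from scipy.optimize import minimize


def _split_bounds(n_free, n_split):
    return [(None, None)] * n_free + [(0.0, None)] * (2 * n_split)


def oracle_l1_linear(X, y, lam, factors, tol=1e-12):
    """min (1/n) sum (y - b - Xw)^2 + lam * sum f_j |w_j| via splitting."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    factors = np.asarray(factors, float)
    keep = np.isfinite(factors)
    Xk = X[:, keep]
    fk = factors[keep]
    q = Xk.shape[1]

    def fg(z):
        b, wp, wm = z[0], z[1:1 + q], z[1 + q:]
        w = wp - wm
        r = y - b - Xk @ w
        f = np.mean(r**2) + lam * np.sum(fk * (wp + wm))
        gb = -2.0 * np.mean(r)
        gw = -2.0 / n * (Xk.T @ r)
        g = np.concatenate([[gb], gw + lam * fk, -gw + lam * fk])
        return f, g

    res = minimize(fg, np.zeros(1 + 2 * q), jac=True, method="L-BFGS-B",
                   bounds=_split_bounds(1, q),
                   options={"maxiter": 50000, "ftol": tol, "gtol": 1e-12})
    w = np.zeros(p)
    w[keep] = res.x[1:1 + q] - res.x[1 + q:]
    return float(res.x[0]), w, float(res.fun)


def oracle_l1_logistic(X, y, lam, factors, tol=1e-14):
    """min (1/n) sum [-y eta + log(1+e^eta)] + lam * sum f_j |w_j|."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    factors = np.asarray(factors, float)
    keep = np.isfinite(factors)
    Xk = X[:, keep]
    fk = factors[keep]
    q = Xk.shape[1]

    def fg(z):
        b, wp, wm = z[0], z[1:1 + q], z[1 + q:]
        w = wp - wm
        eta = b + Xk @ w
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        f = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
        f += lam * float(np.sum(fk * (wp + wm)))
        gb = float(np.mean(mu - y))
        gw = Xk.T @ (mu - y) / n
        g = np.concatenate([[gb], gw + lam * fk, -gw + lam * fk])
        return f, g

    res = minimize(fg, np.zeros(1 + 2 * q), jac=True, method="L-BFGS-B",
                   bounds=_split_bounds(1, q),
                   options={"maxiter": 50000, "ftol": tol, "gtol": 1e-12})
    w = np.zeros(p)
    w[keep] = res.x[1:1 + q] - res.x[1 + q:]
    return float(res.x[0]), w, float(res.fun)


def oracle_pass(labeled, alpha, lam1, lam2, tol=1e-14):
    """Generic minimizer of the prior-shrinkage objective

        (1/n) sum ell(Y, zeta + gamma S + X'beta)
            + lam1 ||(beta - rho alpha)_A||_1 + lam2 ||beta_{A^c}||_1

    over (zeta, gamma, rho, beta), via splitting u = (beta - rho alpha)_A and
    w = beta_{A^c}.  Returns (zeta, gamma, rho, beta, min_objective).
    """
    Y, S, X = labeled.Y, labeled.S, labeled.X
    n, p = X.shape
    alpha = np.asarray(alpha, float)
    A = np.flatnonzero(alpha)
    Ac = np.flatnonzero(alpha == 0)
    qa, qc = A.size, Ac.size
    XA, XC = X[:, A], X[:, Ac]
    aA = alpha[A]

    def unpack(z):
        zeta, gamma, rho = z[0], z[1], z[2]
        up = z[3:3 + qa]
        um = z[3 + qa:3 + 2 * qa]
        wp = z[3 + 2 * qa:3 + 2 * qa + qc]
        wm = z[3 + 2 * qa + qc:]
        return zeta, gamma, rho, up, um, wp, wm

    def fg(z):
        zeta, gamma, rho, up, um, wp, wm = unpack(z)
        betaA = rho * aA + (up - um)
        betaC = wp - wm
        eta = zeta + gamma * S + XA @ betaA + XC @ betaC
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        f = float(np.mean(np.logaddexp(0.0, eta) - Y * eta))
        f += lam1 * float(np.sum(up + um)) + lam2 * float(np.sum(wp + wm))
        resid = (mu - Y) / n
        gA = XA.T @ resid
        gC = XC.T @ resid
        g = np.concatenate([
            [float(np.sum(resid))],
            [float(S @ resid)],
            [float(aA @ gA)],
            gA + lam1, -gA + lam1,
            gC + lam2, -gC + lam2,
        ])
        return f, g

    z0 = np.zeros(3 + 2 * qa + 2 * qc)
    res = minimize(fg, z0, jac=True, method="L-BFGS-B",
                   bounds=_split_bounds(3, qa + qc),
                   options={"maxiter": 100000, "ftol": tol, "gtol": 1e-12})
    zeta, gamma, rho, up, um, wp, wm = unpack(res.x)
    beta = np.zeros(p)
    beta[A] = rho * aA + (up - um)
    beta[Ac] = wp - wm
    return float(zeta), float(gamma), float(rho), beta, float(res.fun)
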