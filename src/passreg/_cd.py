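"""Coordinate-descent kernels for weighted-l1 penalized regression.

All kernels operate on a column-scaled design prepared by :mod:`passreg.solvers`.
Penalty factors follow the convention: 0 = unpenalized, finite > 0 = scaled
l1 weight, +inf = coordinate excluded (coefficient pinned at 0).
"""

import math

import numba as nb
import numpy as np

NB_CACHE = True


@nb.njit(cache=NB_CACHE)
def _soft(z, t):
    if z > t:
        return z - t
    if z < -t:
        return -(-z - t)
    return 0.0


@nb.njit(cache=NB_CACHE)
def _wls_objective(r, v, w, lam, factors, n):
    obj = 0.0
    for i in range(n):
        obj += 0.5 * v[i] * r[i] * r[i]
    obj /= n
    for j in range(w.shape[0]):
        if w[j] != 0.0 and np.isfinite(factors[j]):
            obj += lam * factors[j] * abs(w[j])
    return obj


@nb.njit(cache=NB_CACHE)
def _wls_cd(X, z, v, lam, factors, w, b, tol, max_passes):
    """Weighted penalized least squares by cyclic coordinate descent.

    minimize (1/(2n)) sum_i v_i (z_i - b - x_i'w)^2 + lam * sum_j factors_j |w_j|

    Mutates ``w`` in place; returns (b, n_passes).  The unweighted linear
    lasso with objective (1/n) sum (.)^2 + penalty is the special case v = 2.
    """
    n, p = X.shape
    vsum = 0.0
    for i in range(n):
        vsum += v[i]
    d = np.zeros(p)
    for j in range(p):
        if np.isinf(factors[j]):
            continue
        xj = X[:, j]
        s = 0.0
        for i in range(n):
            s += v[i] * xj[i] * xj[i]
        d[j] = s / n

    r = np.empty(n)
    for i in range(n):
        s = z[i] - b
        r[i] = s
    for j in range(p):
        if w[j] != 0.0:
            xj = X[:, j]
            wj = w[j]
            for i in range(n):
                r[i] -= xj[i] * wj

    active = np.empty(p, dtype=np.int64)
    obj = _wls_objective(r, v, w, lam, factors, n)
    passes = 0
    while passes < max_passes:
        # full pass (also rebuilds the active set)
        na = 0
        gb = 0.0
        for i in range(n):
            gb += v[i] * r[i]
        db = gb / vsum
        if db != 0.0:
            b += db
            for i in range(n):
                r[i] -= db
        for j in range(p):
            if np.isinf(factors[j]) or d[j] <= 0.0:
                continue
            xj = X[:, j]
            wj = w[j]
            g = 0.0
            for i in range(n):
                g += v[i] * xj[i] * r[i]
            g = g / n + d[j] * wj
            wnew = _soft(g, lam * factors[j]) / d[j]
            if wnew != wj:
                delta = wnew - wj
                for i in range(n):
                    r[i] -= xj[i] * delta
                w[j] = wnew
            if w[j] != 0.0:
                active[na] = j
                na += 1
        passes += 1
        newobj = _wls_objective(r, v, w, lam, factors, n)
        if abs(obj - newobj) <= tol * (abs(newobj) + 1e-10):
            return b, passes
        obj = newobj
        # inner passes restricted to the active set
        while passes < max_passes:
            gb = 0.0
            for i in range(n):
                gb += v[i] * r[i]
            db = gb / vsum
            if db != 0.0:
                b += db
                for i in range(n):
                    r[i] -= db
            for k in range(na):
                j = active[k]
                xj = X[:, j]
                wj = w[j]
                g = 0.0
                for i in range(n):
                    g += v[i] * xj[i] * r[i]
                g = g / n + d[j] * wj
                wnew = _soft(g, lam * factors[j]) / d[j]
                if wnew != wj:
                    delta = wnew - wj
                    for i in range(n):
                        r[i] -= xj[i] * delta
                    w[j] = wnew
            passes += 1
            newobj = _wls_objective(r, v, w, lam, factors, n)
            done = abs(obj - newobj) <= tol * (abs(newobj) + 1e-10)
            obj = newobj
            if done:
                break
    return b, passes


@nb.njit(cache=NB_CACHE)
def _softplus(t):
    if t > 0.0:
        return t + math.log1p(math.exp(-t))
    return math.log1p(math.exp(t))


@nb.njit(cache=NB_CACHE)
def _logistic_objective(X, y, w, b, lam, factors):
    n = X.shape[0]
    p = X.shape[1]
    obj = 0.0
    for i in range(n):
        eta = b
        for j in range(p):
            if w[j] != 0.0:
                eta += X[i, j] * w[j]
        obj += _softplus(eta) - y[i] * eta
    obj /= n
    for j in range(p):
        if w[j] != 0.0 and np.isfinite(factors[j]):
            obj += lam * factors[j] * abs(w[j])
    return obj


@nb.njit(cache=NB_CACHE)
def _logistic_cd(X, y, lam, factors, w, b, tol, max_outer, max_passes):
    """Penalized logistic regression by IRLS with inner weighted CD.

    minimize (1/n) sum_i [-y_i eta_i + log(1 + e^{eta_i})] + lam sum_j f_j |w_j|

    ``y`` may be fractional in [0, 1].  Mutates ``w``.  Returns
    (b, n_passes, status) with status 0 = converged, 1 = max iterations,
    2 = divergence guard hit (near-separation with vanishing penalty).
    """
    n, p = X.shape
    eta = np.empty(n)
    mu = np.empty(n)
    v = np.empty(n)
    z = np.empty(n)
    obj = _logistic_objective(X, y, w, b, lam, factors)
    total_passes = 0
    status = 1
    for _ in range(max_outer):
        for i in range(n):
            e = b
            for j in range(p):
                if w[j] != 0.0:
                    e += X[i, j] * w[j]
            eta[i] = e
            m = 1.0 / (1.0 + math.exp(-e)) if e > -30.0 else 0.0
            if e > 30.0:
                m = 1.0
            mu[i] = m
            vi = m * (1.0 - m)
            if vi < 1e-5:
                vi = 1e-5
            v[i] = vi
            z[i] = e + (y[i] - m) / vi
        b, np_inner = _wls_cd(X, z, v, lam, factors, w, b, tol, 1000)
        total_passes += np_inner
        # divergence guard against perfect separation at lam ~ 0
        norm2 = b * b
        for j in range(p):
            norm2 += w[j] * w[j]
        if norm2 > 1e8:
            status = 2
            break
        newobj = _logistic_objective(X, y, w, b, lam, factors)
        if abs(obj - newobj) <= tol * (abs(newobj) + 1e-10):
            status = 0
            obj = newobj
            break
        obj = newobj
        if total_passes >= max_passes:
            break
    return b, total_passes, status
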