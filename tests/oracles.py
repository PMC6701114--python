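"""Independent oracles used by the test suite.

Deliberately naive implementations that share no code with the package:
ordinary least squares by explicit normal equations, the F-distribution
upper tail by numeric integration of its density, Benjamini-Hochberg by the
literal textbook loop, and DFFITS by brute-force leave-one-out refitting.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """beta = (X'X)^-1 X'y by explicit matrix inversion; returns (beta, rss)."""
    XtX = X.T @ X
    beta = np.linalg.inv(XtX) @ (X.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def f_density(x: float, d1: int, d2: int) -> float:
    if x <= 0:
        return 0.0
    log_b = (math.lgamma(d1 / 2) + math.lgamma(d2 / 2)
             - math.lgamma((d1 + d2) / 2))
    log_num = 0.5 * (d1 * math.log(d1 * x) + d2 * math.log(d2)
                     - (d1 + d2) * math.log(d1 * x + d2))
    return math.exp(log_num - log_b) / x


def f_upper_tail(F: float, d1: int, d2: int) -> float:
    """P(F_{d1,d2} > F) by adaptive quadrature of the density."""
    val, _err = quad(f_density, F, np.inf, args=(d1, d2), limit=200)
    return val


def t_two_sided(t: float, df: int) -> float:
    """Two-sided t-tail by quadrature of the Student density."""

    def dens(x):
        log_c = (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
                 - 0.5 * math.log(df * math.pi))
        return math.exp(log_c - (df + 1) / 2 * math.log1p(x * x / df))

    val, _err = quad(dens, abs(t), np.inf, limit=200)
    return 2.0 * val


def full_design(x: np.ndarray, cohorts: np.ndarray, labels: list[str]) -> np.ndarray:
    """Treatment-coded design built column by column, reference first."""
    cols = [np.ones_like(x)]
    for lab in labels[1:]:
        cols.append((cohorts == lab).astype(float))
    cols.append(x)
    for lab in labels[1:]:
        cols.append(x * (cohorts == lab))
    return np.column_stack(cols)


def loo_dffits(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """DFFITS by literally refitting without each observation."""
    n, p = X.shape
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    out = np.zeros(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta_i, rss_i = ols_normal_equations(X[keep], y[keep])
        yhat_full = float(X[i] @ np.linalg.inv(X.T @ X) @ X.T @ y)
        yhat_del = float(X[i] @ beta_i)
        s_del = math.sqrt(rss_i / (n - 1 - p))
        h_ii = float(H[i, i])
        if s_del == 0.0:
            out[i] = 0.0
        else:
            out[i] = (yhat_full - yhat_del) / (s_del * math.sqrt(h_ii))
    return out


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Textbook BH: sort, q_i = p_(i) m / i, enforce monotone from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = min(prev, 1.0)
    return q
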