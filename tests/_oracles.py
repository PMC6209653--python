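"""Independent brute-force reference implementations used as test oracles.

Deliberately written in plain numpy, separately from the package code, so
the two routes can disagree.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def oracle_crude_or(a, b, c, d):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se


def oracle_mh(cells):
    """Mantel-Haenszel pooled log OR and RBG standard error.

    ``cells`` is a sequence of (a, b, c, d) tuples; zero-cell tables get the
    +0.5 correction applied to all four cells.
    """
    t = np.asarray(cells, dtype=float)
    zero = (t.min(axis=1) == 0)[:, None]
    t = np.where(zero, t + 0.5, t)
    a, b, c, d = t.T
    n = t.sum(axis=1)
    R = a * d / n
    S = b * c / n
    P = (a + d) / n
    Q = (b + c) / n
    log_or = np.log(R.sum() / S.sum())
    var = (
        (P * R).sum() / (2 * R.sum() ** 2)
        + ((P * S) + (Q * R)).sum() / (2 * R.sum() * S.sum())
        + (Q * S).sum() / (2 * S.sum() ** 2)
    )
    return float(log_or), float(np.sqrt(var))


def oracle_iv_fixed(y, se):
    y = np.asarray(y, dtype=float)
    w = 1.0 / np.asarray(se, dtype=float) ** 2
    pooled = (w * y).sum() / w.sum()
    return float(pooled), float(1.0 / np.sqrt(w.sum()))


def oracle_dl(y, se):
    """DerSimonian-Laird pooled log OR, its SE, and tau^2."""
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    w = 1.0 / se**2
    y_fixed = (w * y).sum() / w.sum()
    q = (w * (y - y_fixed) ** 2).sum()
    df = len(y) - 1
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / c) if c > 0 and df > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = (w_star * y).sum() / w_star.sum()
    return float(pooled), float(1.0 / np.sqrt(w_star.sum())), float(tau2)


def oracle_q_i2(y, se):
    y = np.asarray(y, dtype=float)
    w = 1.0 / np.asarray(se, dtype=float) ** 2
    y_fixed = (w * y).sum() / w.sum()
    q = float((w * (y - y_fixed) ** 2).sum())
    df = len(y) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, i2


def oracle_select(p_q, i2):
    return "fixed_MH" if (p_q > 0.1 or i2 <= 50.0) else "random_DL"


def oracle_pool_auto(cells):
    """Full re-pooling with the Q/I2 fixed-vs-random rule; returns pooled OR."""
    t = np.asarray(cells, dtype=float)
    effects = [oracle_crude_or(*row) for row in t]
    y = [e[0] for e in effects]
    se = [e[1] for e in effects]
    q, df, i2 = oracle_q_i2(y, se)
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    if oracle_select(p_q, i2) == "fixed_MH":
        log_or, _ = oracle_mh(cells)
    else:
        log_or, _, _ = oracle_dl(y, se)
    return float(np.exp(log_or))


def oracle_egger(log_ors, ses):
    """OLS of standardized effect on precision via lstsq + covariance matrix."""
    y = np.asarray(log_ors, dtype=float) / np.asarray(ses, dtype=float)
    x = 1.0 / np.asarray(ses, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - 2
    sigma2 = (resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    intercept = float(beta[0])
    intercept_se = float(np.sqrt(cov[0, 0]))
    t = intercept / intercept_se
    p = 2 * float(stats.t.sf(abs(t), df))
    return intercept, intercept_se, t, p
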