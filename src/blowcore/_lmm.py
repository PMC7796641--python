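"""Marginal-ML linear mixed model with a random intercept and continuous AR(1) residuals.

The model for an alpha-diversity metric y is

    y = X beta + Z b + e,   b ~ N(0, s_b^2 I),   e ~ N(0, s_e^2 R(phi)),

where Z encodes a single random-intercept grouping factor and R has
block-diagonal structure over AR blocks (subjects), with R_ij = phi^|t_i - t_j|
on the continuous week index. Estimation is by direct maximization of the
marginal Gaussian log-likelihood over (log s_b, log s_e, atanh phi) with the
fixed effects profiled out by GLS at each step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize


@dataclass
class LmmFit:
    beta: np.ndarray
    loglik: float
    sigma_b: float
    sigma_e: float
    phi: float
    converged: bool
    n_params: int


def _build_V(n, Z, ar_blocks, lags, s_b, s_e, phi):
    V = s_b**2 * (Z @ Z.T)
    for idx in ar_blocks:
        t = lags[idx]
        V[np.ix_(idx, idx)] += s_e**2 * phi ** np.abs(t[:, None] - t[None, :])
    return V


def _profile_nll(params, y, X, Z, ar_blocks, lags, fix_phi):
    log_sb, log_se = params[0], params[1]
    phi = 0.0 if fix_phi else np.tanh(params[2])
    s_b, s_e = np.exp(log_sb), np.exp(log_se)
    if s_e < 1e-8:
        return 1e10
    n = len(y)
    V = _build_V(n, Z, ar_blocks, lags, s_b, s_e, phi)
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.log(np.diag(c)).sum()
    Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
    Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ Vi_X
    try:
        beta = linalg.solve(XtViX, X.T @ Vi_y, assume_a="pos")
    except linalg.LinAlgError:
        return 1e10
    r = y - X @ beta
    Vi_r = Vi_y - Vi_X @ beta
    nll = 0.5 * (logdet + r @ Vi_r + n * np.log(2 * np.pi))
    return float(nll)


def fit_lmm_ar1(y, X, re_labels, ar_group, ar_time, fix_phi=False) -> LmmFit:
    """ML fit. ``re_labels`` groups the random intercept; ``ar_group``/``ar_time``
    define the AR(1) residual blocks and the continuous lag within them."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    re_labels = np.asarray(re_labels)
    levels = np.unique(re_labels)
    Z = (re_labels[:, None] == levels[None, :]).astype(float)
    ar_group = np.asarray(ar_group)
    ar_blocks = [np.flatnonzero(ar_group == g) for g in np.unique(ar_group)]
    lags = np.asarray(ar_time, dtype=float)
    if len(np.unique(lags)) < 3:
        fix_phi = True

    resid_sd = max(np.std(y - X @ np.linalg.lstsq(X, y, rcond=None)[0]), 1e-3)
    starts = [
        np.array([np.log(resid_sd / 2), np.log(resid_sd), 0.0]),
        np.array([np.log(resid_sd), np.log(resid_sd / 2), 0.5]),
        np.array([np.log(resid_sd / 4), np.log(resid_sd), -0.3]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _profile_nll, x0, args=(y, X, Z, ar_blocks, lags, fix_phi),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e9:
        raise RuntimeError(f"LMM fit failed to converge: {best.message}")
    log_sb, log_se = best.x[0], best.x[1]
    phi = 0.0 if fix_phi else float(np.tanh(best.x[2]))
    s_b, s_e = float(np.exp(log_sb)), float(np.exp(log_se))
    # recover beta at the optimum
    V = _build_V(len(y), Z, ar_blocks, lags, s_b, s_e, phi)
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
    Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    beta = linalg.solve(X.T @ Vi_X, X.T @ Vi_y, assume_a="pos")
    n_params = X.shape[1] + (2 if fix_phi else 3)
    return LmmFit(
        beta=beta, loglik=-float(best.fun), sigma_b=s_b, sigma_e=s_e, phi=phi,
        converged=bool(best.success), n_params=n_params,
    )
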