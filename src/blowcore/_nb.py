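"""Vectorized log-link negative-binomial GLM fitting.

All taxa share the design matrix, so maximum-likelihood fitting runs as
batched IRLS across taxa: Fisher-scoring updates for the coefficients given
the dispersion, alternated with a damped Newton update of the per-taxon
dispersion theta (var = mu + mu^2/theta) on the log scale. theta is clamped to
[1e-3, 1e6]; at the upper clamp the fit is numerically a Poisson regression.

All-zero response columns carry no information: they are fitted at mu ~ 0 with
log-likelihood defined as 0, so their likelihood-ratio contributions vanish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

THETA_MIN = 1e-3
THETA_MAX = 1e6
_ETA_CLIP = 40.0


@dataclass
class ManyFit:
    beta: np.ndarray      # (p, m)
    theta: np.ndarray     # (m,)
    loglik: np.ndarray    # (m,)
    mu: np.ndarray        # (n, m)
    converged: np.ndarray  # (m,) bool
    zero_column: np.ndarray  # (m,) bool


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-column NB log-likelihood; safe at y = 0 and mu -> 0."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-12, None)
    th = np.asarray(theta, dtype=float)
    ll = (
        special.gammaln(y + th) - special.gammaln(th) - special.gammaln(y + 1.0)
        + th * np.log(th / (th + mu))
        + np.where(y > 0, y * np.log(mu / (th + mu)), 0.0)
    )
    return ll.sum(axis=0)


def nb_loglik_saturated(y: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """NB log-likelihood at mu = y (zero cells contribute 0)."""
    y = np.asarray(y, dtype=float)
    th = np.asarray(theta, dtype=float)
    mu = np.where(y > 0, y, 1.0)
    ll = np.where(
        y > 0,
        special.gammaln(y + th) - special.gammaln(th) - special.gammaln(y + 1.0)
        + th * np.log(th / (th + mu)) + y * np.log(mu / (th + mu)),
        0.0,
    )
    return ll.sum(axis=0)


def _theta_newton(y, mu, theta, n_iter=25, tol=1e-10):
    """Damped Newton ascent of the profile likelihood in log(theta), batched."""
    th = theta.copy()
    for _ in range(n_iter):
        tm = th[None, :] + mu
        score = (
            special.digamma(y + th[None, :]) - special.digamma(th[None, :])
            + np.log(th[None, :]) + 1.0 - np.log(tm) - (y + th[None, :]) / tm
        ).sum(axis=0)
        hess = (
            special.polygamma(1, y + th[None, :]) - special.polygamma(1, th[None, :])
            + 1.0 / th[None, :] - 2.0 / tm + (y + th[None, :]) / tm**2
        ).sum(axis=0)
        # Newton in t = log(theta): dl/dt = th*score, d2l/dt2 = th*score + th^2*hess
        grad_t = th * score
        hess_t = th * score + th**2 * hess
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(hess_t < 0, -grad_t / hess_t, np.sign(grad_t) * 0.5)
        step = np.nan_to_num(step, nan=0.0)
        step = np.clip(step, -2.0, 2.0)
        th = np.clip(th * np.exp(step), THETA_MIN, THETA_MAX)
        if np.max(np.abs(step)) < tol:
            break
    return th


def fit_many(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    theta: np.ndarray | float | None = None,
    max_outer: int = 8,
    max_inner: int = 30,
    tol: float = 1e-10,
) -> ManyFit:
    """Fit NB GLMs for every column of ``Y`` against the shared design ``X``.

    ``theta=None`` estimates a per-column dispersion by ML; a scalar or array
    holds it fixed (used where nested fits must share the dispersion).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    n, m = Y.shape
    p = X.shape[1]
    zero_col = Y.sum(axis=0) == 0

    estimate_theta = theta is None
    if estimate_theta:
        th = np.ones(m)
    else:
        th = np.broadcast_to(np.asarray(theta, dtype=float), (m,)).copy()

    # initial coefficients from a log-linear least-squares fit
    Z0 = np.log(Y + 0.5) - offset[:, None]
    beta, *_ = np.linalg.lstsq(X, Z0, rcond=None)

    eye = np.eye(p) * 1e-10

    def _mu(b):
        eta = np.clip(X @ b + offset[:, None], -_ETA_CLIP, _ETA_CLIP)
        return np.exp(eta)

    mu = _mu(beta)
    ll = nb_loglik(Y, mu, th)
    converged = np.zeros(m, dtype=bool)

    for _ in range(max_outer):
        # --- IRLS for beta given theta ---
        delta = np.zeros(m)
        for _ in range(max_inner):
            w = mu * th[None, :] / (th[None, :] + mu)
            z = np.log(np.clip(mu, 1e-12, None)) - offset[:, None] + (Y - mu) / np.clip(mu, 1e-12, None)
            A = np.einsum("ip,im,iq->mpq", X, w, X) + eye[None, :, :]
            rhs = np.einsum("ip,im->mp", X, w * z)
            try:
                new_beta = np.linalg.solve(A, rhs[:, :, None])[:, :, 0].T  # (p, m)
            except np.linalg.LinAlgError:
                new_beta = beta
            delta = np.max(np.abs(new_beta - beta), axis=0)
            # step-halving where the likelihood worsens
            cand_mu = _mu(new_beta)
            cand_ll = nb_loglik(Y, cand_mu, th)
            worse = cand_ll < ll - 1e-9
            tries = 0
            while worse.any() and tries < 6:
                new_beta[:, worse] = 0.5 * (new_beta[:, worse] + beta[:, worse])
                cand_mu = _mu(new_beta)
                cand_ll = nb_loglik(Y, cand_mu, th)
                worse = cand_ll < ll - 1e-9
                tries += 1
            beta, mu = new_beta, cand_mu
            ll = cand_ll
            if np.max(delta) < 1e-9:
                break
        if not estimate_theta:
            converged = delta < 1e-6
            break
        # --- theta update given mu ---
        th_new = _theta_newton(Y, mu, th)
        th_new[zero_col] = th[zero_col]
        ll_new = nb_loglik(Y, mu, th_new)
        done = np.abs(ll_new - ll) < tol * (1 + np.abs(ll_new))
        th, ll = th_new, ll_new
        converged = done
        if done.all():
            break

    # all-zero columns: mu ~ 0, log-likelihood defined as exactly 0
    if zero_col.any():
        beta[:, zero_col] = 0.0
        beta[0, zero_col] = -_ETA_CLIP
        mu[:, zero_col] = np.exp(np.clip(offset[:, None] - _ETA_CLIP, -700, 0))
        ll[zero_col] = 0.0
        converged[zero_col] = True

    return ManyFit(beta=beta, theta=th, loglik=ll, mu=mu,
                   converged=converged, zero_column=zero_col)


def theta_ml_update(Y, mu, theta, n_iter=4):
    """A few Newton steps on the theta profile score in log-space, batched.

    The derivative is taken by finite differences of the score (digamma only),
    avoiding the slow trigamma evaluation; adequate when started near the
    optimum, as in warm-started resample refits.
    """
    def score(th):
        tm = th[None, :] + mu
        return (
            special.digamma(Y + th[None, :]) - special.digamma(th[None, :])
            + np.log(th[None, :]) + 1.0 - np.log(tm) - (Y + th[None, :]) / tm
        ).sum(axis=0)

    th = theta.copy()
    h = 0.05
    for _ in range(n_iter):
        s0 = score(th)
        s1 = score(th * np.exp(h))
        # d(score)/d(log theta) by forward difference; fall back to damped step
        dsl = (s1 - s0) / h
        grad_t = th * s0
        hess_t = th * dsl  # approx d(th*score)/dlog th ~ th*ds/dlogth near optimum
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(hess_t < 0, -grad_t / hess_t, np.sign(grad_t) * 0.3)
        step = np.nan_to_num(step, nan=0.0)
        step = np.clip(step, -1.5, 1.5)
        th = np.clip(th * np.exp(step), THETA_MIN, THETA_MAX)
    return th


def irls_fixed_theta(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    theta: np.ndarray,
    beta_init: np.ndarray | None = None,
    max_iter: int = 40,
    tol: float = 1e-8,
):
    """Lean batched IRLS at fixed per-column dispersion.

    Returns ``(beta, mu, qll)`` where ``qll`` is the log-likelihood kernel
    ``sum theta*log(theta/(theta+mu)) + y*log(mu/(theta+mu))`` — the gammaln
    terms are constant in mu at fixed theta, so likelihood *ratios* between
    nested fits of the same response are exact.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    p = X.shape[1]
    th = np.asarray(theta, dtype=float)[None, :]
    eye = np.eye(p) * 1e-9

    def _qll(mu):
        mu = np.clip(mu, 1e-12, None)
        return (
            th * np.log(th / (th + mu))
            + np.where(Y > 0, Y * np.log(mu / (th + mu)), 0.0)
        ).sum(axis=0)

    if beta_init is None:
        Z0 = np.log(Y + 0.5) - offset[:, None]
        beta, *_ = np.linalg.lstsq(X, Z0, rcond=None)
    else:
        beta = beta_init.copy()
    eta = np.clip(X @ beta + offset[:, None], -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    qll = _qll(mu)
    for _ in range(max_iter):
        w = mu * th / (th + mu)
        z = np.log(np.clip(mu, 1e-12, None)) - offset[:, None] + (Y - mu) / np.clip(mu, 1e-12, None)
        A = np.einsum("ip,im,iq->mpq", X, w, X) + eye[None, :, :]
        rhs = np.einsum("ip,im->mp", X, w * z)
        try:
            new_beta = np.linalg.solve(A, rhs[:, :, None])[:, :, 0].T
        except np.linalg.LinAlgError:
            break
        cand_mu = np.exp(np.clip(X @ new_beta + offset[:, None], -_ETA_CLIP, _ETA_CLIP))
        cand_qll = _qll(cand_mu)
        worse = cand_qll < qll - 1e-9
        tries = 0
        while worse.any() and tries < 5:
            new_beta[:, worse] = 0.5 * (new_beta[:, worse] + beta[:, worse])
            cand_mu = np.exp(np.clip(X @ new_beta + offset[:, None], -_ETA_CLIP, _ETA_CLIP))
            cand_qll = _qll(cand_mu)
            worse = cand_qll < qll - 1e-9
            tries += 1
        delta = np.max(np.abs(new_beta - beta))
        beta, mu, qll = new_beta, cand_mu, cand_qll
        if delta < tol:
            break
    zero_col = Y.sum(axis=0) == 0
    if zero_col.any():
        qll = qll.copy()
        qll[zero_col] = 0.0
    return beta, mu, qll


def pit_residuals(Y: np.ndarray, mu: np.ndarray, theta: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Randomized probability-integral-transform residuals under a fitted NB.

    u = F(y-1) + V * (F(y) - F(y-1)) with V ~ Uniform(0,1); u is Uniform(0,1)
    when the model is correct.
    """
    from scipy import stats

    th = np.broadcast_to(theta, mu.shape)
    pr = th / (th + mu)
    lower = stats.nbinom.cdf(Y - 1, th, pr)
    upper = stats.nbinom.cdf(Y, th, pr)
    V = rng.uniform(size=Y.shape)
    return np.clip(lower + V * (upper - lower), 1e-12, 1.0 - 1e-12)


def invert_pit_rowtable(U: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Precompute pseudo-counts for whole-row residual resampling.

    Returns ``T[s, i, j]`` = F^{-1}_{ij}(U[s, j]): the count obtained when the
    residual row ``s`` is placed at sample ``i`` and inverted through the null
    fitted distribution of cell ``(i, j)``.
    """
    from scipy import stats

    n, m = U.shape
    th = np.broadcast_to(theta, (n, m))
    pr = th / (th + mu)
    T = stats.nbinom.ppf(
        U[:, None, :], np.broadcast_to(th, (n, n, m)), np.broadcast_to(pr, (n, n, m))
    )
    return T


def invert_pit_rows(U_rows: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Invert one resampled residual matrix through the null fitted cells."""
    from scipy import stats

    th = np.broadcast_to(theta, mu.shape)
    pr = th / (th + mu)
    return stats.nbinom.ppf(U_rows, th, pr)
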