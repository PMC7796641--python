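"""Multivariate abundance testing: per-taxon NB GLMs, sum-of-LR resampling tests,
deviance partitioning and subject-vs-time variance-ratio estimation.

The community-level test fits a log-link negative-binomial model to every
taxon, with the log of per-sample total counts as an offset, and sums the
per-taxon likelihood-ratio statistics for the factor of interest. Its null
distribution is calibrated by PIT-trap resampling: probability-integral-
transform residuals are computed under the fitted null, whole sample **rows**
of the residual matrix are resampled with replacement (preserving cross-taxon
dependence — the property this residual bootstrap exists to protect), inverted
through each cell's null fitted distribution to pseudo-counts, and both models
are refitted. Per-taxon adjusted p-values come from the same resamples by a
step-down maxT procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _glmm, _nb
from .tables_io import CountTable, SampleRecord, metadata_by_sample

logger = logging.getLogger(__name__)

#: factors resolvable from SampleRecord fields
_FACTOR_GETTERS = {
    "subject": lambda r: r.subject_id,
    "time": lambda r: str(r.week),
    "sex": lambda r: r.sex or "NA",
    "age": lambda r: str(r.age_level) if r.age_level is not None else "NA",
    "pool": lambda r: r.pool_system or "NA",
    "sample_type": lambda r: r.sample_type,
}


@dataclass
class NbFit:
    """Single-taxon NB GLM fit (full-ML; the batched path backs the tests)."""

    taxon_id: str
    coefficients: dict
    theta: float
    log_likelihood: float
    deviance: float
    converged: bool

    def __post_init__(self):
        assert self.theta > 0
        assert self.deviance >= -1e-8


@dataclass
class MvTestResult:
    factor: str
    sum_of_lr: float
    p_value: float
    n_resamples: int
    per_taxon: pd.DataFrame
    seed: int
    n_samples: int
    nuisance: tuple = ()


@dataclass
class DeviancePartition:
    factor: str
    df: int
    explained_deviance: float
    reference_deviance: float
    pseudo_r2: float
    conditioning: tuple = ()


@dataclass
class VarianceRatio:
    sigma_subject: float
    sigma_time: float
    ratio: float
    per_taxon: pd.DataFrame
    aggregation: str = "median of per-taxon variances"
    time_at_boundary: bool = False


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _factor_labels(metadata: Sequence[SampleRecord], sample_ids, factor: str):
    meta = metadata_by_sample(metadata)
    try:
        get = _FACTOR_GETTERS[factor]
    except KeyError:
        raise ValueError(f"unknown factor {factor!r}; expected one of {sorted(_FACTOR_GETTERS)}")
    return [get(meta[s]) for s in sample_ids]


def _dummies(labels) -> np.ndarray:
    levels = sorted(set(labels))
    cols = [np.array([1.0 if l == lev else 0.0 for l in labels]) for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(labels), 0))


def build_design(metadata, sample_ids, factors: Sequence[str]) -> np.ndarray:
    """Intercept plus treatment-coded dummies for each factor, aliasing-checked."""
    parts = [np.ones((len(sample_ids), 1))]
    for f in factors:
        parts.append(_dummies(_factor_labels(metadata, sample_ids, f)))
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design for factors {tuple(factors)} is rank-deficient (aliased)")
    return X


# ---------------------------------------------------------------------------
# single-taxon fit
# ---------------------------------------------------------------------------

def fit_nb_glm(y, design: np.ndarray, offset, taxon_id: str = "",
               term_names: Sequence[str] | None = None) -> NbFit:
    """Full-ML NB GLM for one count vector (joint over coefficients and theta)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    offset = np.asarray(offset, dtype=float)
    if len(y) != X.shape[0] or len(y) != len(offset):
        raise ValueError("y, design and offset lengths disagree")
    fit = _nb.fit_many(y[:, None], X, offset, max_outer=60, max_inner=60, tol=1e-13)
    names = list(term_names) if term_names is not None else [f"b{k}" for k in range(X.shape[1])]
    theta = float(fit.theta[0])
    ll = float(fit.loglik[0])
    dev = float(2.0 * (_nb.nb_loglik_saturated(y[:, None], fit.theta) - fit.loglik)[0])
    return NbFit(
        taxon_id=taxon_id,
        coefficients=dict(zip(names, fit.beta[:, 0])),
        theta=theta,
        log_likelihood=ll,
        deviance=max(dev, 0.0),
        converged=bool(fit.converged[0]),
    )


# ---------------------------------------------------------------------------
# sum-of-LR PIT-trap test
# ---------------------------------------------------------------------------

def _paired_lr_fixed(Y, X_null, X_full, offset, theta, init_null=None, init_full=None):
    """Per-taxon LR between nested fits at fixed dispersion (clipped at 0)."""
    beta_n, mu_n, qll_n = _nb.irls_fixed_theta(Y, X_null, offset, theta, beta_init=init_null)
    beta_f, mu_f, qll_f = _nb.irls_fixed_theta(Y, X_full, offset, theta, beta_init=init_full)
    lr = np.maximum(2.0 * (qll_f - qll_n), 0.0)
    return lr, (beta_n, mu_n), (beta_f, mu_f)


def sum_of_lr_test(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    factor: str,
    nuisance_terms: Sequence[str] = (),
    n_resamples: int = 999,
    seed: int = 0,
    adjusted_p: bool = True,
    resample_method: str = "permutation",
    _row_table_limit: int = 40_000_000,
) -> MvTestResult:
    """Community-level sum-of-likelihood-ratio test for ``factor``.

    p = (1 + #{resampled statistic >= observed}) / (1 + n_resamples).

    Null calibration resamples whole sample rows of the PIT residual matrix,
    preserving cross-taxon dependence. The default resamples rows *without*
    replacement (a permutation of residual rows): with as many taxa as samples
    or more, with-replacement row duplication injects identical latent noise
    into every taxon at once and measurably widens the null distribution of
    the summed statistic, making the test conservative; ``bootstrap`` is
    available for comparison. Per-taxon dispersions are re-estimated on each
    pseudo-dataset (warm-started), mirroring their estimation on the observed
    data, so the statistic is computed by one recipe throughout.
    """
    if resample_method not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown resample_method {resample_method!r}")
    labels = _factor_labels(metadata, table.sample_ids, factor)
    if len(set(labels)) < 2:
        per_taxon = pd.DataFrame(
            {"taxon_id": table.taxon_ids, "lr": 0.0, "p_adj": 1.0}
        )
        return MvTestResult(factor=factor, sum_of_lr=0.0, p_value=1.0,
                            n_resamples=n_resamples, per_taxon=per_taxon,
                            seed=seed, n_samples=table.n_samples,
                            nuisance=tuple(nuisance_terms))
    X_null = build_design(metadata, table.sample_ids, nuisance_terms)
    X_full = build_design(metadata, table.sample_ids, tuple(nuisance_terms) + (factor,))
    offset = np.log(table.depths.astype(float))
    Y = table.counts.astype(float)
    n, m = Y.shape

    rng = np.random.default_rng(seed)
    null_est = _nb.fit_many(Y, X_null, offset, max_outer=6)
    theta = null_est.theta
    lr_obs, (beta_n, mu_n), (beta_f, _) = _paired_lr_fixed(
        Y, X_null, X_full, offset, theta, init_null=null_est.beta)
    stat_obs = float(lr_obs.sum())

    U = _nb.pit_residuals(Y, mu_n, theta[None, :], rng)
    use_table = n * n * m <= _row_table_limit
    T = _nb.invert_pit_rowtable(U, mu_n, theta[None, :]) if use_table else None

    stats_b = np.empty(n_resamples)
    lr_b = np.empty((n_resamples, m)) if adjusted_p else None
    rows_idx = np.arange(n)
    for b in range(n_resamples):
        if resample_method == "permutation":
            rows = rng.permutation(n)
        else:
            rows = rng.integers(0, n, size=n)
        if use_table:
            Ystar = T[rows, rows_idx, :]
        else:
            Ystar = _nb.invert_pit_rows(U[rows], mu_n, theta[None, :])
        # warm-started null fit, dispersion re-estimate, then both models
        bn1, mun1, _ = _nb.irls_fixed_theta(
            Ystar, X_null, offset, theta, beta_init=beta_n, max_iter=10)
        theta_b = _nb.theta_ml_update(Ystar, mun1, theta, n_iter=3)
        _, _, qn = _nb.irls_fixed_theta(
            Ystar, X_null, offset, theta_b, beta_init=bn1, max_iter=6)
        _, _, qf = _nb.irls_fixed_theta(
            Ystar, X_full, offset, theta_b, beta_init=beta_f, max_iter=10)
        lr = np.maximum(2.0 * (qf - qn), 0.0)
        stats_b[b] = lr.sum()
        if adjusted_p:
            lr_b[b] = lr
    p = float((1 + np.sum(stats_b >= stat_obs - 1e-9)) / (1 + n_resamples))

    if adjusted_p and n_resamples > 0:
        p_adj = _stepdown_maxt(lr_obs, lr_b)
    else:
        p_adj = np.full(m, np.nan)
    per_taxon = pd.DataFrame(
        {"taxon_id": table.taxon_ids, "lr": lr_obs, "p_adj": p_adj}
    )
    return MvTestResult(
        factor=factor, sum_of_lr=stat_obs, p_value=p, n_resamples=n_resamples,
        per_taxon=per_taxon, seed=seed, n_samples=n, nuisance=tuple(nuisance_terms),
    )


def _stepdown_maxt(lr_obs: np.ndarray, lr_b: np.ndarray) -> np.ndarray:
    """Westfall-Young step-down maxT adjusted p-values from resampled statistics."""
    m = lr_obs.size
    order = np.argsort(lr_obs)[::-1]
    # successive maxima over the tail of the ordering, per resample
    tail_max = np.maximum.accumulate(lr_b[:, order[::-1]], axis=1)[:, ::-1]
    B = lr_b.shape[0]
    p = (1 + (tail_max >= lr_obs[order][None, :] - 1e-9).sum(axis=0)) / (1 + B)
    p = np.maximum.accumulate(p)  # enforce monotonicity down the ordering
    out = np.empty(m)
    out[order] = p
    return out


# ---------------------------------------------------------------------------
# deviance partitioning
# ---------------------------------------------------------------------------

def deviance_partition(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    factors: Sequence[str] = ("subject", "time"),
    max_outer: int = 6,
) -> list:
    """Partition summed deviance between two factors (each conditioned on the other).

    For factor A given B: explained = 2 * sum_taxa (ll_{A+B} - ll_B) and the
    reference is the summed deviance of the B-only model, so the quotient is the
    share of the deviance left unexplained by B that A accounts for — a
    multivariate McFadden-style pseudo-R2. Dispersions are estimated once under
    the joint A+B model and held fixed across the nested fits, which makes the
    nesting inequalities (and pseudo_r2 in [0, 1]) exact.
    """
    a, b = factors
    offset = np.log(table.depths.astype(float))
    Y = table.counts.astype(float)
    joint_factors = (a,) if a == b else (a, b)  # duplicate factor adds nothing
    X_ab = build_design(metadata, table.sample_ids, joint_factors)
    joint = _nb.fit_many(Y, X_ab, offset, max_outer=max_outer)
    theta = joint.theta
    ll_sat = _nb.nb_loglik_saturated(Y, theta)

    def _ll(factors_used):
        X = build_design(metadata, table.sample_ids, factors_used)
        fit = _nb.fit_many(Y, X, offset, theta=theta, max_outer=1, max_inner=100)
        return fit.loglik

    ll_joint = _nb.fit_many(Y, X_ab, offset, theta=theta, max_outer=1, max_inner=100).loglik
    out = []
    for target, cond in ((a, b), (b, a)):
        ll_cond = _ll((cond,))
        explained = float(2.0 * np.maximum(ll_joint - ll_cond, 0.0).sum())
        reference = float(2.0 * np.maximum(ll_sat - ll_cond, 0.0).sum())
        df = len(set(_factor_labels(metadata, table.sample_ids, target))) - 1
        out.append(
            DeviancePartition(
                factor=target, df=df, explained_deviance=explained,
                reference_deviance=reference,
                pseudo_r2=explained / reference if reference > 0 else 0.0,
                conditioning=(cond,),
            )
        )
    return out


# ---------------------------------------------------------------------------
# variance ratio
# ---------------------------------------------------------------------------

def variance_ratio(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    max_taxa: int | None = None,
    boundary_sigma: float = 0.05,
) -> VarianceRatio:
    """Subject-vs-time random-effect SD ratio, pooled across per-taxon NB GLMMs.

    Each taxon gets a log-link NB model with random intercepts for subject and
    for week (Laplace-approximate ML); per-taxon dispersions come from a
    fixed-effect NB fit with both factors. Components are pooled as the median
    of per-taxon variances; the ratio is the ratio of pooled SDs. When the
    pooled time SD sits at the boundary the ratio is flagged rather than
    trusted.
    """
    meta = metadata_by_sample(metadata)
    blow = [s for s in table.sample_ids if meta[s].sample_type == "blow"]
    sub = table.select_samples(blow)
    subjects = sorted({meta[s].subject_id for s in blow})
    weeks = sorted({meta[s].week for s in blow})
    if len(subjects) < 3 or len(weeks) < 3:
        raise ValueError("variance_ratio needs >= 3 subjects and >= 3 time points")
    if max_taxa is not None and sub.n_taxa > max_taxa:
        totals = sub.counts.sum(axis=0)
        keep = np.argsort(totals)[::-1][:max_taxa]
        sub = sub.select_taxa([sub.taxon_ids[i] for i in sorted(keep)])
    nonzero = sub.counts.sum(axis=0) > 0
    sub = sub.select_taxa([t for t, nz in zip(sub.taxon_ids, nonzero) if nz])

    subject_idx = np.array([subjects.index(meta[s].subject_id) for s in sub.sample_ids])
    time_idx = np.array([weeks.index(meta[s].week) for s in sub.sample_ids])
    offset = np.log(sub.depths.astype(float))
    Y = sub.counts.astype(float)

    X = build_design(metadata, sub.sample_ids, ("subject", "time"))
    fixed = _nb.fit_many(Y, X, offset, max_outer=6)
    theta = np.clip(fixed.theta, 0.05, 1e4)

    sig_s, sig_t, _ = _glmm.fit_variance_components(Y, subject_idx, time_idx, offset, theta)
    var_s = float(np.median(sig_s**2))
    var_t = float(np.median(sig_t**2))
    pooled_s, pooled_t = np.sqrt(var_s), np.sqrt(var_t)
    at_boundary = pooled_t < boundary_sigma
    ratio = pooled_s / pooled_t if pooled_t > 0 else np.inf
    per_taxon = pd.DataFrame(
        {"taxon_id": sub.taxon_ids, "sigma_subject": sig_s, "sigma_time": sig_t,
         "theta": theta}
    )
    return VarianceRatio(
        sigma_subject=pooled_s, sigma_time=pooled_t, ratio=float(ratio),
        per_taxon=per_taxon, time_at_boundary=bool(at_boundary),
    )
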