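"""NB GLM fitting, sum-of-LR resampling test, deviance partition, variance ratio."""

import numpy as np
import pytest

from blowcore import _nb
from blowcore.multivariate_abundance import (
    build_design,
    deviance_partition,
    fit_nb_glm,
    sum_of_lr_test,
    variance_ratio,
)
from blowcore.synthetic_cohort import CohortParams, generate_cohort


def _toy(n=8, seed=0, theta=1.0):
    rng = np.random.default_rng(seed)
    x = (np.arange(n) % 2).astype(float)
    X = np.column_stack([np.ones(n), x])
    off = np.log(rng.uniform(800, 3000, n))
    mu = np.exp(-5.5 + 0.8 * x + off)
    y = rng.poisson(rng.gamma(theta, mu / theta)).astype(float)
    return y, X, off


class TestFitNbGlm:
    def test_all_zero_response_has_zero_lr(self):
        n = 8
        X = np.column_stack([np.ones(n), (np.arange(n) % 2).astype(float)])
        off = np.log(np.full(n, 1000.0))
        y = np.zeros(n)
        full = fit_nb_glm(y, X, off)
        null = fit_nb_glm(y, X[:, :1], off)
        assert 2 * (full.log_likelihood - null.log_likelihood) == pytest.approx(0.0, abs=1e-9)

    def test_poisson_limit_matches_poisson_glm(self):
        """Equidispersed counts push theta to the clamp; coefficients match Poisson."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 40
        x = (np.arange(n) % 2).astype(float)
        X = np.column_stack([np.ones(n), x])
        off = np.log(np.full(n, 2000.0))
        y = rng.poisson(np.exp(-4.0 + 0.5 * x + off)).astype(float)
        fit = fit_nb_glm(y, X, off)
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        assert fit.theta == pytest.approx(_nb.THETA_MAX)
        assert np.allclose(list(fit.coefficients.values()), pois.params, atol=1e-4)

    def test_deviance_nonnegative_and_theta_positive(self):
        y, X, off = _toy(seed=3, theta=0.6)
        fit = fit_nb_glm(y, X, off)
        assert fit.theta > 0
        assert fit.deviance >= 0

    def test_batched_matches_single(self):
        """fit_many on stacked columns reproduces per-column fits."""
        ys = []
        for s in range(4):
            y, X, off = _toy(seed=s, theta=1.0)
            ys.append(y)
        Y = np.column_stack(ys)
        batch = _nb.fit_many(Y, X, off, max_outer=60, max_inner=60, tol=1e-13)
        for j in range(4):
            single = fit_nb_glm(Y[:, j], X, off)
            assert batch.loglik[j] == pytest.approx(single.log_likelihood, abs=1e-6)


@pytest.fixture(scope="module")
def cohort():
    params = CohortParams(
        n_subjects=6, weeks=(2, 6, 11), n_blow_taxa=40, core_size_mean=0,
        transient_presence_prob=1.0, n_water_taxa=0, n_contam_taxa=0,
        n_water_samples=0, n_pos_controls=0, n_neg_controls=0,
        n_extraction_blanks=0, rng_seed=3,
    )
    return generate_cohort(params)[:2]


class TestSumOfLr:

    def test_single_level_factor_gives_null_result(self, cohort):
        table, meta = cohort
        for r in meta:
            r.sex = "F"
        res = sum_of_lr_test(table, meta, "sex", n_resamples=9, seed=0)
        assert res.sum_of_lr == 0.0
        assert res.p_value == 1.0

    def test_statistic_is_sum_of_per_taxon_lr(self, cohort):
        table, meta = cohort
        res = sum_of_lr_test(table, meta, "time", n_resamples=19, seed=1)
        assert res.sum_of_lr == pytest.approx(res.per_taxon["lr"].sum(), abs=1e-8)
        assert 0 < res.p_value <= 1
        assert res.p_value >= 1 / (res.n_resamples + 1)

    def test_reproducible_given_seed(self, cohort):
        table, meta = cohort
        r1 = sum_of_lr_test(table, meta, "time", n_resamples=19, seed=5)
        r2 = sum_of_lr_test(table, meta, "time", n_resamples=19, seed=5)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.per_taxon["p_adj"], r2.per_taxon["p_adj"])

    def test_planted_subject_effect_detected(self):
        params = CohortParams(
            n_subjects=6, weeks=(2, 6, 11, 19), n_blow_taxa=50, core_size_mean=0,
            transient_presence_prob=1.0, n_water_taxa=0, n_contam_taxa=0,
            n_water_samples=0, n_pos_controls=0, n_neg_controls=0,
            n_extraction_blanks=0, sigma_subject=1.0, sigma_time=0.1, rng_seed=9,
        )
        table, meta, *_ = generate_cohort(params)
        res = sum_of_lr_test(table, meta, "subject", n_resamples=99, seed=2)
        assert res.p_value <= 0.02

    def test_adjusted_p_monotone_in_lr(self, cohort):
        table, meta = cohort
        res = sum_of_lr_test(table, meta, "time", n_resamples=49, seed=2)
        df = res.per_taxon.sort_values("lr", ascending=False)
        assert (np.diff(df["p_adj"]) >= -1e-12).all()

    def test_monotone_nesting_of_likelihood(self, cohort):
        """Adding a factor never decreases the summed fixed-theta log-likelihood."""
        table, meta = cohort
        Y = table.counts.astype(float)
        off = np.log(table.depths.astype(float))
        X0 = build_design(meta, table.sample_ids, ())
        X1 = build_design(meta, table.sample_ids, ("time",))
        est = _nb.fit_many(Y, X0, off, max_outer=6)
        _, _, q0 = _nb.irls_fixed_theta(Y, X0, off, est.theta, beta_init=est.beta)
        _, _, q1 = _nb.irls_fixed_theta(Y, X1, off, est.theta)
        assert (q1 - q0 >= -1e-6).all()

    def test_aliased_design_rejected(self, cohort):
        table, meta = cohort
        with pytest.raises(ValueError, match="rank|alias"):
            sum_of_lr_test(table, meta, "subject", nuisance_terms=("subject",),
                           n_resamples=9, seed=0)


@pytest.fixture(scope="module")
def cohort_time_null():
    params = CohortParams(
        n_subjects=6, weeks=(2, 6, 11, 19), n_blow_taxa=60, core_size_mean=0,
        transient_presence_prob=1.0, n_water_taxa=0, n_contam_taxa=0,
        n_water_samples=0, n_pos_controls=0, n_neg_controls=0,
        n_extraction_blanks=0, sigma_subject=0.8, sigma_time=0.0, rng_seed=21,
    )
    return generate_cohort(params)[:2]


class TestDeviancePartition:

    def test_duplicate_factor_explains_nothing(self, cohort_time_null):
        table, meta = cohort_time_null
        parts = deviance_partition(table, meta, factors=("subject", "subject"))
        assert parts[0].explained_deviance == pytest.approx(0.0, abs=1e-6)

    def test_subject_dominates_when_time_null(self, cohort_time_null):
        table, meta = cohort_time_null
        parts = {p.factor: p for p in deviance_partition(table, meta)}
        assert parts["subject"].pseudo_r2 > 3 * parts["time"].pseudo_r2
        # with no true time effect, the time share is pure LR noise: each taxon
        # contributes ~df_time deviance units in expectation, small-sample
        # inflation included, so bound it by 2.5x that level
        noise = table.n_taxa * parts["time"].df / parts["time"].reference_deviance
        assert parts["time"].pseudo_r2 < 2.5 * noise
        for p in parts.values():
            assert 0.0 <= p.pseudo_r2 <= 1.0
            assert p.explained_deviance >= 0
        assert parts["subject"].df == 5
        assert parts["time"].df == 3


class TestVarianceRatio:
    def test_degenerate_time_flagged(self):
        params = CohortParams(
            n_subjects=6, weeks=(2, 6, 11), n_blow_taxa=40, core_size_mean=0,
            transient_presence_prob=1.0, n_water_taxa=0, n_contam_taxa=0,
            n_water_samples=0, n_pos_controls=0, n_neg_controls=0,
            n_extraction_blanks=0, sigma_subject=0.8, sigma_time=0.0, rng_seed=13,
        )
        table, meta, *_ = generate_cohort(params)
        vr = variance_ratio(table, meta)
        assert vr.time_at_boundary
        assert vr.sigma_time < 0.05
        assert vr.ratio > 5

    def test_needs_enough_levels(self, small_cohort):
        table, meta, *_ = small_cohort
        two_weeks = [r.sample_id for r in meta
                     if r.sample_type == "blow" and r.week in (2, 6)]
        sub = table.select_samples(two_weeks)
        with pytest.raises(ValueError):
            variance_ratio(sub, meta)
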