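# Methods

This note records the models, the synthetic-data design, the numerical
choices, and the places where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic cohort generator

The generator (`blowcore.synthetic_cohort`) emulates a longitudinal captive
study: `n_subjects = 13` animals sampled at study weeks {2, 6, 11, 19, 28,
37}, one water sample per pool system per sampling event (28 in total), and a
set of technical controls (2 positive, 7 negative PCR controls, 4 extraction
blanks). Three disjoint taxon pools are planted: 1471 true blow taxa, 520
water-associated taxa, 157 technical contaminants.

**Count model.** For sample *(i, t)* and taxon *j*, relative weights are

    w_j(i, t) = base_j · boost_ij · occupancy_ijt · exp(b_ij + u_tj)

normalized within the sample and scaled by a library size `L_it` drawn
log-normal, moment-matched to mean 29,168 / sd 13,578 reads (log-normal
rather than gamma: strictly positive with the heavy right tail implied by
sd ≈ 0.47 × mean). Counts are negative binomial with dispersion θ
(var = μ + μ²/θ), drawn as an exact gamma-Poisson mixture so non-integer θ is
exact. The shared default θ = 2 represents residual (post-effects)
replicate-level noise; per-taxon dispersion is available by flag.

**Planted cores.** Each subject draws a core of size ~Poisson(176) from the
blow taxa, weighted by a shared log-normal "popularity" (log-sd 2.0); popular
taxa recur across subjects, so an inter-core emerges as a consequence rather
than being planted directly (and is, by construction, a subset of the
intra-cores). Core members get their own weight profile
`exp(0.8·z_pop + N(0, 0.8²))`, coupled to popularity: the taxa shared across
animals are also the consistently abundant ones, which is what gives the
cross-subject community a high read share (the study conditions put it at
17–41% of reads). Core members take the time wobble `u_tj` but not a second
subject effect — their subject-level variation *is* the per-subject weight
draw. The per-subject boost has a closed form,

    boost_i = target/(1−target) · S_out,i / S_in,i ,

with `S_in`/`S_out` the expected effective core/non-core weight mass
(occupancy thinning and the log-normal means of the random effects included),
so the expected core read fraction equals `core_frac_target = 0.73` exactly —
a one-dimensional calibration solved analytically instead of by root finding.

**Transients.** Non-core blow taxa are present in a given blow sample only
with probability `transient_presence_prob = 0.4`, on top of NB sampling
zeros. Persistence is the defining property of a core; a generator whose
"non-core" taxa never blink out would make the presence-based core rule
meaningless. The value 0.4 makes a typical transient survive all four
intra-core weeks with probability ≈ 0.4⁴ ≈ 2.6%, which leaves the detected
cores close to the planted ones (the acceptance suite measures sensitivity
and the read-fraction calibration directly).

**Leakage.** Water taxa leak into blow samples (presence probability 0.10 at
2% relative weight), contaminants into blow at 0.02; blow taxa cross-talk
into water (0.05) and controls (0.02). Controls carry the contaminant pool at
90% occupancy, positive controls additionally a 50× genomic-DNA spike taxon.

**Random effects.** `b_ij ~ N(0, σ_subject²)` and `u_tj ~ N(0, σ_time²)` on
the log scale, defaults σ_subject = 0.7, σ_time = 0.2 (ratio 3.5). The
realized ratio of the drawn effects is recorded in the truth object.

**`null_cohort`** generates a cohort in which a named factor (sex, age,
treatment, pool) has exactly zero effect while its labels are still assigned.
It also zeroes the subject/time random effects, the cores and the occupancy
thinning: those are subject- or sample-level processes orthogonal to the
factor, and the calibration harness needs rows exchangeable under the null —
otherwise a rejection measures the factor's confounding with repeated
measures, not the resampling machinery.

**What the generator does not emulate.** Sequence-level artifacts (chimeras,
primer bias), taxon-taxon interactions, compositional correlation beyond the
shared normalization, occupancy autocorrelation over time, and realistic
per-sample richness: with 0.4 occupancy over 1295 transients, simulated blow
samples run ~450–500 observed taxa, above the few hundred typical of real
blow libraries. Passing recovery tests therefore demonstrate correctness of
the estimators under a known NB world, not field performance on real blow
data.

## QC cascade

Order: taxonomy screen → relative-abundance filter (< 1e-6 of all reads
removed; exactly at threshold retained) → depth cutoff (< 6000 reads removed;
exactly 6000 retained) → technical decontamination → water decontamination.
Prevalence scores use presence = count > 0, so per-sample depth normalization
cannot change any decision and is a documented no-op. The exact
(hypergeometric one-sided tail) branch replaces the Yates-corrected
chi-square whenever an expected cell is below 5 — the standard small-sample
rule, and it keeps scores defined when a taxon is absent from an entire
class. Controls for the technical stage are negative PCR controls and
extraction blanks; positive controls carry deliberate foreign DNA and are
excluded from both classes, then dropped with the rest of the technical
samples after the stage. Removal is score < 0.5 in the `is_contaminant`
direction; the `is_not_contaminant` direction is computed and reported but
not used for removal.

## Alpha diversity

Shannon is reported in nats (base configurable). Chao1 is the bias-corrected
form (finite at F₂ = 0); the classic form is a flag. ACE uses the
conventional rare cutoff of 10; when every rare read is a singleton the ACE
coverage is zero, and the record is flagged with a Chao1 fallback. Metrics
are computed on a single deterministic rarefied draw per seed (draw-averaged
rarefaction would shrink the estimator variance the downstream LMM assumes).
Expected rarefaction curves use the exact hypergeometric formula.

The subject/time tests fit, by ML, `metric ~ factor` with a random intercept
for the complementary factor and continuous-AR(1) residuals (`φ^|Δweek|`)
within subject, via direct marginal-likelihood optimization (Nelder-Mead over
log-SDs and atanh φ, three starts). With fewer than three distinct weeks φ is
fixed at 0. The reported fixed-effect p-value is the **F transformation** of
the Gaussian LRT, `F = (e^{LRT/n} − 1)(n − p)/q ~ F(q, n−p)`: at n ≈ 30–80
the χ² reference is visibly anticonservative (ML, no REML correction) while
the F form gives near-uniform null p-values; the χ² p-value is kept as a
secondary field. The importance of the random intercept itself is assessed by
a parametric bootstrap of its boundary LRT (default 500 refits), not by a χ²
mixture.

## Beta ordination

Bray-Curtis on raw (unrarefied) counts. NMDS minimizes Kruskal stress-1 with
disparities from isotonic regression (pool-adjacent-violators, ties averaged),
optimized by SMACOF; the best of 20 seeded random starts plus one classical
(Torgerson) metric-MDS start is returned, with stress-1 recomputed
independently of the optimizer for the reported value. Exactly embeddable
inputs converge through the metric start without luck; an all-equal
dissimilarity matrix converges (degenerate) with a warning rather than a
crash.

## Multivariate abundance

`fit_nb_glm` is full joint ML (alternating batched IRLS for coefficients and
damped Newton in log θ, θ clamped to [1e-3, 1e6]; at the upper clamp the fit
is numerically Poisson). All-zero taxa are fitted at μ ≈ 0 with
log-likelihood defined as 0, so LR contributions vanish.

The **sum-of-LR test** fixes per-taxon θ at its observed-null ML estimate,
computes the LR kernel (the gammaln terms cancel at fixed θ), and calibrates
by resampling whole rows of the randomized PIT residual matrix
`u = F(y−1) + V·(F(y)−F(y−1))` under the fitted null, inverting each
resampled row through the target cell's null distribution. Rows are resampled
**without replacement** (a permutation) by default: with as many taxa as
samples or more, with-replacement duplication of residual rows injects
identical latent noise into every taxon simultaneously and widens the
resampled null of the summed statistic well beyond its true sampling spread,
driving rejection rates to zero; the permutation variant with per-resample θ
re-estimation (warm-started) is calibrated at the nominal level in the
acceptance suite's 200-simulation study. With-replacement resampling remains
available (`resample_method="bootstrap"`). p = (1 + exceedances)/(1 + B);
per-taxon adjusted p-values use the same resamples through step-down maxT.

**Deviance partition.** For factors A, B: explained(A|B) =
2Σ(ℓ_{A+B} − ℓ_B); the reference is the summed deviance of the B-only model
(2Σ(ℓ_sat − ℓ_B)), so the quotient is the share of deviance unexplained by B
that A accounts for. θ is estimated once under A+B and held fixed across the
nested fits, making the nesting inequalities — and pseudo-R² ∈ [0, 1] —
exact. Both numerator and denominator are reported so either normalization
convention is recoverable. Time enters categorically (one level per week).

**Variance ratio.** Per taxon, a log-link NB model with random intercepts for
subject and week is fitted by profile-Laplace ML: the joint mode of
(intercept, b, u) by batched Fisher-Newton (the intercept unpenalized and
excluded from the Laplace determinant), and the outer search over
(log σ_s, log σ_t) on a 7×7 common grid refined twice per taxon (final
spacing a few percent, warm-started modes across grid points). θ per taxon
comes from a fixed-effect NB fit with both factors, clamped to [0.05, 1e4].
Components pool as the median of per-taxon variances; a pooled time-SD below
0.05 flags the ratio as boundary-degenerate rather than trusted. This
per-taxon-then-pool route targets the same estimand as one joint
multivariate fit at a fraction of the cost; the aggregation rule is recorded
in the output.

## Core detection

Presence means count > 0 — no abundance threshold. A missing required week
may be repaired by a sample within ±1 week (earlier sample preferred on
ties, logged); subjects that still lack a week are excluded from intra-core
analysis rather than scored on fewer samples. Inter-core selection of 10
subjects is uniform without replacement under a recorded seed, re-drawn per
week under one master seed (whether a single draw was reused across weeks
was an open choice; re-drawing is recorded in the output so either analysis
is reproducible). Abundance summaries are computed on the post-filter,
unrarefied table — the fractions are depth-normalized by construction.

## Treatment phases

Blow samples of treated subjects are labelled Before (before the first
treatment start), Directly_After (≤ 7 days after the most recent treatment
end), or After (≥ 14 days); untreated subjects are None. Two windows the
four-label scheme leaves open are resolved conservatively and logged:
samples taken *during* an active interval and samples in the 8–13-day gap
are both Directly_After (recently-treated is the safer reading for a
transition window).

## Pipeline

One master seed fans out through `SeedSequence.spawn` to every stochastic
stage, so stages are independently re-runnable yet reproducible; the run
ledger records per-stage sample/taxon counts (taxa_in − removed = taxa_out is
asserted in tests), seeds, parameters and output paths, and is flushed after
every stage so a failed run leaves its partial ledger.

## Problem sizes used in validation

The test suite validates at deliberately compact sizes: the type-I-error
study uses 200 null cohorts of 8 subjects × 4 weeks × 100 taxa with 199
resamples; variance-ratio recovery uses 13 subjects × 6 weeks × 200 taxa over
10 seeds per planted ratio; core recovery uses the full default cohort
(13 × 6, 2148 taxa) over 10 seeds. The acceptance script runs the complete
pipeline once at the default study conditions with 99 resamples for the
community tests and the top-200 taxa for the variance ratio, plus one
planted-ratio recovery cohort.
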