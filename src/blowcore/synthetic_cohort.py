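"""Synthetic longitudinal blow-microbiota cohorts with planted ground truth.

The generator emulates a captive-dolphin study design: ``n_subjects`` animals
sampled at fixed study weeks, pool-water samples collected alongside, and a
small set of technical-control samples (negative PCR controls, extraction
blanks, positive controls carrying a genomic spike). Taxa fall into three
disjoint pools — true blow taxa, pool-water taxa that leak into blow at a low
rate, and technical-contaminant taxa concentrated in the controls.

Each subject carries a planted persistent community (its *intra-core*): a
subset of blow taxa, drawn with a shared "popularity" bias so that a small pool
of taxa recurs across subjects and an inter-core emerges without being planted
explicitly. Core taxa receive a per-subject abundance boost calibrated in
closed form so that the expected fraction of a blow sample's reads coming from
the core equals ``core_frac_target``. Non-core blow taxa are transient: beyond
negative-binomial sampling noise, each is present in a given blow sample only
with probability ``transient_presence_prob`` — persistent presence is what
distinguishes the core, and the transients' churn is what a presence-based
core rule has to cut through.

Log expected counts follow

    eta_ij(t) = log L_it + log q_ij(t),   q ~ normalized weights, with
    weight_j(i, t) = base_j * boost_ij * exp(b_ij + u_tj)

where ``b_ij ~ N(0, sigma_subject^2)`` and ``u_tj ~ N(0, sigma_time^2)`` are
per-taxon subject and time effects on the log scale, and library sizes L are
log-normal, moment-matched to ``library_size_mean``/``sd``. Counts are
negative binomial with dispersion ``theta`` (var = mu + mu^2/theta), drawn as a
gamma-Poisson mixture so non-integer theta is exact.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
import numpy as np

from .tables_io import CountTable, SampleRecord, TaxonomyRecord

_STUDY_START = _dt.date(2017, 4, 3)  # Monday of study week 0
_POOLS = ("Dolphin_Bay", "Dolphin_Beach", "Endeavour", "QVC")


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort generator (defaults = study conditions)."""

    n_subjects: int = 13
    weeks: tuple = (2, 6, 11, 19, 28, 37)
    n_blow_taxa: int = 1471
    n_water_taxa: int = 520
    n_contam_taxa: int = 157
    n_offtarget_taxa: int = 0
    library_size_mean: float = 29168.0
    library_size_sd: float = 13578.0
    control_library_mean: float = 20000.0
    control_library_sd: float = 6000.0
    core_frac_target: float = 0.73
    core_size_mean: float = 176.0
    sigma_subject: float = 0.7
    sigma_time: float = 0.2
    nb_dispersion: float = 2.0
    per_taxon_dispersion: bool = False
    treatment_effect_size: float = 0.0
    n_treated_subjects: int = 4
    # abundance-profile shape
    baseline_sigma: float = 1.5     # log-sd of transient blow-taxon base weights
    core_weight_sigma: float = 0.8  # log-sd of core-member weights within a subject
    popularity_sigma: float = 2.0   # log-sd of the shared core-membership bias
    share_coupling: float = 0.8     # how strongly shared (popular) taxa are also abundant
    transient_presence_prob: float = 0.4
    # cross-compartment leakage
    water_leak_prob: float = 0.10   # water taxon present in a blow sample
    water_leak_scale: float = 0.02  # relative weight of a leaked water taxon
    contam_leak_prob: float = 0.02
    contam_leak_scale: float = 0.01
    blow_in_water_prob: float = 0.05
    blow_in_control_prob: float = 0.02
    # control-sample layout (positive PCR controls, negative PCR controls, blanks)
    n_pos_controls: int = 2
    n_neg_controls: int = 7
    n_extraction_blanks: int = 4
    n_water_samples: int = 28
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0 or self.n_blow_taxa <= 0:
            raise ValueError("n_subjects and n_blow_taxa must be positive")
        if self.n_water_taxa < 0 or self.n_contam_taxa < 0 or self.n_offtarget_taxa < 0:
            raise ValueError("taxon pool sizes must be non-negative")
        if not self.weeks:
            raise ValueError("weeks must be non-empty")
        if not 0.0 < self.core_frac_target < 1.0:
            raise ValueError("core_frac_target must be in (0, 1)")
        if self.sigma_subject < 0 or self.sigma_time < 0:
            raise ValueError("sigma_subject and sigma_time must be >= 0")
        if self.library_size_mean <= 0 or self.library_size_sd < 0:
            raise ValueError("library size parameters must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 < self.transient_presence_prob <= 1.0:
            raise ValueError("transient_presence_prob must be in (0, 1]")
        if self.core_size_mean < 0:
            raise ValueError("core_size_mean must be >= 0")
        if self.core_size_mean > self.n_blow_taxa:
            raise ValueError(
                f"core_size_mean ({self.core_size_mean}) cannot exceed n_blow_taxa "
                f"({self.n_blow_taxa}); core_frac_target is unreachable"
            )


@dataclass
class SyntheticTruth:
    """Planted structure of one generated cohort, for recovery tests."""

    core_sets: dict                      # subject_id -> frozenset of taxon_ids
    inter_core: frozenset                # taxa in >= 10 subjects' planted cores
    blow_taxa: frozenset
    water_taxa: frozenset
    contaminant_taxa: frozenset
    offtarget_taxa: frozenset
    realized_sigma_ratio: float          # sd(b) / sd(u) of the drawn effects
    sigma_subject: float
    sigma_time: float
    expected_counts: np.ndarray          # samples x taxa, E[count]
    sample_ids: tuple
    taxon_ids: tuple
    core_boosts: dict = field(default_factory=dict)  # subject_id -> boost factor

    def summary(self) -> dict:
        return {
            "n_subjects_with_core": sum(1 for s in self.core_sets.values() if s),
            "mean_core_size": float(np.mean([len(s) for s in self.core_sets.values()]))
            if self.core_sets
            else 0.0,
            "n_inter_core": len(self.inter_core),
            "n_blow_taxa": len(self.blow_taxa),
            "n_water_taxa": len(self.water_taxa),
            "n_contaminant_taxa": len(self.contaminant_taxa),
            "realized_sigma_ratio": self.realized_sigma_ratio,
        }


def _week_date(week: int) -> _dt.date:
    return _STUDY_START + _dt.timedelta(weeks=int(week))


def _lognormal_params(mean: float, sd: float):
    """Moment-match a log-normal to the given mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta) -> np.ndarray:
    """Negative binomial draw via the exact gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-300) / theta)
    lam = np.where(mean > 0, lam, 0.0)
    return rng.poisson(lam)


def generate_cohort(params: CohortParams):
    """Generate one cohort: returns ``(CountTable, metadata, taxonomy, SyntheticTruth)``."""
    rng = np.random.default_rng(params.rng_seed)
    subjects = [f"D{i + 1:02d}" for i in range(params.n_subjects)]
    blow_taxa = [f"zotu{j + 1:04d}" for j in range(params.n_blow_taxa)]
    water_taxa = [f"water{j + 1:04d}" for j in range(params.n_water_taxa)]
    contam_taxa = [f"contam{j + 1:04d}" for j in range(params.n_contam_taxa)]
    offtarget_taxa = [f"offtarget{j + 1:03d}" for j in range(params.n_offtarget_taxa)]
    taxa = blow_taxa + water_taxa + contam_taxa + offtarget_taxa
    n_blow, n_water, n_contam = params.n_blow_taxa, params.n_water_taxa, params.n_contam_taxa

    # --- subject attributes --------------------------------------------------
    sexes = [("F" if i % 2 else "M") for i in range(params.n_subjects)]
    ages = [1 + (i % 4) for i in range(params.n_subjects)]
    pools = [_POOLS[i % min(3, len(_POOLS))] for i in range(params.n_subjects)]
    treated = subjects[-min(params.n_treated_subjects, params.n_subjects):] if params.n_treated_subjects else []
    # one interval per treated subject, ending shortly before a mid-study week
    treat_intervals = {}
    mid_weeks = [9, 10, 13, 16]
    for k, s in enumerate(treated):
        end = _week_date(mid_weeks[k % len(mid_weeks)])
        start = end - _dt.timedelta(weeks=2 + (k % 3))
        treat_intervals[s] = [(start, end)]

    # --- planted cores -------------------------------------------------------
    popularity = np.exp(rng.normal(0.0, params.popularity_sigma, size=n_blow))
    pop_p = popularity / popularity.sum()
    core_sets: dict = {}
    core_masks = np.zeros((params.n_subjects, n_blow), dtype=bool)
    for i, s in enumerate(subjects):
        size = 0
        if params.core_size_mean > 0:
            size = min(int(rng.poisson(params.core_size_mean)), n_blow)
        idx = rng.choice(n_blow, size=size, replace=False, p=pop_p) if size else np.array([], int)
        core_masks[i, idx] = True
        core_sets[s] = frozenset(blow_taxa[j] for j in idx)
    core_count = core_masks.sum(axis=0)
    inter_thresh = min(10, params.n_subjects)
    inter_core = frozenset(
        blow_taxa[j] for j in np.nonzero(core_count >= inter_thresh)[0]
    ) if params.core_size_mean > 0 else frozenset()

    # --- abundance machinery -------------------------------------------------
    base = np.exp(rng.normal(0.0, params.baseline_sigma, size=n_blow))
    # core-member weights couple to the shared popularity: taxa that recur
    # across subjects' cores are also the consistently abundant ones, which is
    # what gives the cross-subject shared community its high read share
    zpop = np.log(popularity) / params.popularity_sigma
    core_w = np.exp(
        params.share_coupling * zpop[None, :]
        + rng.normal(0.0, params.core_weight_sigma, size=(params.n_subjects, n_blow))
    )
    water_base = np.exp(rng.normal(0.0, 1.2, size=n_water)) if n_water else np.zeros(0)
    contam_base = np.exp(rng.normal(0.0, 1.0, size=n_contam)) if n_contam else np.zeros(0)
    offtarget_base = np.exp(rng.normal(0.0, 1.0, size=params.n_offtarget_taxa))

    b_eff = rng.normal(0.0, params.sigma_subject, size=(params.n_subjects, n_blow))
    u_eff = rng.normal(0.0, params.sigma_time, size=(len(params.weeks), n_blow))
    if params.sigma_subject > 0 and params.sigma_time > 0:
        realized_ratio = float(b_eff.std(ddof=1) / u_eff.std(ddof=1))
    elif params.sigma_time == 0 and params.sigma_subject > 0:
        realized_ratio = float("inf")
    else:
        realized_ratio = float("nan") if params.sigma_subject == 0 and params.sigma_time == 0 else 0.0

    theta_taxa = (
        np.exp(rng.normal(np.log(params.nb_dispersion), 0.4, size=len(taxa)))
        if params.per_taxon_dispersion
        else np.full(len(taxa), params.nb_dispersion)
    )

    # closed-form core boost: expected core read share = core_frac_target
    target = params.core_frac_target
    boosts = {}
    for i, s in enumerate(subjects):
        mask = core_masks[i]
        # core members carry the subject-level time wobble only; transients also
        # carry the subject effect — the lognormal means of those effects enter
        # the expected-weight balance
        s_in = float(core_w[i][mask].sum()) * np.exp(params.sigma_time**2 / 2.0)
        # expected effective non-core weight: transients thinned by occupancy,
        # plus the water-leak mass that competes for reads in blow samples
        s_out = (
            float(base[~mask].sum()) * params.transient_presence_prob
            * np.exp((params.sigma_subject**2 + params.sigma_time**2) / 2.0)
        )
        if n_water:
            s_out += params.water_leak_prob * params.water_leak_scale * float(water_base.sum())
        if n_contam:
            s_out += params.contam_leak_prob * params.contam_leak_scale * float(contam_base.sum())
        if mask.any():
            if s_in <= 0:
                raise ValueError("core_frac_target unreachable: empty effective core weight")
            boosts[s] = target / (1.0 - target) * s_out / s_in
        else:
            boosts[s] = 1.0

    # --- assemble samples ----------------------------------------------------
    mu_log, sig_log = _lognormal_params(params.library_size_mean, params.library_size_sd)
    cmu_log, csig_log = _lognormal_params(params.control_library_mean, params.control_library_sd)

    sample_ids: list = []
    metadata: list = []
    rows: list = []

    week_index = {w: k for k, w in enumerate(params.weeks)}
    for i, s in enumerate(subjects):
        for w in params.weeks:
            sid = f"{s}_w{w:02d}"
            lib = float(rng.lognormal(mu_log, sig_log))
            weight = np.zeros(len(taxa))
            core = core_masks[i]
            # core members get their own (narrower) weight profile: the planted
            # core is the persistent, consistently-abundant fraction, so its
            # members neither inherit the transient pool's heavy low tail nor
            # take a second subject effect on top of their per-subject weight
            wvec = base * np.exp(b_eff[i])
            wvec[core] = core_w[i, core] * boosts[s]
            present = np.ones(n_blow, dtype=bool)
            if params.transient_presence_prob < 1.0:
                present = rng.random(n_blow) < params.transient_presence_prob
                present[core] = True
            wvec = wvec * present * np.exp(u_eff[week_index[w]])
            if params.treatment_effect_size and s in treat_intervals:
                from .tables_io import label_treatment_phase, TreatmentPhase

                rec = SampleRecord(sid, s, "blow", week=w,
                                   treatment_intervals=treat_intervals[s])
                if label_treatment_phase(rec, _week_date(w)) is TreatmentPhase.DIRECTLY_AFTER:
                    wvec[~core] *= np.exp(-params.treatment_effect_size)
            weight[:n_blow] = wvec
            if n_water:
                leak = rng.random(n_water) < params.water_leak_prob
                weight[n_blow:n_blow + n_water] = water_base * leak * params.water_leak_scale
            if n_contam:
                leak = rng.random(n_contam) < params.contam_leak_prob
                weight[n_blow + n_water:n_blow + n_water + n_contam] = (
                    contam_base * leak * params.contam_leak_scale
                )
            q = weight / weight.sum()
            rows.append((sid, lib * q))
            sample_ids.append(sid)
            metadata.append(
                SampleRecord(
                    sample_id=sid, subject_id=s, sample_type="blow", week=w,
                    pool_system=pools[i], sex=sexes[i], age_level=ages[i],
                    treatment_intervals=list(treat_intervals.get(s, [])),
                )
            )

    # water samples: one per pool per week, cycling until n_water_samples
    if n_water and params.n_water_samples:
        n_pools_used = min(4, len(_POOLS))
        k = 0
        for w in list(params.weeks) * 10:
            if k >= params.n_water_samples:
                break
            pool = _POOLS[k % n_pools_used]
            sid = f"W{k + 1:02d}_w{w:02d}"
            lib = float(rng.lognormal(mu_log, sig_log))
            weight = np.zeros(len(taxa))
            weight[n_blow:n_blow + n_water] = water_base * np.exp(
                rng.normal(0.0, 0.3, size=n_water)
            )
            mix = rng.random(n_blow) < params.blow_in_water_prob
            weight[:n_blow] = base * mix * 0.02
            q = weight / weight.sum()
            rows.append((sid, lib * q))
            sample_ids.append(sid)
            metadata.append(
                SampleRecord(sample_id=sid, subject_id=f"pool_{pool}",
                             sample_type="water", week=w, pool_system=pool)
            )
            k += 1

    # technical controls
    def _control_sample(sid, stype, spike=False):
        lib = float(rng.lognormal(cmu_log, csig_log))
        weight = np.zeros(len(taxa))
        if n_contam:
            occ = rng.random(n_contam) < 0.9
            weight[n_blow + n_water:n_blow + n_water + n_contam] = contam_base * occ
        if spike and n_contam:
            weight[n_blow + n_water] *= 50.0  # genomic-DNA spike dominates positives
        cross = rng.random(n_blow) < params.blow_in_control_prob
        weight[:n_blow] += base * cross * 0.005
        if weight.sum() == 0:
            weight[:] = 1.0  # pathological: no contaminants and no cross-talk
        q = weight / weight.sum()
        rows.append((sid, lib * q))
        sample_ids.append(sid)
        metadata.append(SampleRecord(sample_id=sid, subject_id="control", sample_type=stype))

    for k in range(params.n_pos_controls):
        _control_sample(f"POS{k + 1:02d}", "pos_control", spike=True)
    for k in range(params.n_neg_controls):
        _control_sample(f"NEG{k + 1:02d}", "neg_control")
    for k in range(params.n_extraction_blanks):
        _control_sample(f"BLANK{k + 1:02d}", "extraction_blank")

    # off-target taxa (Archaea / chloroplast / mitochondria) ride along in blow
    expected = np.vstack([mu for _, mu in rows])
    if params.n_offtarget_taxa:
        n_off = params.n_offtarget_taxa
        blow_rows = np.array([m.sample_type == "blow" for m in metadata])
        off_w = offtarget_base / offtarget_base.sum() * 0.01
        off_mu = np.outer(expected.sum(axis=1) * blow_rows, off_w)
        expected[:, -n_off:] = off_mu

    counts = _nb_draw(rng, expected, theta_taxa[None, :])
    table = CountTable(tuple(sample_ids), tuple(taxa), counts.astype(np.int64))

    lineages = {}
    off_kinds = ("Archaea;Euryarchaeota", "Bacteria;Cyanobacteria;Chloroplast",
                 "Eukaryota;Mitochondria")
    for j, t in enumerate(taxa):
        if t.startswith("offtarget"):
            lineages[t] = TaxonomyRecord(t, tuple(off_kinds[j % 3].split(";")))
        elif t.startswith("water"):
            lineages[t] = TaxonomyRecord(t, ("Bacteria", "Proteobacteria", "Marinomonas"))
        elif t.startswith("contam"):
            lineages[t] = TaxonomyRecord(t, ("Bacteria", "Proteobacteria", "Ralstonia"))
        else:
            lineages[t] = TaxonomyRecord(t, ("Bacteria", "Bacteroidetes", "Flavobacteriaceae"))

    truth = SyntheticTruth(
        core_sets=core_sets,
        inter_core=inter_core,
        blow_taxa=frozenset(blow_taxa),
        water_taxa=frozenset(water_taxa),
        contaminant_taxa=frozenset(contam_taxa),
        offtarget_taxa=frozenset(offtarget_taxa),
        realized_sigma_ratio=realized_ratio,
        sigma_subject=params.sigma_subject,
        sigma_time=params.sigma_time,
        expected_counts=expected,
        sample_ids=tuple(sample_ids),
        taxon_ids=tuple(taxa),
        core_boosts=boosts,
    )
    return table, metadata, lineages, truth


def null_cohort(params: CohortParams, factor: str):
    """Generate a cohort in which ``factor`` has exactly zero effect on counts.

    ``factor`` is one of ``sex``, ``age``, ``treatment``, ``pool``. Factor labels
    are still assigned to subjects, so downstream tests can be run against a true
    null. The harness also zeroes the exchangeability-breaking structure
    (subject/time random effects, planted cores, occupancy thinning): these are
    subject- or sample-level processes unrelated to the factor, and leaving them
    on would test the label assignment's confounding with them rather than the
    testing machinery's calibration.
    """
    if factor not in ("sex", "age", "treatment", "pool"):
        raise ValueError(f"unknown null factor {factor!r}")
    null_params = replace(
        params,
        sigma_subject=0.0,
        sigma_time=0.0,
        core_size_mean=0.0,
        transient_presence_prob=1.0,
        n_water_taxa=0,
        n_contam_taxa=0,
        n_offtarget_taxa=0,
        treatment_effect_size=0.0,
        n_water_samples=0,
        n_pos_controls=0,
        n_neg_controls=0,
        n_extraction_blanks=0,
    )
    table, metadata, _, _ = generate_cohort(null_params)
    return table, metadata
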