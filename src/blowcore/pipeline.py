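"""End-to-end pipeline: simulate/ingest -> QC -> diversity -> ordination -> tests -> core.

A single master seed fans out to every stochastic stage through a counter-based
``numpy.random.SeedSequence`` spawn, so stages are independently reproducible.
The run writes headed TSV artifacts per stage plus a JSON run ledger with
per-stage sample/taxon counts, seeds, parameters and output paths.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha_diversity, beta_ordination, core_detection, multivariate_abundance, qc_filter
from .synthetic_cohort import CohortParams, generate_cohort
from .tables_io import (
    CountTable,
    read_count_table,
    read_metadata,
    read_taxonomy,
    write_count_table,
    write_metadata,
    write_taxonomy,
)

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "counts_path", "counts_format", "metadata_path", "taxonomy_path", "preset",
    "min_reads", "min_rel_abund", "contaminant_threshold", "water_filter",
    "rarefaction_depth", "test_factors", "n_resamples",
    "core_weeks", "inter_core_weeks", "inter_core_subjects",
    "run_alpha", "run_ordination", "run_tests", "run_partition",
    "run_varratio", "varratio_max_taxa", "run_core",
    "out_dir", "seed",
}


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run; unknown keys are rejected."""

    counts_path: str | None = None
    counts_format: str = "tsv"
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    preset: str | None = None        # "paper" simulates the default cohort
    min_reads: int = 6000
    min_rel_abund: float = 1e-6
    contaminant_threshold: float = 0.5
    water_filter: bool = True
    rarefaction_depth: int | None = None
    test_factors: tuple = ("subject", "time")
    n_resamples: int = 99
    core_weeks: tuple = core_detection.INTRA_CORE_WEEKS
    inter_core_weeks: tuple = core_detection.INTER_CORE_WEEKS
    inter_core_subjects: int = 10
    run_alpha: bool = True
    run_ordination: bool = True
    run_tests: bool = False
    run_partition: bool = False
    run_varratio: bool = False
    varratio_max_taxa: int = 200
    run_core: bool = True
    out_dir: str = "blowcore_run"
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if not (cfg.preset or (cfg.counts_path and cfg.metadata_path)):
            raise ValueError("config needs either a preset or counts_path + metadata_path")
        if cfg.min_reads < 0 or not 0 <= cfg.min_rel_abund < 1:
            raise ValueError("filter thresholds out of range")
        if not 0 <= cfg.contaminant_threshold <= 1:
            raise ValueError("contaminant_threshold must be in [0, 1]")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("test_factors", "core_weeks", "inter_core_weeks"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls.from_mapping(data)


def _stage_seeds(master: int, n: int = 16):
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run ledger."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    ledger: dict = {"config": dataclasses.asdict(config), "stages": [], "outputs": {}}
    ledger_path = out / "run_ledger.json"

    def _flush():
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (tuple, set, frozenset)):
                return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        ledger_path.write_text(json.dumps(ledger, indent=2, default=_default))

    try:
        # --- ingest / simulate -------------------------------------------
        truth = None
        if config.preset:
            if config.preset != "paper":
                raise ValueError(f"unknown preset {config.preset!r}")
            params = CohortParams(rng_seed=seeds[0])
            table, metadata, taxonomy, truth = generate_cohort(params)
            write_count_table(table, out / "simulated_counts.tsv")
            write_metadata(metadata, out / "simulated_metadata.tsv")
            write_taxonomy(taxonomy, out / "simulated_taxonomy.tsv")
            (out / "simulated_truth.json").write_text(json.dumps(
                {
                    **truth.summary(),
                    "core_sets": {s: sorted(v) for s, v in truth.core_sets.items()},
                    "contaminant_taxa": sorted(truth.contaminant_taxa),
                    "water_taxa": sorted(truth.water_taxa),
                },
                indent=2,
            ))
            ledger["stages"].append({"stage": "simulate", "seed": seeds[0],
                                     "n_samples": table.n_samples, "n_taxa": table.n_taxa})
        else:
            table = read_count_table(config.counts_path, config.counts_format)
            metadata = read_metadata(config.metadata_path)
            taxonomy = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
            ledger["stages"].append({"stage": "ingest",
                                     "n_samples": table.n_samples, "n_taxa": table.n_taxa})
        _flush()

        # --- QC cascade ---------------------------------------------------
        filtered, stages = qc_filter.run_qc_cascade(
            table, metadata, taxonomy,
            min_rel_abund=config.min_rel_abund, min_reads=config.min_reads,
            contaminant_threshold=config.contaminant_threshold,
            water_filter=config.water_filter,
        )
        manifest = pd.concat([s.manifest for s in stages], ignore_index=True)
        manifest.to_csv(out / "qc_removals.tsv", sep="\t", index=False)
        write_count_table(filtered, out / "filtered_counts.tsv")
        ledger["stages"].extend(qc_filter.cascade_ledger(table, stages))
        ledger["outputs"]["filtered_counts"] = str(out / "filtered_counts.tsv")
        _flush()

        # --- alpha diversity ---------------------------------------------
        if config.run_alpha:
            rare = alpha_diversity.rarefy(filtered, config.rarefaction_depth, seed=seeds[1])
            alpha = alpha_diversity.alpha_table(rare)
            alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
            tests = []
            for metric in ("richness", "shannon", "chao1", "ace"):
                for factor in ("subject", "time"):
                    try:
                        res = alpha_diversity.alpha_lmm_test(alpha, metadata, metric, factor)
                        tests.append(res.__dict__)
                    except (ValueError, RuntimeError) as exc:
                        logger.warning("alpha LMM %s/%s failed: %s", metric, factor, exc)
            pd.DataFrame(tests).to_csv(out / "alpha_tests.tsv", sep="\t", index=False)
            ledger["stages"].append({
                "stage": "alpha", "seed": seeds[1],
                "rarefaction_depth": int(rare.depths[0]) if rare.n_samples else None,
                "n_samples": rare.n_samples,
            })
            _flush()

        # --- ordination ----------------------------------------------------
        if config.run_ordination:
            dm = beta_ordination.bray_curtis(filtered)
            pd.DataFrame(dm.values, index=list(dm.sample_ids),
                         columns=list(dm.sample_ids)).to_csv(out / "bray_curtis.tsv", sep="\t")
            ord_res = beta_ordination.nmds(dm, seed=seeds[2])
            coords = pd.DataFrame(ord_res.coordinates, index=list(ord_res.sample_ids),
                                  columns=["axis1", "axis2"])
            with open(out / "nmds_coordinates.tsv", "w") as fh:
                fh.write(f"# stress1 = {ord_res.stress1:.6f}\n")
                coords.to_csv(fh, sep="\t", index_label="sample_id")
            ledger["stages"].append({"stage": "ordination", "seed": seeds[2],
                                     "stress1": ord_res.stress1})
            _flush()

        # --- multivariate tests --------------------------------------------
        if config.run_tests:
            results = []
            for factor in config.test_factors:
                res = multivariate_abundance.sum_of_lr_test(
                    filtered, metadata, factor,
                    n_resamples=config.n_resamples, seed=seeds[3],
                )
                res.per_taxon.to_csv(out / f"test_{factor}_per_taxon.tsv",
                                     sep="\t", index=False)
                results.append({"factor": factor, "sum_of_lr": res.sum_of_lr,
                                "p_value": res.p_value, "n_resamples": res.n_resamples})
            (out / "mv_tests.json").write_text(json.dumps(results, indent=2))
            ledger["stages"].append({"stage": "mv_tests", "seed": seeds[3],
                                     "results": results})
            _flush()

        if config.run_partition:
            parts = multivariate_abundance.deviance_partition(filtered, metadata)
            pd.DataFrame([p.__dict__ for p in parts]).to_csv(
                out / "deviance_partition.tsv", sep="\t", index=False)
            ledger["stages"].append({
                "stage": "partition",
                "results": [{"factor": p.factor, "pseudo_r2": p.pseudo_r2} for p in parts],
            })
            _flush()

        if config.run_varratio:
            vr = multivariate_abundance.variance_ratio(
                filtered, metadata, max_taxa=config.varratio_max_taxa)
            vr.per_taxon.to_csv(out / "variance_components.tsv", sep="\t", index=False)
            ledger["stages"].append({
                "stage": "varratio", "sigma_subject": vr.sigma_subject,
                "sigma_time": vr.sigma_time, "ratio": vr.ratio,
            })
            _flush()

        # --- core detection -------------------------------------------------
        if config.run_core:
            intra_sets, abundance = [], []
            for subject in core_detection.eligible_subjects(
                    filtered, metadata, config.core_weeks):
                cs = core_detection.intra_core(filtered, metadata, subject,
                                               weeks=config.core_weeks)
                intra_sets.append(cs)
                abundance.extend(core_detection.core_abundance(filtered, metadata, cs))
            inter_sets = []
            for w in config.inter_core_weeks:
                try:
                    cs = core_detection.inter_core(
                        filtered, metadata, w,
                        n_subjects=config.inter_core_subjects, seed=seeds[4])
                    inter_sets.append(cs)
                    abundance.extend(core_detection.core_abundance(filtered, metadata, cs))
                except core_detection.EligibilityError as exc:
                    logger.warning("inter-core week %s skipped: %s", w, exc)
            pd.DataFrame([r.__dict__ for r in abundance]).to_csv(
                out / "core_abundance.tsv", sep="\t", index=False)
            intra_rows = [{"subject_id": c.subject_id, "n_members": len(c)}
                          for c in intra_sets]
            pd.DataFrame(intra_rows).to_csv(out / "intra_core_sizes.tsv",
                                            sep="\t", index=False)
            hist = core_detection.sharing_histogram(intra_sets) if intra_sets else {}
            ledger["stages"].append({
                "stage": "core", "seed": seeds[4],
                "n_intra_subjects": len(intra_sets),
                "mean_intra_size": float(np.mean([len(c) for c in intra_sets]))
                if intra_sets else 0.0,
                "inter_sizes": {int(c.weeks[0]): len(c) for c in inter_sets},
                "intra_sharing": hist,
            })
            if truth is not None and intra_sets:
                report = core_detection.core_recovery_report(intra_sets, truth)
                report.to_csv(out / "core_recovery.tsv", sep="\t", index=False)
                ledger["stages"][-1]["recovery_median_sensitivity"] = float(
                    report["sensitivity"].median())
            _flush()
    except Exception as exc:
        ledger["error"] = f"{type(exc).__name__}: {exc}"
        _flush()
        raise
    return ledger
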