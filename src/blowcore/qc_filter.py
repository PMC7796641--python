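"""Quality-control and contaminant-filtering cascade for blow count tables.

The cascade runs in a fixed order:

1. taxonomy screening (drop Archaea, chloroplast and mitochondrial taxa),
2. global relative-abundance filter (drop taxa below ``min_rel_abund`` of all
   reads; the default 1e-6 is 0.0001% expressed as a fraction),
3. per-sample read-depth cutoff (drop samples below ``min_reads``; a sample at
   exactly the minimum is kept),
4. prevalence-based technical decontamination against negative controls and
   extraction blanks, after which the control samples are dropped,
5. the same prevalence machinery with pooled water samples as the control
   class, after which the water samples are dropped.

Prevalence scoring builds, per taxon, the 2x2 presence table
(present/absent x control/true, presence = count > 0) and reports a one-sided
association probability: the Yates-corrected chi-square tail halved and folded
by direction, replaced by the exact conditional (hypergeometric) tail whenever
any expected cell is below 5. Small scores in the ``is_contaminant`` direction
mean prevalence is skewed toward the controls. Because presence is count > 0,
per-sample depth normalization cannot change any prevalence decision, so the
conventional normalize step is a documented no-op.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import (
    TECHNICAL_CONTROL_TYPES,
    CountTable,
    SampleRecord,
    TaxonomyRecord,
    metadata_by_sample,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContaminantCall:
    """Prevalence-score verdict for one taxon."""

    taxon_id: str
    score: float
    classification: str  # contaminant | not_contaminant | indeterminate
    n_present_controls: int
    n_present_samples: int
    exact: bool = False


@dataclass
class StageResult:
    """Outcome of one cascade stage, for the removal manifests and ledger."""

    stage: str
    table: CountTable
    removed_taxa: tuple = ()
    removed_samples: tuple = ()
    scores: pd.DataFrame | None = None

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [{"id": t, "stage": self.stage, "kind": "taxon"} for t in self.removed_taxa]
        rows += [{"id": s, "stage": self.stage, "kind": "sample"} for s in self.removed_samples]
        return pd.DataFrame(rows, columns=["id", "stage", "kind"])


# ---------------------------------------------------------------------------
# simple filters
# ---------------------------------------------------------------------------

def screen_taxonomy(table: CountTable, taxonomy: Mapping[str, TaxonomyRecord]) -> StageResult:
    """Remove taxa flagged as Archaea, chloroplast or mitochondrion.

    Taxa without a taxonomy record are retained (no lineage, no evidence).
    """
    removed = [
        t for t in table.taxon_ids
        if t in taxonomy and taxonomy[t].is_off_target
    ]
    out = table.drop_taxa(removed)
    if out.n_taxa == 0:
        logger.warning("taxonomy screen removed every taxon")
    return StageResult("taxonomy_screen", out, removed_taxa=tuple(removed))


def filter_rare_taxa(table: CountTable, min_rel_abund: float = 1e-6) -> StageResult:
    """Drop taxa whose share of the grand total is below ``min_rel_abund``.

    Taxa exactly at the threshold are retained.
    """
    grand = table.counts.sum()
    if grand == 0:
        raise ValueError("cannot apply relative-abundance filter: grand total is 0")
    frac = table.counts.sum(axis=0) / grand
    removed = [t for t, f in zip(table.taxon_ids, frac) if f < min_rel_abund]
    return StageResult("rare_taxa", table.drop_taxa(removed), removed_taxa=tuple(removed))


def filter_low_depth_samples(table: CountTable, min_reads: int = 6000) -> StageResult:
    """Drop samples with read depth strictly below ``min_reads``."""
    depths = table.depths
    removed = [s for s, d in zip(table.sample_ids, depths) if d < min_reads]
    return StageResult("depth_filter", table.drop_samples(removed), removed_samples=tuple(removed))


# ---------------------------------------------------------------------------
# prevalence scores
# ---------------------------------------------------------------------------

def _one_sided_scores(a, n_controls, b, n_true):
    """Vectorized one-sided prevalence scores for the is_contaminant direction.

    ``a`` present-in-control counts, ``b`` present-in-true counts. Returns
    (score, exact_flag). Small score <=> prevalence skewed toward controls.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    K = a + b                          # taxon-present margin
    N = n_controls + n_true
    # exact one-sided tail P(X >= a) for X ~ Hypergeom(N, K, n_controls)
    exact_p = stats.hypergeom.sf(a - 1, N, K, n_controls)
    # expected cells of the 2x2 under independence
    exp_cells = np.stack(
        [
            K * n_controls / N, K * n_true / N,
            (N - K) * n_controls / N, (N - K) * n_true / N,
        ]
    )
    use_exact = (exp_cells < 5).any(axis=0)
    # Yates-corrected chi-square, one-sided by observed direction
    c = n_controls - a
    d = n_true - b
    num = np.abs(a * d - b * c) - N / 2.0
    num = np.maximum(num, 0.0) ** 2 * N
    den = K * (N - K) * n_controls * n_true
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    p_two = stats.chi2.sf(chi2, df=1)
    toward_controls = a / n_controls > b / n_true
    chi_p = np.where(toward_controls, p_two / 2.0, 1.0 - p_two / 2.0)
    score = np.where(use_exact, exact_p, chi_p)
    return np.clip(score, 0.0, 1.0), use_exact


def prevalence_contaminant_scores(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    control_types: Sequence[str] = TECHNICAL_CONTROL_TYPES,
    direction: str = "is_contaminant",
) -> list:
    """Score each taxon's prevalence skew between control and true samples.

    ``direction='is_contaminant'``: small scores indicate control-skewed taxa.
    ``direction='is_not_contaminant'``: small scores indicate taxa skewed toward
    the true samples (the lower hypergeometric tail / folded chi-square).
    Taxa absent from every sample of one class always get the exact conditional
    score, never NaN.
    """
    if direction not in ("is_contaminant", "is_not_contaminant"):
        raise ValueError(f"unknown direction {direction!r}")
    meta = metadata_by_sample(metadata)
    control_types = tuple(control_types)
    ctrl_rows, true_rows = [], []
    for i, sid in enumerate(table.sample_ids):
        rec = meta.get(sid)
        if rec is None:
            raise KeyError(f"sample {sid!r} missing from metadata")
        if rec.sample_type in control_types:
            ctrl_rows.append(i)
        elif rec.sample_type == "pos_control" and "pos_control" not in control_types:
            continue  # deliberate foreign DNA: excluded from both classes
        else:
            true_rows.append(i)
    if not ctrl_rows:
        raise ValueError(f"no control samples of types {control_types} in table")
    if not true_rows:
        raise ValueError("no true samples left after excluding controls")

    present = table.counts > 0
    a = present[ctrl_rows].sum(axis=0)
    b = present[true_rows].sum(axis=0)
    if direction == "is_contaminant":
        score, exact = _one_sided_scores(a, len(ctrl_rows), b, len(true_rows))
    else:
        # skew toward true samples == skew toward "controls" when classes swap
        score, exact = _one_sided_scores(b, len(true_rows), a, len(ctrl_rows))
    calls = []
    for j, t in enumerate(table.taxon_ids):
        s = float(score[j])
        if s < 0.5:
            cls = "contaminant" if direction == "is_contaminant" else "not_contaminant"
        elif s > 0.5:
            cls = "not_contaminant" if direction == "is_contaminant" else "contaminant"
        else:
            cls = "indeterminate"
        calls.append(
            ContaminantCall(
                taxon_id=t, score=s, classification=cls,
                n_present_controls=int(a[j]), n_present_samples=int(b[j]),
                exact=bool(exact[j]),
            )
        )
    return calls


def calls_to_frame(calls: Sequence[ContaminantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_id": c.taxon_id, "score": c.score,
                "classification": c.classification,
                "n_present_controls": c.n_present_controls,
                "n_present_samples": c.n_present_samples, "exact": c.exact,
            }
            for c in calls
        ]
    )


def remove_contaminants(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    calls: Sequence[ContaminantCall],
    threshold: float = 0.5,
    control_types: Sequence[str] = TECHNICAL_CONTROL_TYPES,
) -> StageResult:
    """Drop taxa scored below ``threshold`` and then drop the control samples.

    Positive controls are dropped alongside the scored control types: once
    decontamination is done, no technical sample belongs in the table.
    """
    by_taxon = {c.taxon_id: c for c in calls}
    missing = [t for t in table.taxon_ids if t not in by_taxon]
    if missing:
        raise ValueError(f"calls do not cover taxa, e.g. {missing[:3]}")
    removed_taxa = [t for t in table.taxon_ids if by_taxon[t].score < threshold]
    meta = metadata_by_sample(metadata)
    drop_types = set(control_types) | {"pos_control", "neg_control", "extraction_blank"}
    removed_samples = [
        s for s in table.sample_ids
        if s in meta and meta[s].sample_type in drop_types
    ]
    out = table.drop_taxa(removed_taxa).drop_samples(removed_samples)
    return StageResult(
        "technical_decontamination", out,
        removed_taxa=tuple(removed_taxa), removed_samples=tuple(removed_samples),
        scores=calls_to_frame(calls),
    )


def remove_water_taxa(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    threshold: float = 0.5,
) -> StageResult:
    """Water-source filtering: same prevalence rule with pooled water samples as controls."""
    meta = metadata_by_sample(metadata)
    water = [s for s in table.sample_ids if s in meta and meta[s].sample_type == "water"]
    if not water:
        raise ValueError("no water samples present; cannot run water-source filtering")
    calls = prevalence_contaminant_scores(table, metadata, control_types=("water",))
    removed_taxa = [c.taxon_id for c in calls if c.score < threshold]
    out = table.drop_taxa(removed_taxa).drop_samples(water)
    return StageResult(
        "water_decontamination", out,
        removed_taxa=tuple(removed_taxa), removed_samples=tuple(water),
        scores=calls_to_frame(calls),
    )


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def run_qc_cascade(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    taxonomy: Mapping[str, TaxonomyRecord] | None = None,
    min_rel_abund: float = 1e-6,
    min_reads: int = 6000,
    contaminant_threshold: float = 0.5,
    water_filter: bool = True,
) -> tuple:
    """Run the full cascade; returns ``(final_table, list_of_StageResult)``."""
    stages = []
    current = table
    if taxonomy is not None:
        res = screen_taxonomy(current, taxonomy)
        stages.append(res)
        current = res.table
    res = filter_rare_taxa(current, min_rel_abund)
    stages.append(res)
    current = res.table
    res = filter_low_depth_samples(current, min_reads)
    stages.append(res)
    current = res.table
    calls = prevalence_contaminant_scores(current, metadata)
    res = remove_contaminants(current, metadata, calls, threshold=contaminant_threshold)
    stages.append(res)
    current = res.table
    if water_filter:
        res = remove_water_taxa(current, metadata, threshold=contaminant_threshold)
        stages.append(res)
        current = res.table
    return current, stages


def cascade_ledger(table_in: CountTable, stages: Sequence[StageResult]) -> list:
    """Per-stage sample/taxon bookkeeping (taxa_in - removed = taxa_out)."""
    ledger = []
    n_samples, n_taxa = table_in.n_samples, table_in.n_taxa
    for st in stages:
        entry = {
            "stage": st.stage,
            "samples_in": n_samples,
            "taxa_in": n_taxa,
            "samples_removed": len(st.removed_samples),
            "taxa_removed": len(st.removed_taxa),
            "samples_out": st.table.n_samples,
            "taxa_out": st.table.n_taxa,
        }
        ledger.append(entry)
        n_samples, n_taxa = st.table.n_samples, st.table.n_taxa
    return ledger
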