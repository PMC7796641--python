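"""Intra- and inter-core taxon detection and abundance summaries.

A subject's *intra-core* is the set of taxa present (count > 0, no abundance
threshold) in every one of its blow samples across a fixed set of study weeks.
A missing week can be repaired by a sample taken within ``substitution_window``
weeks of it (ties resolved toward the earlier sample); subjects that still
cannot supply every week are excluded rather than scored on fewer samples.

The *inter-core* at one week is the set of taxa present in the samples of
``n_subjects`` subjects drawn uniformly at random (seeded, and the draw is
recorded) from those eligible at that week.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import SyntheticTruth
from .tables_io import CountTable, SampleRecord, metadata_by_sample

logger = logging.getLogger(__name__)

INTRA_CORE_WEEKS = (6, 11, 19, 28)
INTER_CORE_WEEKS = (2, 6, 11, 19, 28, 37)


class EligibilityError(ValueError):
    """A subject (or week) cannot supply the samples a core rule requires."""


@dataclass(frozen=True)
class CoreSet:
    scope: str                     # "intra" | "inter"
    members: frozenset
    weeks: tuple
    subject_id: str | None = None  # intra only
    selected_subjects: tuple = ()  # inter only
    samples_used: tuple = ()
    rule_params: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.members)


@dataclass(frozen=True)
class CoreAbundanceRecord:
    subject_id: str
    week: int
    core_scope: str
    core_read_fraction: float

    def __post_init__(self):
        assert 0.0 <= self.core_read_fraction <= 1.0


def _blow_samples_by_subject_week(table: CountTable, metadata: Sequence[SampleRecord]):
    meta = metadata_by_sample(metadata)
    out: dict = {}
    for sid in table.sample_ids:
        rec = meta.get(sid)
        if rec is None or rec.sample_type != "blow":
            continue
        out.setdefault(rec.subject_id, {}).setdefault(rec.week, []).append(sid)
    return out


def _pick_week_sample(by_week: dict, week: int, window: int):
    """One sample for a required week, allowing +/-window substitution (earlier wins)."""
    if week in by_week:
        return sorted(by_week[week])[0], week
    for delta in range(1, window + 1):
        for w in (week - delta, week + delta):  # earlier sample preferred on tie
            if w in by_week:
                logger.info("substituting week %d sample for missing week %d", w, week)
                return sorted(by_week[w])[0], w
    return None, None


def intra_core(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    subject_id: str,
    weeks: Sequence[int] = INTRA_CORE_WEEKS,
    substitution_window: int = 1,
) -> CoreSet:
    """Taxa present in all of one subject's samples across the required weeks."""
    by_subject = _blow_samples_by_subject_week(table, metadata)
    by_week = by_subject.get(subject_id, {})
    samples = []
    for w in weeks:
        sid, _ = _pick_week_sample(by_week, w, substitution_window)
        if sid is None:
            raise EligibilityError(
                f"subject {subject_id!r} has no blow sample for week {w} "
                f"(within +/-{substitution_window} weeks)"
            )
        samples.append(sid)
    idx = [table.sample_index(s) for s in samples]
    present_all = (table.counts[idx] > 0).all(axis=0)
    members = frozenset(t for t, keep in zip(table.taxon_ids, present_all) if keep)
    return CoreSet(
        scope="intra", members=members, weeks=tuple(weeks), subject_id=subject_id,
        samples_used=tuple(samples),
        rule_params={"presence": "count>0", "substitution_window": substitution_window},
    )


def eligible_subjects(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    weeks: Sequence[int],
    substitution_window: int = 1,
) -> list:
    """Subjects able to supply one blow sample for every required week."""
    by_subject = _blow_samples_by_subject_week(table, metadata)
    out = []
    for subject, by_week in sorted(by_subject.items()):
        if all(_pick_week_sample(by_week, w, substitution_window)[0] is not None
               for w in weeks):
            out.append(subject)
    return out


def inter_core(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    week: int,
    n_subjects: int = 10,
    seed: int = 0,
    substitution_window: int = 1,
) -> CoreSet:
    """Taxa present across ``n_subjects`` randomly selected subjects at one week."""
    candidates = eligible_subjects(table, metadata, [week], substitution_window)
    if len(candidates) < n_subjects:
        raise EligibilityError(
            f"only {len(candidates)} subjects eligible at week {week}, "
            f"need {n_subjects}"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(candidates, size=n_subjects, replace=False).tolist())
    by_subject = _blow_samples_by_subject_week(table, metadata)
    samples = []
    for s in chosen:
        sid, _ = _pick_week_sample(by_subject[s], week, substitution_window)
        samples.append(sid)
    idx = [table.sample_index(s) for s in samples]
    present_all = (table.counts[idx] > 0).all(axis=0)
    members = frozenset(t for t, keep in zip(table.taxon_ids, present_all) if keep)
    return CoreSet(
        scope="inter", members=members, weeks=(week,),
        selected_subjects=tuple(chosen), samples_used=tuple(samples),
        rule_params={"presence": "count>0", "n_subjects": n_subjects, "seed": seed},
    )


def core_abundance(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    core: CoreSet,
) -> list:
    """Fraction of each relevant sample's reads that falls in the core members."""
    missing = core.members - set(table.taxon_ids)
    if missing:
        raise KeyError(f"core members not in table, e.g. {sorted(missing)[:3]}")
    meta = metadata_by_sample(metadata)
    member_idx = [table.taxon_index(t) for t in sorted(core.members)]
    records = []
    for sid in core.samples_used:
        i = table.sample_index(sid)
        depth = table.counts[i].sum()
        frac = float(table.counts[i, member_idx].sum() / depth) if depth > 0 else 0.0
        rec = meta[sid]
        records.append(
            CoreAbundanceRecord(
                subject_id=rec.subject_id, week=rec.week,
                core_scope=core.scope, core_read_fraction=frac,
            )
        )
    return records


def sharing_histogram(core_sets: Sequence[CoreSet]):
    """How many core sets each taxon belongs to: {k: taxon count}, plus union size.

    For intra sets k counts subjects; for inter sets k counts time points.
    """
    counts: dict = {}
    for cs in core_sets:
        for t in cs.members:
            counts[t] = counts.get(t, 0) + 1
    hist: dict = {}
    for k in counts.values():
        hist[k] = hist.get(k, 0) + 1
    return {"histogram": dict(sorted(hist.items())), "union_size": len(counts)}


def core_recovery_report(
    core_sets: Sequence[CoreSet],
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Sensitivity and FDR of detected intra-cores against the planted truth."""
    rows = []
    for cs in core_sets:
        if cs.scope != "intra":
            continue
        planted = set(truth.core_sets.get(cs.subject_id, frozenset()))
        detected = set(cs.members)
        tp = len(detected & planted)
        sens = tp / len(planted) if planted else np.nan
        fdr = (len(detected) - tp) / len(detected) if detected else 0.0
        rows.append(
            {"subject_id": cs.subject_id, "n_planted": len(planted),
             "n_detected": len(detected), "sensitivity": sens, "fdr": fdr}
        )
    return pd.DataFrame(rows)
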