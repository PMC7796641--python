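"""Domain types and readers/writers for count tables, sample metadata and taxonomy.

The package-wide conventions fixed here:

* count tables are oriented **samples in rows, taxa in columns**, whatever the
  on-disk orientation (BIOM stores observations, i.e. taxa, in rows);
* counts are non-negative integers with unique sample and taxon identifiers;
* metadata and taxonomy travel as headed, tab-separated text; dates are ISO-8601;
* week numbers are study weeks, not calendar weeks.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("blow", "water", "pos_control", "neg_control", "extraction_blank")
#: sample types used as the control class for technical decontamination by default;
#: positive controls carry deliberate foreign DNA and are excluded from both classes.
TECHNICAL_CONTROL_TYPES = ("neg_control", "extraction_blank")


class FormatError(ValueError):
    """A file violated the expected on-disk layout (bad cell, wrong header...)."""


class ValidationError(ValueError):
    """An in-memory object violated a domain invariant."""


@dataclass(frozen=True)
class CountTable:
    """A samples x taxa matrix of non-negative integer read counts.

    ``counts[i, j]`` is the number of reads of taxon ``taxon_ids[j]`` observed in
    sample ``sample_ids[i]``.
    """

    sample_ids: tuple
    taxon_ids: tuple
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.taxon_ids)} taxa)"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64, copy=False)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, taxon {self.taxon_ids[j]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon_ids")
        object.__setattr__(self, "counts", counts)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    def depth(self, sample_id: str) -> int:
        return int(self.counts[self.sample_index(sample_id)].sum())

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(str(sample_id))
        except ValueError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def taxon_index(self, taxon_id: str) -> int:
        try:
            return self.taxon_ids.index(str(taxon_id))
        except ValueError:
            raise KeyError(f"unknown taxon_id {taxon_id!r}") from None

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return CountTable(tuple(self.sample_ids[i] for i in idx), self.taxon_ids, self.counts[idx])

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        idx = [self.taxon_index(t) for t in taxon_ids]
        return CountTable(self.sample_ids, tuple(self.taxon_ids[i] for i in idx), self.counts[:, idx])

    def drop_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        drop = {str(t) for t in taxon_ids}
        keep = [t for t in self.taxon_ids if t not in drop]
        return self.select_taxa(keep)

    def drop_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        drop = {str(s) for s in sample_ids}
        keep = [s for s in self.sample_ids if s not in drop]
        return self.select_samples(keep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.taxon_ids))

    def __eq__(self, other):
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


class TreatmentPhase(str, Enum):
    """Timing of a blow sample relative to a subject's antimicrobial treatment."""

    NONE = "None"
    BEFORE = "Before"
    DIRECTLY_AFTER = "Directly_After"
    AFTER = "After"


@dataclass
class SampleRecord:
    """Per-sample metadata record."""

    sample_id: str
    subject_id: str
    sample_type: str
    week: int | None = None
    pool_system: str | None = None
    sex: str | None = None
    age_level: int | None = None
    treatment_intervals: list = field(default_factory=list)

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown sample_type {self.sample_type!r} "
                f"(expected one of {SAMPLE_TYPES})"
            )
        if self.sample_type in ("blow", "water"):
            if self.week is None or int(self.week) < 0:
                raise ValidationError(f"sample {self.sample_id!r}: blow/water samples need week >= 0")
            self.week = int(self.week)
        elif self.week is not None:
            self.week = int(self.week)
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValidationError(f"sample {self.sample_id!r}: sex must be F, M or missing")
        if self.age_level is not None:
            self.age_level = int(self.age_level)
            if self.age_level not in (1, 2, 3, 4):
                raise ValidationError(
                    f"sample {self.sample_id!r}: age_level {self.age_level} not in 1..4 "
                    "(1: 0-10y, 2: 11-20y, 3: 21-30y, 4: 31-40y)"
                )
        self.treatment_intervals = [
            (_as_date(a), _as_date(b)) for a, b in self.treatment_intervals
        ]
        for start, end in self.treatment_intervals:
            if end < start:
                raise ValidationError(
                    f"sample {self.sample_id!r}: treatment interval ends before it starts"
                )


@dataclass(frozen=True)
class TaxonomyRecord:
    """Ranked lineage for one taxon, with off-target flags derived from it."""

    taxon_id: str
    lineage: tuple

    @property
    def is_archaea(self) -> bool:
        return any("archaea" in r.lower() for r in self.lineage)

    @property
    def is_chloroplast(self) -> bool:
        return any("chloroplast" in r.lower() for r in self.lineage)

    @property
    def is_mitochondrion(self) -> bool:
        return any("mitochondri" in r.lower() for r in self.lineage)

    @property
    def is_off_target(self) -> bool:
        return self.is_archaea or self.is_chloroplast or self.is_mitochondrion


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value).strip())


# ---------------------------------------------------------------------------
# count-table I/O
# ---------------------------------------------------------------------------

def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a count table from ``tsv`` (samples x taxa) or ``biom_json``.

    The TSV dialect is: first row taxon IDs, first column sample IDs,
    tab-delimited integer cells. BIOM 1.0 JSON stores taxa (observations) in
    rows; orientation is normalized to samples-in-rows on read.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown count-table format {format!r}")


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")
    elif format == "biom_json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown count-table format {format!r}")


def _read_tsv(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    taxon_ids = tuple(df.columns)
    sample_ids = tuple(str(i) for i in df.index)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    vals = numeric.to_numpy(dtype=float)
    bad = ~np.isfinite(vals) | (vals != np.floor(vals))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"{path}: non-integer count {df.iat[i, j]!r} at sample "
            f"{sample_ids[i]!r}, taxon {taxon_ids[j]!r}"
        )
    if (vals < 0).any():
        i, j = map(int, np.argwhere(vals < 0)[0])
        raise FormatError(
            f"{path}: negative count {df.iat[i, j]} at sample {sample_ids[i]!r}, "
            f"taxon {taxon_ids[j]!r}"
        )
    return CountTable(sample_ids, taxon_ids, vals.astype(np.int64))


def _read_biom_json(path) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    if "rows" not in doc or "columns" not in doc or "data" not in doc:
        raise FormatError(f"{path}: not a BIOM 1.0 JSON table")
    taxon_ids = tuple(r["id"] for r in doc["rows"])
    sample_ids = tuple(c["id"] for c in doc["columns"])
    shape = tuple(doc.get("shape", (len(taxon_ids), len(sample_ids))))
    mat = np.zeros(shape, dtype=np.float64)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=np.float64)
    if np.any(mat != np.floor(mat)):
        r, c = np.argwhere(mat != np.floor(mat))[0]
        raise FormatError(
            f"{path}: non-integer count {mat[r, c]} at taxon {taxon_ids[r]!r}, "
            f"sample {sample_ids[c]!r}"
        )
    # BIOM rows are observations (taxa): transpose to samples-in-rows
    return CountTable(sample_ids, taxon_ids, mat.T.astype(np.int64))


def _write_biom_json(table: CountTable, path) -> None:
    mat = table.counts.T  # observations in rows
    rows, cols = np.nonzero(mat)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "blowcore",
        "date": _dt.datetime.now().isoformat(timespec="seconds"),
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_taxa, table.n_samples],
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [[int(r), int(c), int(mat[r, c])] for r, c in zip(rows, cols)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "sample_type",
    "week",
    "pool_system",
    "sex",
    "age_level",
    "treatment_start",
    "treatment_end",
)


def read_metadata(path) -> list:
    """Read per-sample metadata from a headed TSV into ``SampleRecord`` objects.

    ``treatment_start``/``treatment_end`` hold ISO dates, possibly empty;
    multiple treatment intervals are separated by ``;`` in both columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        starts = [s for s in str(row["treatment_start"]).split(";") if s.strip()]
        ends = [s for s in str(row["treatment_end"]).split(";") if s.strip()]
        if len(starts) != len(ends):
            raise FormatError(
                f"{path}: sample {row['sample_id']!r} has {len(starts)} treatment starts "
                f"but {len(ends)} ends"
            )
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                subject_id=row["subject_id"],
                sample_type=row["sample_type"],
                week=int(row["week"]) if str(row["week"]).strip() else None,
                pool_system=row["pool_system"] or None,
                sex=row["sex"] or None,
                age_level=int(row["age_level"]) if str(row["age_level"]).strip() else None,
                treatment_intervals=list(zip(starts, ends)),
            )
        )
    return records


def write_metadata(records: Sequence[SampleRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "subject_id": r.subject_id,
                "sample_type": r.sample_type,
                "week": "" if r.week is None else r.week,
                "pool_system": r.pool_system or "",
                "sex": r.sex or "",
                "age_level": "" if r.age_level is None else r.age_level,
                "treatment_start": ";".join(str(a) for a, _ in r.treatment_intervals),
                "treatment_end": ";".join(str(b) for _, b in r.treatment_intervals),
            }
        )
    pd.DataFrame(rows, columns=list(_METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> dict:
    """Read a taxonomy TSV (taxon_id, lineage with ranks separated by ';')."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "taxon_id" not in df.columns or "lineage" not in df.columns:
        raise FormatError(f"{path}: taxonomy TSV needs taxon_id and lineage columns")
    out = {}
    for _, row in df.iterrows():
        lineage = tuple(r.strip() for r in str(row["lineage"]).split(";") if r.strip())
        out[row["taxon_id"]] = TaxonomyRecord(row["taxon_id"], lineage)
    return out


def write_taxonomy(taxonomy: Mapping[str, TaxonomyRecord], path) -> None:
    rows = [
        {"taxon_id": t, "lineage": ";".join(rec.lineage)} for t, rec in taxonomy.items()
    ]
    pd.DataFrame(rows, columns=["taxon_id", "lineage"]).to_csv(path, sep="\t", index=False)


def metadata_by_sample(records: Sequence[SampleRecord]) -> dict:
    return {r.sample_id: r for r in records}


# ---------------------------------------------------------------------------
# treatment-phase labelling
# ---------------------------------------------------------------------------

def label_treatment_phase(record: SampleRecord, sample_date) -> TreatmentPhase:
    """Label a blow sample relative to its subject's antimicrobial treatment.

    Untreated subjects get ``None``; samples before the first treatment start are
    ``Before``; samples within 13 days after the most recent treatment end (or
    during an active interval) are ``Directly_After``; samples 14 or more days
    after the most recent end are ``After``. The 8-13-day gap is unlabelled by
    the four-phase scheme's plain reading, and is conservatively assigned to the
    recently-treated window; the assignment is logged.
    """
    date = _as_date(sample_date)
    intervals = sorted(record.treatment_intervals)
    if not intervals:
        return TreatmentPhase.NONE
    if date < intervals[0][0]:
        return TreatmentPhase.BEFORE
    for start, end in intervals:
        if start <= date <= end:
            logger.warning(
                "sample %s taken during an active treatment interval; labelled Directly_After",
                record.sample_id,
            )
            return TreatmentPhase.DIRECTLY_AFTER
    last_end = max(end for start, end in intervals if end < date)
    gap = (date - last_end).days
    if gap >= 14:
        return TreatmentPhase.AFTER
    if gap > 7:
        logger.info(
            "sample %s falls in the 8-13 day gap after treatment; assigned Directly_After",
            record.sample_id,
        )
    return TreatmentPhase.DIRECTLY_AFTER
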