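"""Filtering cascade behaviour and prevalence-score properties."""

import numpy as np
import pytest

from blowcore.qc_filter import (
    filter_low_depth_samples,
    filter_rare_taxa,
    prevalence_contaminant_scores,
    remove_contaminants,
    remove_water_taxa,
    screen_taxonomy,
)
from blowcore.tables_io import CountTable, SampleRecord, TaxonomyRecord


def _table(counts, prefix="s"):
    counts = np.asarray(counts)
    return CountTable(
        tuple(f"{prefix}{i}" for i in range(counts.shape[0])),
        tuple(f"t{j}" for j in range(counts.shape[1])),
        counts,
    )


class TestTaxonomyScreen:
    def test_flagged_taxa_removed_order_preserved(self):
        t = _table([[1, 2, 3, 4]])
        tax = {
            "t0": TaxonomyRecord("t0", ("Bacteria",)),
            "t1": TaxonomyRecord("t1", ("Bacteria", "Chloroplast")),
            "t2": TaxonomyRecord("t2", ("Archaea",)),
            "t3": TaxonomyRecord("t3", ("Bacteria", "Firmicutes")),
        }
        res = screen_taxonomy(t, tax)
        assert res.table.taxon_ids == ("t0", "t3")
        assert set(res.removed_taxa) == {"t1", "t2"}

    def test_no_flags_identity(self):
        t = _table([[1, 2]])
        res = screen_taxonomy(t, {})
        assert res.table == t

    def test_all_flagged_gives_empty_table(self):
        t = _table([[1, 2]])
        tax = {f"t{j}": TaxonomyRecord(f"t{j}", ("Archaea",)) for j in range(2)}
        res = screen_taxonomy(t, tax)
        assert res.table.n_taxa == 0


class TestRareTaxa:
    def test_below_threshold_removed_at_threshold_kept(self):
        # grand total 10_000_000: t0 at 1e-7 removed, t1 at exactly 1e-6 kept
        counts = np.array([[1, 10, 9_999_989 - 10]])
        t = _table(counts)
        res = filter_rare_taxa(t, min_rel_abund=1e-6)
        assert "t0" in res.removed_taxa
        assert "t1" in res.table.taxon_ids

    def test_zero_threshold_identity(self):
        t = _table([[3, 5]])
        assert filter_rare_taxa(t, min_rel_abund=0.0).table == t

    def test_empty_grand_total_errors(self):
        with pytest.raises(ValueError):
            filter_rare_taxa(_table([[0, 0]]))

    def test_idempotent(self):
        t = _table([[1, 500, 100000], [0, 300, 150000]])
        once = filter_rare_taxa(t, 1e-4).table
        twice = filter_rare_taxa(once, 1e-4).table
        assert once == twice


class TestDepthFilter:
    @pytest.mark.parametrize("depth,kept", [(5999, False), (6000, True), (6001, True)])
    def test_boundary(self, depth, kept):
        t = _table([[depth]])
        res = filter_low_depth_samples(t)
        assert (res.table.n_samples == 1) is kept

    def test_idempotent(self):
        t = _table([[7000], [100], [6000]])
        once = filter_low_depth_samples(t).table
        assert filter_low_depth_samples(once).table == once


def _qc_fixture():
    """4 controls, 6 blow samples; t0 control-only, t1 blow-only, t2 everywhere."""
    counts = np.zeros((10, 3), dtype=int)
    counts[:4, 0] = 50          # t0 present in all controls only
    counts[4:, 1] = 80          # t1 present in all blow only
    counts[:, 2] = 10           # t2 everywhere
    table = _table(counts)
    meta = [
        SampleRecord(f"s{i}", "control", "neg_control") for i in range(4)
    ] + [
        SampleRecord(f"s{i}", f"D{i}", "blow", week=2) for i in range(4, 10)
    ]
    return table, meta


class TestPrevalenceScores:
    def test_maximal_skew_directions(self):
        table, meta = _qc_fixture()
        calls = {c.taxon_id: c for c in prevalence_contaminant_scores(table, meta)}
        assert calls["t0"].score < 0.5 and calls["t0"].classification == "contaminant"
        assert calls["t1"].score > 0.5
        not_calls = {c.taxon_id: c for c in prevalence_contaminant_scores(
            table, meta, direction="is_not_contaminant")}
        assert not_calls["t1"].score < 0.5

    def test_swap_symmetry(self):
        """is_not_contaminant equals is_contaminant with classes swapped."""
        table, meta = _qc_fixture()
        swapped_meta = []
        for r in meta:
            if r.sample_type == "neg_control":
                swapped_meta.append(SampleRecord(r.sample_id, "D", "blow", week=2))
            else:
                swapped_meta.append(SampleRecord(r.sample_id, "c", "neg_control"))
        direct = prevalence_contaminant_scores(table, meta, direction="is_not_contaminant")
        swapped = prevalence_contaminant_scores(table, swapped_meta,
                                                direction="is_contaminant")
        for c1, c2 in zip(direct, swapped):
            assert c1.score == pytest.approx(c2.score, abs=1e-12)

    def test_all_absent_taxon_gets_finite_score(self):
        table, meta = _qc_fixture()
        t2 = CountTable(table.sample_ids, table.taxon_ids,
                        np.where(np.arange(3)[None, :] == 2, 0, table.counts))
        calls = prevalence_contaminant_scores(t2, meta)
        assert all(np.isfinite(c.score) for c in calls)

    def test_no_controls_errors(self):
        table, meta = _qc_fixture()
        blow_only = [r for r in meta if r.sample_type == "blow"]
        sub = table.select_samples([r.sample_id for r in blow_only])
        with pytest.raises(ValueError, match="neg_control"):
            prevalence_contaminant_scores(sub, blow_only)


class TestRemoval:
    def test_remove_and_drop_controls(self):
        table, meta = _qc_fixture()
        calls = prevalence_contaminant_scores(table, meta)
        res = remove_contaminants(table, meta, calls)
        assert "t0" not in res.table.taxon_ids
        assert res.table.n_samples == 6  # controls dropped

    def test_threshold_zero_removes_nothing(self):
        table, meta = _qc_fixture()
        calls = prevalence_contaminant_scores(table, meta)
        res = remove_contaminants(table, meta, calls, threshold=0.0)
        assert res.removed_taxa == ()

    def test_threshold_monotone(self):
        table, meta = _qc_fixture()
        calls = prevalence_contaminant_scores(table, meta)
        removed = [
            set(remove_contaminants(table, meta, calls, threshold=thr).removed_taxa)
            for thr in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        for lo, hi in zip(removed, removed[1:]):
            assert lo <= hi

    def test_water_filter_separable(self):
        counts = np.zeros((8, 2), dtype=int)
        counts[:4, 0] = 100      # water taxon in water samples only
        counts[4:, 1] = 60       # blow taxon in blow only
        table = _table(counts)
        meta = [SampleRecord(f"s{i}", "pool", "water", week=2) for i in range(4)] + [
            SampleRecord(f"s{i}", f"D{i}", "blow", week=2) for i in range(4, 8)
        ]
        res = remove_water_taxa(table, meta)
        assert res.table.taxon_ids == ("t1",)
        assert res.table.n_samples == 4
        assert set(res.removed_samples) == {"s0", "s1", "s2", "s3"}

    def test_water_filter_without_water_errors(self):
        table, meta = _qc_fixture()
        with pytest.raises(ValueError):
            remove_water_taxa(table, meta)


class TestSyntheticRecovery:
    def test_contaminant_and_water_recovery(self, small_cohort):
        from blowcore.qc_filter import run_qc_cascade

        table, meta, tax, truth = small_cohort
        filtered, stages = run_qc_cascade(table, meta, tax)
        removed_contam = set(stages[-2].removed_taxa)
        removed_water = set(stages[-1].removed_taxa)
        n_contam = len(truth.contaminant_taxa)
        assert len(removed_contam & truth.contaminant_taxa) / n_contam >= 0.95
        assert len(removed_contam & truth.blow_taxa) / len(truth.blow_taxa) <= 0.05
        assert len(removed_water & truth.water_taxa) / len(truth.water_taxa) >= 0.90
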