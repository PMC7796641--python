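"""Intra-/inter-core detection, abundance summaries and recovery reporting."""

import itertools

import numpy as np
import pytest

from blowcore.core_detection import (
    CoreSet,
    EligibilityError,
    core_abundance,
    core_recovery_report,
    eligible_subjects,
    inter_core,
    intra_core,
    sharing_histogram,
)
from blowcore.tables_io import CountTable, SampleRecord


def _cohort_table(presence, weeks=(6, 11, 19, 28)):
    """Build a table from {subject: {week: count-vector}}; taxa named t0.."""
    sample_ids, rows, meta = [], [], []
    n_taxa = len(next(iter(next(iter(presence.values())).values())))
    for subj, by_week in presence.items():
        for w, vec in by_week.items():
            sid = f"{subj}_w{w}"
            sample_ids.append(sid)
            rows.append(vec)
            meta.append(SampleRecord(sid, subj, "blow", week=w))
    table = CountTable(sample_ids, tuple(f"t{j}" for j in range(n_taxa)),
                       np.array(rows))
    return table, meta


class TestIntraCore:
    def test_presence_in_all_weeks_required(self):
        table, meta = _cohort_table({
            "D1": {6: [3, 3], 11: [1, 0], 19: [7, 7], 28: [2, 2]},
        })
        cs = intra_core(table, meta, "D1")
        assert cs.members == {"t0"}  # t1 absent at week 11

    def test_substitution_window(self):
        table, meta = _cohort_table({
            "D1": {6: [3], 12: [1], 19: [7], 28: [2]},  # week 11 replaced by 12
        })
        cs = intra_core(table, meta, "D1")
        assert "D1_w12" in cs.samples_used
        assert cs.members == {"t0"}

    def test_substitution_prefers_earlier(self):
        table, meta = _cohort_table({
            "D1": {6: [3], 10: [1], 12: [5], 19: [7], 28: [2]},
        })
        cs = intra_core(table, meta, "D1")
        assert "D1_w10" in cs.samples_used

    def test_missing_week_not_repairable(self):
        table, meta = _cohort_table({
            "D1": {6: [3], 19: [7], 28: [2]},
        })
        with pytest.raises(EligibilityError, match="11"):
            intra_core(table, meta, "D1")
        assert eligible_subjects(table, meta, (6, 11, 19, 28)) == []

    def test_monotone_in_weeks(self):
        rng = np.random.default_rng(0)
        by_week = {w: rng.integers(0, 3, size=12) for w in (6, 11, 19, 28)}
        table, meta = _cohort_table({"D1": by_week})
        small = intra_core(table, meta, "D1", weeks=(6, 11))
        big = intra_core(table, meta, "D1", weeks=(6, 11, 19, 28))
        assert big.members <= small.members

    def test_members_subset_of_each_sample_presence(self):
        rng = np.random.default_rng(1)
        by_week = {w: rng.integers(0, 2, size=20) for w in (6, 11, 19, 28)}
        table, meta = _cohort_table({"D1": by_week})
        cs = intra_core(table, meta, "D1")
        for sid in cs.samples_used:
            present = {
                t for t, c in zip(table.taxon_ids, table.sample_vector(sid)) if c > 0
            }
            assert cs.members <= present


class TestInterCore:
    def _four_subjects(self):
        rng = np.random.default_rng(2)
        presence = {f"D{i}": {6: rng.integers(0, 2, size=10)} for i in range(4)}
        return _cohort_table(presence, weeks=(6,))

    def test_matches_exhaustive_enumeration(self):
        table, meta = self._four_subjects()
        subjects = sorted({r.subject_id for r in meta})
        seen = set()
        for seed in range(30):
            cs = inter_core(table, meta, week=6, n_subjects=3, seed=seed)
            seen.add(cs.selected_subjects)
            idx = [table.sample_index(f"{s}_w6") for s in cs.selected_subjects]
            expected = {
                t for j, t in enumerate(table.taxon_ids)
                if (table.counts[idx, j] > 0).all()
            }
            assert cs.members == expected
        # across seeds we cover several of the C(4,3)=4 possible selections
        assert len(seen) >= 2
        for combo in itertools.combinations(subjects, 3):
            idx = [table.sample_index(f"{s}_w6") for s in combo]
            members = {
                t for j, t in enumerate(table.taxon_ids)
                if (table.counts[idx, j] > 0).all()
            }
            assert members <= set(table.taxon_ids)

    def test_universally_present_taxon_always_member(self):
        table, meta = self._four_subjects()
        counts = table.counts.copy()
        counts[:, 0] = 5  # taxon t0 present everywhere
        table = CountTable(table.sample_ids, table.taxon_ids, counts)
        for seed in range(5):
            cs = inter_core(table, meta, week=6, n_subjects=3, seed=seed)
            assert "t0" in cs.members

    def test_single_subject_gives_presence_set(self):
        table, meta = self._four_subjects()
        cs = inter_core(table, meta, week=6, n_subjects=1, seed=0)
        sid = f"{cs.selected_subjects[0]}_w6"
        present = {t for t, c in zip(table.taxon_ids, table.sample_vector(sid)) if c > 0}
        assert cs.members == present

    def test_monotone_in_n_subjects(self):
        table, meta = self._four_subjects()
        small = inter_core(table, meta, week=6, n_subjects=2, seed=1)
        big_members = None
        for seed in range(40):  # find a selection containing the small one
            big = inter_core(table, meta, week=6, n_subjects=4, seed=seed)
            if set(small.selected_subjects) <= set(big.selected_subjects):
                big_members = big.members
                break
        assert big_members is not None and big_members <= small.members

    def test_too_few_eligible_reports_count(self):
        table, meta = self._four_subjects()
        with pytest.raises(EligibilityError, match="4"):
            inter_core(table, meta, week=6, n_subjects=5, seed=0)


class TestCoreAbundance:
    def test_hand_fraction(self):
        table, meta = _cohort_table({"D1": {6: [5, 3, 2]}}, weeks=(6,))
        cs = CoreSet(scope="intra", members=frozenset({"t0", "t2"}), weeks=(6,),
                     subject_id="D1", samples_used=("D1_w6",))
        (rec,) = core_abundance(table, meta, cs)
        assert rec.core_read_fraction == pytest.approx(0.7)

    def test_full_and_empty_core(self):
        table, meta = _cohort_table({"D1": {6: [5, 3, 2]}}, weeks=(6,))
        full = CoreSet("intra", frozenset(table.taxon_ids), (6,), "D1", (), ("D1_w6",))
        empty = CoreSet("intra", frozenset(), (6,), "D1", (), ("D1_w6",))
        assert core_abundance(table, meta, full)[0].core_read_fraction == 1.0
        assert core_abundance(table, meta, empty)[0].core_read_fraction == 0.0


class TestSharingHistogram:
    def test_single_set_mass_at_one(self):
        cs = CoreSet("intra", frozenset({"a", "b"}), (6,), "D1")
        out = sharing_histogram([cs])
        assert out["histogram"] == {1: 2}
        assert out["union_size"] == 2

    def test_matches_brute_force(self):
        sets = [
            CoreSet("intra", frozenset({"a", "b", "c"}), (6,), "D1"),
            CoreSet("intra", frozenset({"b", "c"}), (6,), "D2"),
            CoreSet("intra", frozenset({"c", "d"}), (6,), "D3"),
        ]
        out = sharing_histogram(sets)
        counts = {}
        for t in "abcd":
            k = sum(t in s.members for s in sets)
            counts[t] = k
        expected = {}
        for k in counts.values():
            expected[k] = expected.get(k, 0) + 1
        assert out["histogram"] == expected
        taxon_in_all = [t for t, k in counts.items() if k == 3]
        assert taxon_in_all == ["c"]


class TestRecovery:
    def test_shuffled_truth_gives_baseline_sensitivity(self, small_cohort):
        from blowcore.qc_filter import run_qc_cascade

        table, meta, tax, truth = small_cohort
        filtered, _ = run_qc_cascade(table, meta, tax)
        weeks = (6, 11, 19)
        sets = [intra_core(filtered, meta, s, weeks=weeks)
                for s in eligible_subjects(filtered, meta, weeks)]
        report = core_recovery_report(sets, truth)
        assert report["sensitivity"].median() > 0.9
        # shuffle: random taxon sets of the same size as the planted cores
        rng = np.random.default_rng(0)
        shuffled = truth
        shuffled_sets = {
            s: frozenset(rng.choice(list(truth.blow_taxa), size=len(c), replace=False))
            for s, c in truth.core_sets.items()
        }
        import dataclasses

        shuffled = dataclasses.replace(truth, core_sets=shuffled_sets)
        rep2 = core_recovery_report(sets, shuffled)
        # a random "planted" set overlaps the detected core only by chance
        assert rep2["sensitivity"].median() < 0.6
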