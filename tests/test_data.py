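"""Manifest parsing, subject-wise splitting, pair construction, curriculum."""

import numpy as np
import pandas as pd
import pytest

import longchange as lc
from longchange.data import (ImageRecord, LongitudinalPair, curriculum_filter,
                             make_pairs, max_interval_pairs, read_manifest,
                             split_subjects)


def _records(spec):
    """spec: {subject: [times]} -> records with tiny in-memory images."""
    out = []
    for sid, times in spec.items():
        for t in times:
            out.append(ImageRecord(subject_id=sid, time=float(t),
                                   image=np.zeros((4, 4), np.float32),
                                   target=float(t) * 2.0))
    return out


class TestReadManifest:
    def _write(self, tmp_path, df):
        import tifffile

        for p in df["path"].unique():
            tifffile.imwrite(str(tmp_path / p), np.zeros((4, 4), np.float32))
        path = tmp_path / "manifest.csv"
        df.to_csv(path, index=False)
        return path

    def test_valid_manifest_parses_sorted(self, tmp_path):
        df = pd.DataFrame({
            "subject_id": ["s1", "s1", "s2"],
            "time": [2.0, 1.0, 0.0],
            "path": ["a.tiff", "b.tiff", "c.tiff"],
        })
        records = read_manifest(self._write(tmp_path, df))
        assert len(records) == 3
        assert [(r.subject_id, r.time) for r in records] == \
            [("s1", 1.0), ("s1", 2.0), ("s2", 0.0)]

    def test_duplicate_subject_time_rejected(self, tmp_path):
        df = pd.DataFrame({
            "subject_id": ["s1", "s1"], "time": [2.0, 2.0],
            "path": ["a.tiff", "a.tiff"]})
        with pytest.raises(ValueError, match="duplicate"):
            read_manifest(self._write(tmp_path, df))

    def test_missing_column_rejected(self, tmp_path):
        df = pd.DataFrame({"subject_id": ["s1"], "time": [1.0]})
        path = tmp_path / "manifest.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_manifest(path)

    def test_non_numeric_time_rejected(self, tmp_path):
        df = pd.DataFrame({"subject_id": ["s1"], "time": ["noon"],
                           "path": ["a.tiff"]})
        with pytest.raises(ValueError, match="non-numeric"):
            read_manifest(self._write(tmp_path, df))

    def test_unreadable_image_path_rejected(self, tmp_path):
        df = pd.DataFrame({"subject_id": ["s1"], "time": [1.0],
                           "path": ["gone.tiff"]})
        path = tmp_path / "manifest.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="not found"):
            read_manifest(path)

    def test_metadata_columns_collected_in_order(self, tmp_path):
        df = pd.DataFrame({
            "subject_id": ["s1"], "time": [1.0], "path": ["a.tiff"],
            "meta_time": [1.0], "meta_sex_time": [0.0]})
        rec = read_manifest(self._write(tmp_path, df))[0]
        np.testing.assert_array_equal(rec.metadata, [1.0, 0.0])


class TestSplitSubjects:
    def test_counts_follow_fractions(self):
        recs = _records({f"s{i}": [0, 1] for i in range(10)})
        tr, va, te = split_subjects(recs, (0.6, 0.2, 0.2), seed=1)
        assert len({r.subject_id for r in tr}) == 6
        assert len({r.subject_id for r in va}) == 2
        assert len({r.subject_id for r in te}) == 2

    def test_no_subject_leakage_and_determinism(self):
        recs = _records({f"s{i}": [0, 1] for i in range(13)})
        splits1 = split_subjects(recs, seed=42)
        splits2 = split_subjects(recs, seed=42)
        sets1 = [{r.subject_id for r in s} for s in splits1]
        sets2 = [{r.subject_id for r in s} for s in splits2]
        assert sets1 == sets2
        assert sets1[0] & sets1[1] == set()
        assert sets1[0] & sets1[2] == set()
        assert sets1[1] & sets1[2] == set()

    def test_too_few_subjects_rejected(self):
        recs = _records({"s1": [0, 1], "s2": [0, 1]})
        with pytest.raises(ValueError, match="subjects"):
            split_subjects(recs, (0.6, 0.2, 0.2), seed=0)


class TestMakePairs:
    def test_all_unordered_pairs_enumerated(self, rng):
        pairs = make_pairs(_records({"s1": [0, 1, 2]}), rng=rng)
        assert len(pairs) == 3  # C(3,2)

    def test_both_orders_emission_balances_labels_exactly(self, rng):
        pairs = make_pairs(_records({"s1": [0, 1, 2]}), both_orders=True, rng=rng)
        assert len(pairs) == 6
        assert sum(p.order_label for p in pairs) == 3

    def test_reversed_presentation_negates_delta(self):
        recs = _records({"s1": [0.0, 4.0]})
        pair = LongitudinalPair(recs[1], recs[0])  # presented reversed
        assert pair.delta_time == -4.0
        assert pair.order_label == 0
        assert pair.delta_target == -8.0

    def test_reversing_flips_label_and_negates_deltas(self, rng):
        for p in make_pairs(_records({"s": [0, 2, 5, 9]}), rng=rng):
            q = p.reversed()
            assert q.order_label == 1 - p.order_label
            assert q.delta_time == -p.delta_time
            assert q.delta_target == -p.delta_target

    def test_single_timepoint_subject_skipped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="single timepoint"):
            pairs = make_pairs(_records({"s1": [0], "s2": [0, 1]}), rng=rng)
        assert {p.subject_id for p in pairs} == {"s2"}

    def test_cross_subject_pairing_impossible(self):
        recs = _records({"a": [0], "b": [1]})
        with pytest.raises(ValueError, match="subject"):
            LongitudinalPair(recs[0], recs[1])

    def test_pair_cap_limits_per_subject(self, rng):
        pairs = make_pairs(_records({"s1": list(range(10))}), rng=rng,
                           max_pairs_per_subject=5)
        assert len(pairs) == 5

    def test_max_interval_selection(self, rng):
        pairs = make_pairs(_records({"s1": [0, 1, 7], "s2": [0, 3]}), rng=rng)
        top = max_interval_pairs(pairs)
        assert len(top) == 2
        by_subject = {p.subject_id: abs(p.delta_time) for p in top}
        assert by_subject == {"s1": 7.0, "s2": 3.0}


class TestCurriculum:
    def _pairs(self, dts):
        out = []
        for i, dt in enumerate(dts):
            recs = _records({f"s{i}": [0.0, float(dt)]})
            out.append(LongitudinalPair(recs[0], recs[1]))
        return out

    def test_first_epochs_admit_only_wide_pairs(self):
        pairs = self._pairs([10, 40, 51, 80])
        kept = curriculum_filter(pairs, epoch=0, start_threshold=50.0)
        assert sorted(abs(p.delta_time) for p in kept) == [51, 80]

    def test_threshold_decays_then_vanishes_after_warmup(self):
        pairs = self._pairs([10, 40, 51, 80])
        kept4 = curriculum_filter(pairs, epoch=4, start_threshold=50.0)
        assert sorted(abs(p.delta_time) for p in kept4) == [40, 51, 80]
        for epoch in (10, 11, 25):
            assert len(curriculum_filter(pairs, epoch, 50.0)) == len(pairs)

    def test_zero_threshold_is_identity(self):
        pairs = self._pairs([1, 2, 3])
        assert curriculum_filter(pairs, 0, 0.0) == pairs
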