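import numpy as np
import pytest

from lowbiome import SampleRecord, ValidationError
from lowbiome.alpha import AlphaTable
from lowbiome.controls import (
    compare_tissue_vs_reference,
    exceedance_test,
    matched_control_distances,
    normalize_within_fetus,
    summarize_ct,
)
from lowbiome.core import CtRecord, DistanceMatrix


def _meta(tissue_ids, pbs_ids, organ="gut"):
    meta = []
    for i, s in enumerate(tissue_ids):
        meta.append(
            SampleRecord(s, "fetal_tissue", organ=organ, fetus_id=f"F{i:02d}")
        )
    for i, s in enumerate(pbs_ids):
        meta.append(SampleRecord(s, "pbs", fetus_id=f"F{i:02d}"))
    return meta


class TestExceedance:
    def test_separated_distributions(self):
        meta = _meta([f"t{i}" for i in range(3)], [f"p{i}" for i in range(3)])
        alpha = AlphaTable("shannon", {"t0": 2.0, "t1": 2.0, "t2": 2.0,
                                       "p0": 1.0, "p1": 1.0, "p2": 1.0})
        report = exceedance_test(alpha, meta)
        assert report.threshold == pytest.approx(1.0)
        assert all(report.above[s] for s in ("t0", "t1", "t2"))
        assert not any(report.above[s] for s in ("p0", "p1", "p2"))  # boundary = below
        assert report.class_tables["fetal_tissue"].tolist() == [[3, 0], [0, 3]]

    def test_identical_distribution_p_one(self):
        meta = _meta(["t0", "t1"], ["p0", "p1"])
        alpha = AlphaTable("shannon", {"t0": 1.0, "t1": 2.0, "p0": 1.0, "p1": 2.0})
        report = exceedance_test(alpha, meta)
        assert report.class_pvalues["fetal_tissue"].p_value == pytest.approx(1.0)

    def test_fisher_table_construction(self):
        pbs_ids = [f"p{i}" for i in range(20)]
        tissue_ids = [f"t{i}" for i in range(10)]
        meta = _meta(tissue_ids, pbs_ids)
        values = {s: float(i + 1) for i, s in enumerate(pbs_ids)}  # 1..20 -> q95 = 19.05
        for i, s in enumerate(tissue_ids):
            values[s] = 25.0 if i < 8 else 1.0
        report = exceedance_test(AlphaTable("shannon", values), meta)
        assert report.threshold == pytest.approx(19.05)
        assert report.class_tables["fetal_tissue"].tolist() == [[8, 2], [1, 19]]

    def test_requires_pbs(self):
        meta = [SampleRecord("t0", "fetal_tissue", organ="gut", fetus_id="F")]
        with pytest.raises(ValidationError):
            exceedance_test(AlphaTable("shannon", {"t0": 1.0}), meta)


class TestMatchedDistances:
    def _dm(self, ids, values):
        return DistanceMatrix(ids, values)

    def test_single_match(self):
        meta = [
            SampleRecord("g1", "fetal_tissue", organ="gut", fetus_id="F01"),
            SampleRecord("p1", "pbs", fetus_id="F01"),
        ]
        dm = self._dm(["g1", "p1"], [[0, 0.7], [0.7, 0]])
        mds = matched_control_distances(dm, meta)
        assert len(mds.records) == 1
        assert mds.records[0].distance == pytest.approx(0.7)

    def test_multiple_pbs_averaged_and_reference_set(self):
        meta = [
            SampleRecord("g1", "fetal_tissue", organ="gut", fetus_id="F01"),
            SampleRecord("p1", "pbs", fetus_id="F01"),
            SampleRecord("p2", "pbs", fetus_id="F01"),
            SampleRecord("p3", "pbs", fetus_id="F02"),
        ]
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.2
        v[0, 2] = v[2, 0] = 0.4
        v[0, 3] = v[3, 0] = 0.9
        v[1, 2] = v[2, 1] = 0.1
        v[1, 3] = v[3, 1] = 0.2
        v[2, 3] = v[3, 2] = 0.3
        mds = matched_control_distances(self._dm(["g1", "p1", "p2", "p3"], v), meta)
        assert mds.records[0].distance == pytest.approx(0.3)  # mean of 0.2, 0.4
        assert sorted(mds.pbs_reference) == pytest.approx([0.1, 0.2, 0.3])

    def test_unmatched_tissue_excluded_with_warning(self, caplog):
        meta = [
            SampleRecord("g1", "fetal_tissue", organ="gut", fetus_id="F01"),
            SampleRecord("p1", "pbs", fetus_id="F99"),
            SampleRecord("p2", "pbs", fetus_id="F99"),
        ]
        dm = self._dm(["g1", "p1", "p2"], [[0, 0.5, 0.5], [0.5, 0, 0.1], [0.5, 0.1, 0]])
        with caplog.at_level("WARNING"):
            mds = matched_control_distances(dm, meta)
        assert mds.records == []
        assert "g1" in caplog.text


class TestNormalizeWithinFetus:
    @staticmethod
    def _mds(records):
        from lowbiome.controls import MatchedDistanceSet, MatchedRecord

        return MatchedDistanceSet(
            records=[MatchedRecord(f"s{i}", fid, organ, d) for i, (fid, organ, d) in enumerate(records)]
        )

    def test_division_by_fetus_mean(self):
        mds = self._mds([("F1", "gut", 0.2), ("F1", "skin", 0.4)])
        out = normalize_within_fetus(mds)
        values = sorted(r.distance for r in out.records)
        assert values == pytest.approx([2 / 3, 4 / 3])

    def test_single_tissue_fetus_excluded(self):
        mds = self._mds([("F1", "gut", 0.2), ("F1", "skin", 0.4), ("F2", "gut", 0.9)])
        out = normalize_within_fetus(mds, min_tissues=2)
        assert {r.fetus_id for r in out.records} == {"F1"}

    def test_per_fetus_mean_is_one(self):
        rng = np.random.default_rng(0)
        records = [
            (f"F{k}", organ, float(rng.uniform(0.1, 1)))
            for k in range(5)
            for organ in ("gut", "skin", "lung")
        ]
        out = normalize_within_fetus(self._mds(records))
        by_fetus = out.by_fetus()
        for recs in by_fetus.values():
            assert np.mean([r.distance for r in recs]) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_up_to_mean_one(self):
        mds = self._mds([("F1", "gut", 0.2), ("F1", "skin", 0.4)])
        once = normalize_within_fetus(mds)
        twice = normalize_within_fetus(once)
        assert sorted(r.distance for r in twice.records) == pytest.approx(
            sorted(r.distance for r in once.records)
        )

    def test_zero_mean_rejected(self):
        mds = self._mds([("F1", "gut", 0.0), ("F1", "skin", 0.0)])
        with pytest.raises(ValidationError):
            normalize_within_fetus(mds)


class TestCompareTissueVsReference:
    def test_planted_shift_detected_unpaired(self):
        from lowbiome.controls import MatchedDistanceSet, MatchedRecord

        rng = np.random.default_rng(1)
        records = [
            MatchedRecord(f"s{i}", f"F{i}", "gut", float(rng.uniform(0.6, 0.9)))
            for i in range(10)
        ]
        reference = list(rng.uniform(0.1, 0.3, size=10))
        mds = MatchedDistanceSet(records=records, pbs_reference=reference)
        res = compare_tissue_vs_reference(mds, paired=False)
        assert res["gut"].p_value < 0.01

    def test_null_case_not_significant(self):
        from lowbiome.controls import MatchedDistanceSet, MatchedRecord

        rng = np.random.default_rng(2)
        records = [
            MatchedRecord(f"s{i}", f"F{i}", "gut", float(rng.uniform(0.1, 0.3)))
            for i in range(6)
        ]
        reference = list(rng.uniform(0.1, 0.3, size=12))
        mds = MatchedDistanceSet(records=records, pbs_reference=reference)
        assert compare_tissue_vs_reference(mds, paired=False)["gut"].p_value > 0.05


class TestCtSummary:
    def test_replicate_averaging(self):
        meta = [SampleRecord("s", "pbs"), SampleRecord("t", "fetal_tissue", organ="gut", fetus_id="F")]
        records = [CtRecord("s", (25.0, 25.4)), CtRecord("t", (30.0,))]
        summary = summarize_ct(records, meta)
        assert summary.mean_ct["s"] == pytest.approx(25.2)
        assert summary.mean_ct["t"] == pytest.approx(30.0)

    def test_lower_ct_class_detected(self):
        rng = np.random.default_rng(3)
        meta, records = [], []
        for i in range(10):
            meta.append(SampleRecord(f"g{i}", "fetal_tissue", organ="gut", fetus_id=f"F{i}"))
            records.append(CtRecord(f"g{i}", (float(rng.normal(28, 0.3)),)))
            meta.append(SampleRecord(f"p{i}", "pbs", fetus_id=f"F{i}"))
            records.append(CtRecord(f"p{i}", (float(rng.normal(33, 0.3)),)))
            meta.append(SampleRecord(f"th{i}", "fetal_tissue", organ="thymus", fetus_id=f"F{i}"))
            records.append(CtRecord(f"th{i}", (float(rng.normal(33, 0.3)),)))
        summary = summarize_ct(records, meta)
        assert summary.class_vs_pbs["gut"].p_value < 0.001
        assert summary.organ_vs_internal["gut"].p_value < 0.001
        assert np.mean([summary.mean_ct[f"g{i}"] for i in range(10)]) < np.mean(
            [summary.mean_ct[f"p{i}"] for i in range(10)]
        )
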