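"""Metric computation, table aggregation, Δ arithmetic, boxplot statistics."""

import numpy as np
import pandas as pd
import pytest

from gaitxpop.evaluation import (
    DeltaRecord,
    MetricRecord,
    aggregate_group,
    boxplot_stats,
    compute_metrics,
    participant_deltas,
    select_representatives,
)


def _prov(pids):
    return pd.DataFrame({"participant_id": pids, "group": "young",
                         "segment": 0, "end_idx": range(len(pids))})


class TestComputeMetrics:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(0)
        truths = rng.normal(size=(30, 6))
        recs = compute_metrics(truths, truths, _prov(["A"] * 30), "within")
        assert recs[0].mae_avg == pytest.approx(0.0)
        assert recs[0].r_avg == pytest.approx(1.0)

    def test_hand_computed_offset_series(self):
        truths = np.tile(np.array([[0.0], [10.0], [20.0]]), (1, 6))
        preds = truths + 1.0
        recs = compute_metrics(preds, truths, _prov(["A"] * 3), "within")
        assert recs[0].mae_avg == pytest.approx(1.0)
        assert recs[0].r_avg == pytest.approx(1.0)

    def test_constant_channel_flagged_missing(self):
        truths = np.tile(np.array([[0.0], [10.0], [20.0]]), (1, 6))
        truths[:, 3] = 7.0  # kneeR constant -> R undefined there
        preds = truths + np.random.default_rng(1).normal(0, 0.1, truths.shape)
        with pytest.warns(UserWarning, match="kneeR"):
            recs = compute_metrics(preds, truths, _prov(["A"] * 3), "within")
        assert np.isnan(recs[0].r[3])
        with pytest.warns(UserWarning):
            assert np.isfinite(recs[0].r_avg)

    def test_window_order_invariance(self):
        rng = np.random.default_rng(2)
        truths = rng.normal(size=(40, 6))
        preds = truths + rng.normal(0, 0.5, truths.shape)
        a = compute_metrics(preds, truths, _prov(["A"] * 40), "within")[0]
        perm = rng.permutation(40)
        b = compute_metrics(preds[perm], truths[perm],
                            _prov(["A"] * 40), "within")[0]
        assert a.mae == pytest.approx(b.mae)
        assert a.r == pytest.approx(b.r)


class TestAggregationArithmetic:
    def test_participant_average_equals_bilateral_mean(self):
        rng = np.random.default_rng(3)
        mae = tuple(rng.uniform(1, 8, 6))
        rec = MetricRecord("A", "young", "within", mae,
                           tuple(rng.uniform(0.5, 1, 6)))
        bil = rec.bilateral_mae()
        assert rec.mae_avg == pytest.approx(np.mean(list(bil.values())))
        assert rec.mae_avg == pytest.approx(np.mean(mae))

    def test_group_delta_equals_mean_of_participant_deltas(self):
        rng = np.random.default_rng(4)
        records = []
        for pid in ("A", "B", "C"):
            for strat in ("within", "cross"):
                records.append(MetricRecord(
                    pid, "young", strat, tuple(rng.uniform(2, 8, 6)),
                    tuple(rng.uniform(0.5, 1, 6))))
        table = aggregate_group(records)
        row = table[(table["metric"] == "MAE") & (table["joint"] == "avg")]
        deltas = participant_deltas(records)
        assert row["delta"].iloc[0] == pytest.approx(
            np.mean([d.delta_mae for d in deltas]))
        assert row["delta"].iloc[0] == pytest.approx(
            row["cross"].iloc[0] - row["within"].iloc[0])

    def test_single_participant_group_mean(self):
        rec = MetricRecord.from_bilateral(
            "A", "young", "within",
            {"hip": 4.0, "knee": 6.0, "ankle": 2.0})
        table = aggregate_group([rec])
        hip = table[(table["metric"] == "MAE") & (table["joint"] == "hip")]
        assert hip["within"].iloc[0] == pytest.approx(4.0)

    def test_unpaired_participant_excluded_with_warning(self):
        rng = np.random.default_rng(5)
        records = [
            MetricRecord("A", "g", "within", tuple(rng.uniform(1, 5, 6)),
                         tuple(rng.uniform(0, 1, 6))),
            MetricRecord("A", "g", "cross", tuple(rng.uniform(1, 5, 6)),
                         tuple(rng.uniform(0, 1, 6))),
            MetricRecord("B", "g", "within", tuple(rng.uniform(1, 5, 6)),
                         tuple(rng.uniform(0, 1, 6))),
        ]
        with pytest.warns(UserWarning, match="B"):
            aggregate_group(records)
        with pytest.warns(UserWarning, match="B"):
            deltas = participant_deltas(records)
        assert [d.participant_id for d in deltas] == ["A"]


class TestDeltas:
    def test_identical_strategies_zero_delta(self):
        mae = (3.0,) * 6
        r = (0.9,) * 6
        records = [MetricRecord("A", "g", "within", mae, r),
                   MetricRecord("A", "g", "cross", mae, r)]
        d = participant_deltas(records)[0]
        assert d.delta_mae == 0.0 and d.delta_r == 0.0


class TestBoxplotStats:
    def test_far_point_is_outlier(self):
        bs = boxplot_stats([1, 2, 3, 4, 100])
        assert bs.outliers == (100.0,)
        assert bs.whisker_high <= 4.0

    def test_all_equal_no_outliers(self):
        bs = boxplot_stats([5.0] * 8)
        assert bs.iqr == 0.0 and bs.outliers == ()

    def test_median_of_one_to_eight(self):
        assert boxplot_stats(range(1, 9)).median == pytest.approx(4.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_stats([])

    def test_quartiles_linear_interpolation(self):
        bs = boxplot_stats([1, 2, 3, 4])
        assert bs.q1 == pytest.approx(1.75)
        assert bs.q3 == pytest.approx(3.25)


class TestRepresentatives:
    @staticmethod
    def _records(maes):
        recs, deltas = [], []
        for pid, (within_mae, dmae) in maes.items():
            recs.append(MetricRecord.from_bilateral(
                pid, "g", "within",
                {"hip": within_mae, "knee": within_mae, "ankle": within_mae}))
            deltas.append(DeltaRecord(pid, "g", dmae, -dmae / 10))
        return recs, deltas

    def test_median_closest_selected(self):
        recs, deltas = self._records({
            "A": (3.0, -0.5), "B": (4.0, 0.2), "C": (5.0, -0.1)})
        out = select_representatives(recs, deltas)["g"]
        assert out["median"] == "B"  # 4.0 is the median of {3,4,5}
        assert out["best"] == "A" and out["worst"] == "B"

    def test_exact_median_match(self):
        recs, deltas = self._records({
            "A": (4.46, -0.3), "B": (5.2, -0.2), "C": (3.8, 0.1),
            "D": (4.46, 0.4), "E": (6.0, -0.1)})
        out = select_representatives(recs, deltas)["g"]
        # group median is 4.46; tie between A and D broken by lowest id
        assert out["median"] == "A"

    def test_single_participant_is_everything(self):
        recs, deltas = self._records({"A": (4.0, -0.2)})
        out = select_representatives(recs, deltas)["g"]
        assert out["best"] == out["worst"] == out["median"] == "A"

    def test_heterogeneous_group_subgroup_medians(self):
        recs, deltas = self._records({
            "A": (3.0, -0.5), "B": (4.0, -0.2), "C": (5.0, -0.1),
            "D": (6.0, 0.3), "E": (7.0, 0.6)})
        out = select_representatives(recs, deltas)["g"]
        assert out["improved_median"] == "B"  # median of {3,4,5} is 4
        assert out["degraded_median"] in {"D", "E"}
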