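"""Fold assignment, run enumeration, balanced sampling, training loop."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from gaitxpop import training
from gaitxpop.training import (
    FoldAssignment,
    RunPlan,
    TrainConfig,
    assign_folds,
    compute_sampler_weights,
    enumerate_runs,
    predict_test,
    train_run,
)


def _manifest(sizes: dict[str, int]) -> pd.DataFrame:
    rows = []
    for group, n in sizes.items():
        prefix = group[0].upper()
        rows += [{"participant_id": f"{prefix}{i + 1:02d}", "group": group}
                 for i in range(n)]
    return pd.DataFrame(rows)


class TestAssignFolds:
    def test_balanced_sizes_three_study_groups(self):
        manifest = _manifest({"young": 17, "older": 20, "preop": 14})
        fa = assign_folds(manifest, seed=1)
        for group, n in (("young", 17), ("older", 20), ("preop", 14)):
            sizes = sorted(
                len(fa.participants([f], group)) for f in range(1, 6))
            if n == 20:
                assert sizes == [4, 4, 4, 4, 4]
            elif n == 17:
                assert sizes == [3, 3, 3, 4, 4]
            else:  # 14 participants over 5 folds
                assert sizes == [2, 3, 3, 3, 3]

    def test_every_participant_exactly_once(self):
        manifest = _manifest({"young": 17, "older": 20})
        fa = assign_folds(manifest, seed=0)
        assert sorted(fa.folds) == sorted(manifest["participant_id"])

    def test_determinism_and_persistence(self, tmp_path):
        manifest = _manifest({"young": 7})
        a = assign_folds(manifest, seed=5)
        b = assign_folds(manifest, seed=5)
        assert a == b
        a.save(tmp_path / "folds.json")
        assert FoldAssignment.load(tmp_path / "folds.json") == a

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="young"):
            assign_folds(_manifest({"young": 4}), seed=0)


class TestEnumerateRuns:
    def test_within_counts(self):
        fa = assign_folds(_manifest({"young": 5, "older": 5, "preop": 5}),
                          seed=0)
        assert len(enumerate_runs(fa, "within", groups=["young"])) == 20
        assert len(enumerate_runs(fa, "within")) == 60

    def test_cross_counts_and_pooling(self):
        fa = assign_folds(_manifest({"young": 5, "older": 5, "preop": 5}),
                          seed=0)
        plans = enumerate_runs(fa, "cross")
        assert len(plans) == 20
        for plan in plans:
            assert plan.group is None
            test_ids = fa.participants([plan.test_fold])
            assert {fa.groups[pid] for pid in test_ids} \
                == {"young", "older", "preop"}

    def test_participant_disjointness_audit(self):
        fa = assign_folds(_manifest({"young": 8, "older": 11}), seed=2)
        for strategy in ("within", "cross"):
            for plan in enumerate_runs(fa, strategy):
                test = set(fa.participants([plan.test_fold], plan.group))
                val = set(fa.participants([plan.val_fold], plan.group))
                train = set(fa.participants(plan.train_folds, plan.group))
                assert not test & (train | val)
                assert not val & train

    def test_inconsistent_plan_rejected(self):
        with pytest.raises(ValueError):
            RunPlan("within", "young", test_fold=1, val_fold=1,
                    train_folds=(2, 3, 4))


class TestSamplerWeights:
    def test_inverse_window_count_weights(self, tiny_windows):
        ids = sorted(set(tiny_windows.participants))[:2]
        sw = compute_sampler_weights(tiny_windows, ids)
        pids = tiny_windows.participants[sw.indices]
        for pid in ids:
            n_pid = (pids == pid).sum()
            np.testing.assert_allclose(sw.weights[pids == pid], 1.0 / n_pid)
        assert sw.draws_per_epoch == len(sw.indices)

    def test_single_participant_uniform(self, tiny_windows):
        pid = tiny_windows.participants[0]
        sw = compute_sampler_weights(tiny_windows, [pid])
        assert len(set(sw.weights.tolist())) == 1

    def test_balanced_draw_shares_chi_square(self):
        """Two participants with 100 and 300 windows: weights 1/100 and
        1/300 give expected 50/50 draw shares; 1e5 multinomial draws must
        pass a chi-square test against uniform at alpha = 0.01."""
        prov = pd.DataFrame({
            "participant_id": ["A"] * 100 + ["B"] * 300,
            "group": "g", "segment": 0, "end_idx": 0})
        from gaitxpop.windowing import WindowConfig, WindowDataset
        ds = WindowDataset(np.zeros((400, 6, 10), np.float32),
                           np.zeros((400, 6), np.float32), prov,
                           WindowConfig(10, 5))
        sw = compute_sampler_weights(ds, ["A", "B"])
        np.testing.assert_allclose(np.unique(sw.weights), [1 / 300, 1 / 100])
        rng = np.random.default_rng(0)
        draws = rng.choice(sw.indices, size=100_000,
                           p=sw.weights / sw.weights.sum())
        n_a = (ds.participants[draws] == "A").sum()
        stat, p = chisquare([n_a, 100_000 - n_a])
        assert p > 0.01

    def test_zero_window_participant_warned_and_excluded(self, tiny_windows):
        ids = sorted(set(tiny_windows.participants))[:1] + ["ZZ"]
        with pytest.warns(UserWarning, match="ZZ"):
            sw = compute_sampler_weights(tiny_windows, ids)
        assert set(tiny_windows.participants[sw.indices]) == {ids[0]}


@pytest.fixture(scope="module")
def tiny_run(tiny_windows, tiny_manifest):
    """One desk-scale training run on the clean fixture dataset."""
    fa = assign_folds(tiny_manifest, seed=0)
    cfg = TrainConfig(epochs=2, batch_size=64, width_multiplier=0.125, seed=0)
    plan = RunPlan("within", "young", test_fold=1, val_fold=2,
                   train_folds=(3, 4, 5))
    result = train_run(plan, cfg, tiny_windows, fa)
    return fa, cfg, plan, result


class TestTrainRun:
    def test_loss_decreases(self, tiny_run):
        _, _, _, result = tiny_run
        h = result.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]
        assert np.isfinite(h["val_loss"]).all()

    def test_deterministic_loss_trajectory(self, tiny_run, tiny_windows):
        fa, cfg, plan, result = tiny_run
        again = train_run(plan, cfg, tiny_windows, fa)
        pd.testing.assert_frame_equal(result.history, again.history)

    def test_standardizer_fitted_on_training_folds_only(self, tiny_run,
                                                        tiny_windows):
        fa, _, plan, result = tiny_run
        from gaitxpop.windowing import fit_standardizer
        expected = fit_standardizer(
            tiny_windows, fa.participants(plan.train_folds, "young"))
        np.testing.assert_array_equal(result.standardizer.target_mean,
                                      expected.target_mean)


class TestPredictTest:
    def test_ensemble_of_identical_models_equals_single(self, tiny_run,
                                                        tiny_windows):
        fa, _, _, result = tiny_run
        ens, truths, prov, per_model = predict_test(
            [result] * 4, tiny_windows, fa)
        np.testing.assert_allclose(ens, per_model[0], atol=1e-5)
        test_ids = set(fa.participants([1], "young"))
        assert set(prov["participant_id"]) == test_ids

    def test_constant_models_average(self):
        # models predicting constants 1..4 degrees -> ensemble 2.5
        per_model = np.stack([np.full((10, 6), float(c))
                              for c in (1, 2, 3, 4)])
        np.testing.assert_allclose(per_model.mean(axis=0), 2.5)

    def test_ensemble_mae_bounded_by_worst_model(self, tiny_run,
                                                 tiny_windows):
        fa, cfg, plan, result = tiny_run
        import dataclasses
        results = [result]
        for val in (3, 4, 5):
            p = RunPlan("within", "young", test_fold=1, val_fold=val,
                        train_folds=tuple(sorted({2, 3, 4, 5} - {val})))
            results.append(train_run(p, cfg, tiny_windows, fa))
        ens, truths, _, per_model = predict_test(results, tiny_windows, fa)
        ens_mae = np.abs(ens - truths).mean()
        per_maes = [np.abs(pm - truths).mean() for pm in per_model]
        assert ens_mae <= max(per_maes) + 1e-9

    def test_mismatched_runs_rejected(self, tiny_run, tiny_windows):
        fa, _, _, result = tiny_run
        with pytest.raises(ValueError):
            predict_test([], tiny_windows, fa)


def test_scaled_config_profile():
    cfg = training.scaled_config(seed=3)
    assert cfg.epochs == 5
    assert cfg.width_multiplier == 0.25
    assert cfg.max_windows_per_participant == 2000
    assert cfg.batch_size == 128 and cfg.learning_rate == 0.001
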