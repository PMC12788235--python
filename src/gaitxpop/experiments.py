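"""Desk-scale generalization study.

A scaled-down replica of the full experiment that runs on one CPU in
minutes: three synthetic populations of five participants each with
single-speed bouts, the quarter-width network, and five training
epochs.  The young population is low-heterogeneity (the learnability
floor); the older population is high-heterogeneity, which is the regime
where pooling training data across populations is expected to help; the
pre-operative population walks shorter bouts with a strongly asymmetric,
irregular gait.

``run_scaled_generalization`` trains, for one outer test fold, the four
inner-fold models of (a) within-young, (b) within-older and (c)
cross-population strategies, and reports the ensemble test MAE/R for
the young group plus the older group's ΔMAE = MAE_cross − MAE_within.
A ridge regression from flattened windows is computed alongside as a
linear baseline diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluation, synthetic, training, windowing
from .preprocessing import preprocess_recording
from .windowing import WindowConfig


def scaled_profiles(n_per_group: int = 5) -> dict[str, synthetic.PopulationProfile]:
    """Scaled-down study populations (low sensor noise, single speed)."""
    return {
        "young": synthetic.PopulationProfile(
            name="young", n_participants=n_per_group,
            cadence_mean=112.0, cadence_sd=5.0,
            asymmetry_mean=0.04, asymmetry_sd=0.02, phase_jitter_sd=0.008,
            sensor_noise_sd=0.01, bout_duration_dist=(45.0, 60.0),
            n_speed_conditions=1, heterogeneity_scale=1.0),
        "older": synthetic.PopulationProfile(
            name="older", n_participants=n_per_group,
            cadence_mean=106.0, cadence_sd=6.0,
            asymmetry_mean=0.08, asymmetry_sd=0.04, phase_jitter_sd=0.015,
            sensor_noise_sd=0.01, bout_duration_dist=(45.0, 60.0),
            n_speed_conditions=1, heterogeneity_scale=2.0),
        "preop": synthetic.PopulationProfile(
            name="preop", n_participants=n_per_group,
            cadence_mean=96.0, cadence_sd=7.0,
            rom_mean={"hip": 32.0, "knee": 50.0, "ankle": 22.0},
            asymmetry_mean=0.2, asymmetry_sd=0.06, phase_jitter_sd=0.03,
            sensor_noise_sd=0.01, bout_duration_dist=(30.0, 40.0),
            n_speed_conditions=1, heterogeneity_scale=1.5),
    }


@dataclass
class ScaledStudyResult:
    seed: int
    young_within_mae: float  # ensemble test MAE, degrees
    young_within_r: float  # mean Pearson R over joints
    older_within_mae: float
    older_cross_mae: float
    older_delta_mae: float  # cross - within; negative = improvement
    ridge_young_mae: float  # linear-readout baseline on the young split
    mean_predictor_mae: float  # young test MAE of predicting the train mean


def build_scaled_dataset(seed: int, n_per_group: int = 5
                         ) -> tuple[windowing.WindowDataset,
                                    training.FoldAssignment]:
    """Generate, clean and window the scaled study dataset."""
    recs = synthetic.generate_dataset(scaled_profiles(n_per_group),
                                      seed=seed, gap_rate=0.02)
    cleaned = [preprocess_recording(r)[0] for r in recs]
    cfg = training.scaled_config(seed=seed)
    ds = windowing.windows_from_recordings(
        cleaned, WindowConfig(),
        max_windows_per_participant=cfg.max_windows_per_participant)
    import pandas as pd

    manifest = pd.DataFrame(
        {"participant_id": [r.participant_id for r in recs],
         "group": [r.group for r in recs]})
    assignment = training.assign_folds(manifest, seed=seed)
    return ds, assignment


def run_scaled_generalization(seed: int, test_fold: int = 1,
                              n_per_group: int = 5) -> ScaledStudyResult:
    """One seed of the desk-scale within/cross comparison."""
    ds, assignment = build_scaled_dataset(seed, n_per_group)
    cfg = training.scaled_config(seed=seed)

    within_young = training.run_strategy_outer_fold(
        ds, assignment, cfg, "within", test_fold, "young")
    within_older = training.run_strategy_outer_fold(
        ds, assignment, cfg, "within", test_fold, "older")
    cross = training.run_strategy_outer_fold(
        ds, assignment, cfg, "cross", test_fold)

    def mean_mae_r(run, group):
        prov = run["provenance"]
        sel = (prov["group"] == group).to_numpy()
        recs = evaluation.compute_metrics(
            run["predictions"][sel], run["truths"][sel],
            prov.loc[sel].reset_index(drop=True), "any")
        return (float(np.mean([r.mae_avg for r in recs])),
                float(np.mean([r.r_avg for r in recs])))

    yw_mae, yw_r = mean_mae_r(within_young, "young")
    ow_mae, _ = mean_mae_r(within_older, "older")
    oc_mae, _ = mean_mae_r(cross, "older")

    # diagnostics on the same young split
    train_ids = assignment.participants(
        within_young["plans"][0].train_folds
        + (within_young["plans"][0].val_fold,), "young")
    test_ids = assignment.participants([test_fold], "young")
    ridge_mae = training.ridge_baseline(ds, train_ids, test_ids)
    std = windowing.fit_standardizer(ds, train_ids)
    te = ds.participant_mask(test_ids)
    mean_pred_mae = float(np.abs(
        ds.targets[te] - std.target_mean[None, :]).mean())

    return ScaledStudyResult(
        seed=seed,
        young_within_mae=yw_mae, young_within_r=yw_r,
        older_within_mae=ow_mae, older_cross_mae=oc_mae,
        older_delta_mae=oc_mae - ow_mae,
        ridge_young_mae=ridge_mae, mean_predictor_mae=mean_pred_mae)
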