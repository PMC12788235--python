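"""Nested subject-wise cross-validation under two training strategies.

Participants are randomly assigned, within each population, to five
folds of near-equal size; the assignment is made once and reused by
every experiment.  In the outer loop each fold serves as the test set;
in the inner loop the remaining four folds rotate through a 4-fold
train/validation split, so every run trains on three folds, monitors
one, and never sees the test participants.

Two strategies share the folds: *within*-population training draws the
training folds from a single group; *cross*-population training pools
the matching fold numbers of all groups.  Test predictions are the
arithmetic mean of the four inner-fold models, each de-standardized with
its own training-only statistics.

Training uses Adam (lr 0.001) on the Huber loss for 100 epochs with
batch size 128 at reference scale; participant imbalance in walking
duration is offset by weighted random sampling with per-window weight
1/(windows of that participant), applied to the training data only.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelSpec, JointAngleEstimator, build_model
from .nn import huber_loss
from .windowing import Standardizer, WindowDataset, fit_standardizer

N_FOLDS = 5


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 0.001
    huber_delta: float = 1.0
    width_multiplier: float = 1.0
    max_windows_per_participant: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch size and learning rate must be positive")


def scaled_config(seed: int = 0) -> TrainConfig:
    """Desk-scale profile: quarter-width network, 5 epochs, capped windows."""
    return TrainConfig(epochs=5, width_multiplier=0.25,
                       max_windows_per_participant=2000, seed=seed)


@dataclass(frozen=True)
class FoldAssignment:
    """Fixed participant -> fold mapping, balanced within each group."""

    folds: dict[str, int]  # participant_id -> fold in 1..k
    groups: dict[str, str]  # participant_id -> group
    k: int
    seed: int

    def participants(self, folds, group: str | None = None) -> list[str]:
        wanted = set(folds)
        return sorted(
            pid for pid, f in self.folds.items()
            if f in wanted and (group is None or self.groups[pid] == group))

    def group_names(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"k": self.k, "seed": self.seed, "folds": self.folds,
                       "groups": self.groups}, fh, indent=1, sort_keys=True)

    @staticmethod
    def load(path: str | Path) -> "FoldAssignment":
        with open(path) as fh:
            d = json.load(fh)
        return FoldAssignment(folds=d["folds"], groups=d["groups"],
                              k=d["k"], seed=d["seed"])


def assign_folds(manifest: pd.DataFrame, k: int = N_FOLDS,
                 seed: int = 0) -> FoldAssignment:
    """Balanced random fold assignment per group (sizes differ by <= 1)."""
    rng = np.random.default_rng((seed, 7))
    folds: dict[str, int] = {}
    groups: dict[str, str] = {}
    for group in sorted(manifest["group"].unique()):
        ids = sorted(manifest.loc[manifest["group"] == group,
                                  "participant_id"])
        if len(ids) < k:
            raise ValueError(
                f"group '{group}' has {len(ids)} participants, needs >= {k}")
        order = rng.permutation(len(ids))
        for chunk, fold in zip(np.array_split(order, k), range(1, k + 1)):
            for idx in chunk:
                folds[ids[idx]] = fold
        for pid in ids:
            groups[pid] = group
    return FoldAssignment(folds=folds, groups=groups, k=k, seed=seed)


@dataclass(frozen=True)
class RunPlan:
    """One inner-loop training run of the nested cross-validation."""

    strategy: str  # "within" | "cross"
    group: str | None  # group under test for within; None pools all
    test_fold: int
    val_fold: int
    train_folds: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strategy not in ("within", "cross"):
            raise ValueError("strategy must be 'within' or 'cross'")
        if self.val_fold == self.test_fold or self.test_fold in self.train_folds \
                or self.val_fold in self.train_folds:
            raise ValueError("test, validation and training folds must differ")


def enumerate_runs(assignment: FoldAssignment, strategy: str,
                   groups: list[str] | None = None,
                   outer_folds: list[int] | None = None) -> list[RunPlan]:
    """All (outer, inner) runs: 5 x 4 per group for within, 5 x 4 for cross."""
    k = assignment.k
    outer = outer_folds or list(range(1, k + 1))
    all_folds = set(range(1, k + 1))
    plans = []
    if strategy == "within":
        for group in groups or assignment.group_names():
            for test in outer:
                for val in sorted(all_folds - {test}):
                    train = tuple(sorted(all_folds - {test, val}))
                    plans.append(RunPlan("within", group, test, val, train))
    elif strategy == "cross":
        for test in outer:
            for val in sorted(all_folds - {test}):
                train = tuple(sorted(all_folds - {test, val}))
                plans.append(RunPlan("cross", None, test, val, train))
    else:
        raise ValueError("strategy must be 'within' or 'cross'")
    return plans


@dataclass
class SamplerWeights:
    """Per-window weights, inverse of the owner's window count."""

    weights: np.ndarray  # aligned with the window indices passed in
    indices: np.ndarray  # window indices into the full dataset
    draws_per_epoch: int


def compute_sampler_weights(ds: WindowDataset, training_ids) -> SamplerWeights:
    """Weight each training window by 1/n_windows(participant).

    Every training participant then has equal expected representation
    per epoch regardless of walking duration.  Participants with no
    windows are excluded with a warning.
    """
    ids = list(dict.fromkeys(training_ids))
    pids = ds.participants
    counts = pd.Series(pids).value_counts()
    missing = [pid for pid in ids if counts.get(pid, 0) == 0]
    if missing:
        warnings.warn(f"participants with zero windows excluded: {missing}")
        ids = [pid for pid in ids if pid not in set(missing)]
    if not ids:
        raise ValueError("no training participant has any windows")
    mask = ds.participant_mask(ids)
    indices = np.flatnonzero(mask)
    weights = 1.0 / counts[pids[indices]].to_numpy(float)
    return SamplerWeights(weights=weights, indices=indices,
                          draws_per_epoch=len(indices))


def _run_seed(cfg: TrainConfig, plan: RunPlan) -> int:
    """Deterministic per-run seed below 2**31 (stable across processes)."""
    group_key = zlib.crc32((plan.group or "").encode())
    key = (cfg.seed, int(plan.strategy == "cross"),
           group_key, plan.test_fold, plan.val_fold)
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2 ** 31))


@dataclass
class RunResult:
    plan: RunPlan
    model: JointAngleEstimator
    standardizer: Standardizer
    history: pd.DataFrame
    seed: int


def train_run(plan: RunPlan, cfg: TrainConfig, ds: WindowDataset,
              assignment: FoldAssignment) -> RunResult:
    """Train one inner-loop model; fully deterministic given (cfg, plan)."""
    train_ids = assignment.participants(plan.train_folds, plan.group)
    val_ids = assignment.participants([plan.val_fold], plan.group)
    standardizer = fit_standardizer(ds, train_ids)

    sampler = compute_sampler_weights(ds, train_ids)
    x_train = standardizer.apply_inputs(ds.inputs[sampler.indices])
    y_train = standardizer.apply_targets(ds.targets[sampler.indices])
    val_mask = ds.participant_mask(val_ids)
    x_val = standardizer.apply_inputs(ds.inputs[val_mask])
    y_val = standardizer.apply_targets(ds.targets[val_mask])

    seed = _run_seed(cfg, plan)
    spec = ModelSpec(width_multiplier=cfg.width_multiplier)
    model = build_model(spec, seed=seed)
    opt = model.make_optimizer(lr=cfg.learning_rate)
    sample_rng = np.random.default_rng((seed, 11))
    probs = sampler.weights / sampler.weights.sum()

    history = []
    for epoch in range(cfg.epochs):
        order = sample_rng.choice(len(x_train), size=sampler.draws_per_epoch,
                                  replace=True, p=probs)
        batch_losses = []
        for b in range(0, len(order), cfg.batch_size):
            sel = order[b:b + cfg.batch_size]
            pred = model.forward(x_train[sel], train=True)
            loss, grad = huber_loss(pred, y_train[sel], cfg.huber_delta)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b}: {plan}")
            model.backward(grad)
            opt.step()
            opt.zero_grad()
            batch_losses.append(loss)
        val_loss = np.nan
        if len(x_val):
            val_pred = model.predict(x_val)
            val_loss, _ = huber_loss(val_pred, y_val, cfg.huber_delta)
        history.append({"epoch": epoch, "train_loss": np.mean(batch_losses),
                        "val_loss": val_loss})
    model.free_caches()
    return RunResult(plan=plan, model=model, standardizer=standardizer,
                     history=pd.DataFrame(history), seed=seed)


def predict_test(results: list[RunResult], ds: WindowDataset,
                 assignment: FoldAssignment, group: str | None = None
                 ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, np.ndarray]:
    """Ensemble prediction on the outer test fold's windows, in degrees.

    The ensemble is the arithmetic mean of the four inner-fold models'
    outputs, each de-standardized with its own training-only statistics.
    Returns (ensemble predictions, truths, provenance, per-model
    predictions), restricted to the shared outer test fold and, if
    given, to one group of the pooled fold.
    """
    if not results:
        raise ValueError("no trained inner models supplied")
    test_folds = {r.plan.test_fold for r in results}
    strategies = {r.plan.strategy for r in results}
    if len(test_folds) != 1 or len(strategies) != 1:
        raise ValueError("inner models must share strategy and test fold")
    test_fold = test_folds.pop()
    scope = group
    if scope is None:
        groups = {r.plan.group for r in results}
        scope = groups.pop() if len(groups) == 1 else None
    test_ids = assignment.participants([test_fold], scope)
    mask = ds.participant_mask(test_ids)
    if not mask.any():
        raise ValueError("outer test fold has no windows")
    x_raw = ds.inputs[mask]
    truths = ds.targets[mask].astype(np.float64)
    per_model = np.stack([
        r.standardizer.invert_targets(
            r.model.predict(r.standardizer.apply_inputs(x_raw)))
        for r in results])
    ensemble = per_model.mean(axis=0)
    prov = ds.provenance.loc[mask].reset_index(drop=True)
    return ensemble, truths, prov, per_model


def ridge_baseline(ds: WindowDataset, train_ids, test_ids,
                   alpha: float = 1.0) -> float:
    """Linear-readout oracle: ridge regression from flattened windows to
    targets, returning test MAE in degrees.  A sanity floor for what a
    purely linear model extracts from the same windows."""
    from sklearn.linear_model import Ridge

    standardizer = fit_standardizer(ds, train_ids)
    mtr = ds.participant_mask(train_ids)
    mte = ds.participant_mask(test_ids)
    xtr = standardizer.apply_inputs(ds.inputs[mtr]).reshape(mtr.sum(), -1)
    xte = standardizer.apply_inputs(ds.inputs[mte]).reshape(mte.sum(), -1)
    ytr = standardizer.apply_targets(ds.targets[mtr])
    model = Ridge(alpha=alpha)
    model.fit(xtr, ytr)
    pred = standardizer.invert_targets(model.predict(xte))
    return float(np.abs(pred - ds.targets[mte]).mean())


def run_strategy_outer_fold(ds: WindowDataset, assignment: FoldAssignment,
                            cfg: TrainConfig, strategy: str, test_fold: int,
                            group: str | None = None) -> dict:
    """Train the 4 inner models for one outer fold and ensemble-predict.

    For the cross strategy predictions cover the pooled test fold; use
    the returned provenance to slice per group.
    """
    plans = [p for p in enumerate_runs(assignment, strategy,
                                       groups=[group] if group else None,
                                       outer_folds=[test_fold])]
    results = [train_run(p, cfg, ds, assignment) for p in plans]
    ensemble, truths, prov, per_model = predict_test(
        results, ds, assignment, group=None if strategy == "cross" else group)
    return {"plans": plans, "results": results, "predictions": ensemble,
            "truths": truths, "provenance": prov, "per_model": per_model}
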