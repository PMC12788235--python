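"""Per-participant metrics, group aggregation and Δ quantities.

Performance is summarized per participant and joint side by the mean
absolute error (MAE, degrees) and Pearson correlation (R) between
estimated and reference joint angles over all of that participant's
test-window targets.  Bilateral joint values are the mean of the left
and right sides; a participant's average is the mean over the six
joint-sides (equivalently of the three bilateral values).

Δ quantities compare the two training strategies per participant and
group: ΔMAE = MAE_cross − MAE_within (negative = improvement) and
ΔR = R_cross − R_within (positive = improvement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ANGLE_COLUMNS, JOINTS

__all__ = [
    "MetricRecord", "DeltaRecord", "BoxplotStats",
    "compute_metrics", "metrics_frame", "aggregate_group",
    "participant_deltas", "boxplot_stats", "select_representatives",
]


@dataclass(frozen=True)
class MetricRecord:
    """One participant's per-joint-side MAE and Pearson R for a strategy."""

    participant_id: str
    group: str
    strategy: str  # "within" | "cross"
    mae: tuple[float, ...]  # 6 values, order hipL,hipR,kneeL,kneeR,ankleL,ankleR
    r: tuple[float, ...]  # 6 values; NaN where R is undefined

    def __post_init__(self) -> None:
        if len(self.mae) != 6 or len(self.r) != 6:
            raise ValueError("expected 6 joint-side values")
        if any(m < 0 for m in self.mae):
            raise ValueError("MAE must be non-negative")
        finite_r = [v for v in self.r if np.isfinite(v)]
        if any(not -1.0000001 <= v <= 1.0000001 for v in finite_r):
            raise ValueError("R must lie in [-1, 1]")

    def bilateral_mae(self) -> dict[str, float]:
        return {j: (self.mae[2 * i] + self.mae[2 * i + 1]) / 2.0
                for i, j in enumerate(JOINTS)}

    def bilateral_r(self) -> dict[str, float]:
        out = {}
        for i, j in enumerate(JOINTS):
            pair = [v for v in self.r[2 * i: 2 * i + 2] if np.isfinite(v)]
            out[j] = float(np.mean(pair)) if pair else np.nan
        return out

    @property
    def mae_avg(self) -> float:
        return float(np.mean(self.mae))

    @property
    def r_avg(self) -> float:
        finite = [v for v in self.r if np.isfinite(v)]
        if len(finite) < 6:
            warnings.warn(f"{self.participant_id}: undefined R channels "
                          "excluded from the participant average")
        return float(np.mean(finite)) if finite else np.nan

    @staticmethod
    def from_bilateral(participant_id: str, group: str, strategy: str,
                       mae_by_joint: dict[str, float],
                       r_by_joint: dict[str, float] | None = None
                       ) -> "MetricRecord":
        """Build a record from bilateral (hip/knee/ankle) values, e.g.
        when only bilateral summaries are available; both sides of a
        joint receive the same value, leaving all averages intact."""
        mae = tuple(mae_by_joint[j] for j in JOINTS for _ in range(2))
        r_by_joint = r_by_joint or {j: np.nan for j in JOINTS}
        r = tuple(r_by_joint[j] for j in JOINTS for _ in range(2))
        return MetricRecord(participant_id, group, strategy, mae, r)


def compute_metrics(predictions: np.ndarray, truths: np.ndarray,
                    provenance: pd.DataFrame, strategy: str
                    ) -> list[MetricRecord]:
    """Per-participant MAE and Pearson R over all test windows, in degrees.

    Predictions must already be de-standardized.  A constant truth or
    prediction channel makes R undefined for that channel; it is flagged
    as NaN and excluded from averages with a warning.
    """
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape or predictions.shape[1] != 6:
        raise ValueError("predictions and truths must both be (N, 6)")
    records = []
    for pid, idx in provenance.groupby("participant_id").groups.items():
        rows = provenance.index.get_indexer(idx)
        p, t = predictions[rows], truths[rows]
        if len(p) < 2:
            warnings.warn(f"{pid}: fewer than 2 windows, R undefined")
        mae = np.abs(p - t).mean(axis=0)
        r = np.full(6, np.nan)
        for c in range(6):
            if len(p) >= 2 and np.std(t[:, c]) > 0 and np.std(p[:, c]) > 0:
                r[c] = np.corrcoef(p[:, c], t[:, c])[0, 1]
            else:
                warnings.warn(
                    f"{pid}/{ANGLE_COLUMNS[c]}: R undefined "
                    "(constant channel), flagged missing")
        group = provenance.loc[idx, "group"].iloc[0]
        records.append(MetricRecord(pid, group, strategy,
                                    tuple(mae), tuple(r)))
    return records


def metrics_frame(records: list[MetricRecord]) -> pd.DataFrame:
    """Tidy per-participant table with bilateral and average columns."""
    rows = []
    for rec in records:
        row = {"participant_id": rec.participant_id, "group": rec.group,
               "strategy": rec.strategy}
        for i, col in enumerate(ANGLE_COLUMNS):
            row[f"mae_{col}"] = rec.mae[i]
            row[f"r_{col}"] = rec.r[i]
        for j, v in rec.bilateral_mae().items():
            row[f"mae_{j}"] = v
        for j, v in rec.bilateral_r().items():
            row[f"r_{j}"] = v
        row["mae_avg"] = rec.mae_avg
        row["r_avg"] = rec.r_avg
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_group(records: list[MetricRecord]) -> pd.DataFrame:
    """Group-level mean tables per joint with within/cross/Δ columns.

    One row per (group, metric, joint-or-average); Δ = cross − within.
    Participants missing one strategy are excluded pairwise with a
    warning.
    """
    df = metrics_frame(records)
    have = df.pivot_table(index=["group", "participant_id"],
                          columns="strategy", values="mae_avg",
                          aggfunc="size")
    strategies = sorted(df["strategy"].unique())
    if len(strategies) == 2:
        complete = have.notna().all(axis=1)
        dropped = have.index[~complete].get_level_values(1).tolist()
        if dropped:
            warnings.warn(
                f"participants missing a strategy excluded: {dropped}")
            df = df[~df["participant_id"].isin(set(dropped))]
    rows = []
    value_cols = [f"mae_{j}" for j in JOINTS] + ["mae_avg"] \
        + [f"r_{j}" for j in JOINTS] + ["r_avg"]
    for group, gdf in df.groupby("group"):
        means = gdf.groupby("strategy")[value_cols].mean()
        for col in value_cols:
            metric, joint = col.split("_", 1)
            row = {"group": group, "metric": metric.upper(), "joint": joint}
            for strat in strategies:
                row[strat] = means.loc[strat, col]
            if {"within", "cross"} <= set(strategies):
                row["delta"] = row["cross"] - row["within"]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeltaRecord:
    """Per-participant strategy difference, cross − within."""

    participant_id: str
    group: str
    delta_mae: float  # degrees; negative = improvement
    delta_r: float  # positive = improvement


def participant_deltas(records: list[MetricRecord]) -> list[DeltaRecord]:
    """ΔMAE and ΔR per participant; skips unpaired participants."""
    by_pid: dict[str, dict[str, MetricRecord]] = {}
    for rec in records:
        by_pid.setdefault(rec.participant_id, {})[rec.strategy] = rec
    deltas = []
    for pid in sorted(by_pid):
        pair = by_pid[pid]
        if {"within", "cross"} <= set(pair):
            w, c = pair["within"], pair["cross"]
            deltas.append(DeltaRecord(pid, w.group,
                                      c.mae_avg - w.mae_avg,
                                      c.r_avg - w.r_avg))
        else:
            warnings.warn(f"{pid}: missing strategy, skipped in Δ table")
    return deltas


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey five-number summary with 1.5×IQR whiskers."""

    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")


def boxplot_stats(values) -> BoxplotStats:
    """Quartiles by linear interpolation; outliers beyond 1.5×IQR fences."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return BoxplotStats(
        median=float(med), q1=float(q1), q3=float(q3), iqr=float(iqr),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=tuple(sorted(outliers.tolist())))


def select_representatives(records: list[MetricRecord],
                           deltas: list[DeltaRecord]) -> dict[str, dict]:
    """Representative participants per group.

    best = largest ΔMAE improvement (most negative), worst = largest
    degradation, median = participant whose within-population MAE is
    closest to the group median (ties broken by lowest participant id).
    For groups with both improved (ΔMAE < 0) and degraded (ΔMAE > 0)
    subgroups, each subgroup's median-closest member is also reported.
    """
    within = {r.participant_id: r for r in records if r.strategy == "within"}
    by_group: dict[str, list[DeltaRecord]] = {}
    for d in deltas:
        by_group.setdefault(d.group, []).append(d)
    out = {}
    for group, ds in by_group.items():
        ds = sorted(ds, key=lambda d: d.participant_id)
        maes = {d.participant_id: within[d.participant_id].mae_avg
                for d in ds if d.participant_id in within}
        group_median = float(np.median(list(maes.values())))

        def closest(pids):
            return min(pids, key=lambda p: (abs(maes[p] - group_median), p))

        entry = {
            "best": min(ds, key=lambda d: (d.delta_mae, d.participant_id)
                        ).participant_id,
            "worst": max(ds, key=lambda d: (d.delta_mae, d.participant_id)
                         ).participant_id,
            "median": closest(list(maes)),
            "group_median_mae": group_median,
        }
        improved = [d.participant_id for d in ds if d.delta_mae < 0]
        degraded = [d.participant_id for d in ds if d.delta_mae > 0]
        if improved and degraded:
            for name, sub in (("improved_median", improved),
                              ("degraded_median", degraded)):
                sub_median = float(np.median([maes[p] for p in sub]))
                entry[name] = min(
                    sub, key=lambda p: (abs(maes[p] - sub_median), p))
        out[group] = entry
    return out
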