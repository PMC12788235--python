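"""Sliding-window dataset construction and leakage-free standardization.

A fixed window of 200 samples (2 s at 100 Hz) slides with a stride of 10
samples (100 ms, 95% overlap) over each valid segment of a cleaned
recording; the input is the 6-channel IMU content of the window and the
target is the 6-channel joint-angle vector at the window's final frame,
so estimation uses only past and current sensor data.  Windows never
cross a segment boundary.

Z-score standardization statistics are computed per channel from the
training participants' windows only and applied unchanged to validation
and test data; predictions are mapped back to degrees before any metric
is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import ANGLE_COLUMNS, IMU_COLUMNS, GaitRecording

PROVENANCE_COLUMNS = ("participant_id", "group", "segment", "end_idx")


@dataclass(frozen=True)
class WindowConfig:
    window_len: int = 200  # frames (2 s at 100 Hz)
    stride: int = 10  # frames (100 ms)

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.window_len:
            raise ValueError("require 0 < stride <= window_len")

    @property
    def overlap_fraction(self) -> float:
        """Fractional overlap between consecutive windows."""
        return 1.0 - self.stride / self.window_len

    def count_windows(self, segment_len: int) -> int:
        """max(0, floor((T - W)/s) + 1) windows in a segment of length T."""
        if segment_len < self.window_len:
            return 0
        return (segment_len - self.window_len) // self.stride + 1


@dataclass
class WindowDataset:
    """Stacked input windows with final-frame targets and provenance."""

    inputs: np.ndarray  # (N, 6, window_len), float32, sensor units
    targets: np.ndarray  # (N, 6), float32, degrees
    provenance: pd.DataFrame  # participant_id, group, segment, end_idx
    config: WindowConfig

    def __post_init__(self) -> None:
        n = len(self.inputs)
        if len(self.targets) != n or len(self.provenance) != n:
            raise ValueError("inputs, targets and provenance lengths differ")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def participants(self) -> np.ndarray:
        return self.provenance["participant_id"].to_numpy()

    def subset(self, mask: np.ndarray) -> "WindowDataset":
        return WindowDataset(self.inputs[mask], self.targets[mask],
                             self.provenance.loc[mask].reset_index(drop=True),
                             self.config)

    def participant_mask(self, ids) -> np.ndarray:
        return self.provenance["participant_id"].isin(set(ids)).to_numpy()

    @staticmethod
    def concatenate(parts: list["WindowDataset"]) -> "WindowDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        cfg = parts[0].config
        return WindowDataset(
            np.concatenate([p.inputs for p in parts]),
            np.concatenate([p.targets for p in parts]),
            pd.concat([p.provenance for p in parts], ignore_index=True),
            cfg)

    # -- optional HDF5 cache -------------------------------------------------

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("inputs", data=self.inputs)
            fh.create_dataset("targets", data=self.targets)
            prov = self.provenance
            fh.create_dataset(
                "provenance/participant_id",
                data=prov["participant_id"].astype("S").to_numpy())
            fh.create_dataset("provenance/group",
                              data=prov["group"].astype("S").to_numpy())
            fh.create_dataset("provenance/segment",
                              data=prov["segment"].to_numpy())
            fh.create_dataset("provenance/end_idx",
                              data=prov["end_idx"].to_numpy())
            fh.attrs["window_len"] = self.config.window_len
            fh.attrs["stride"] = self.config.stride

    @staticmethod
    def load(path: str | Path) -> "WindowDataset":
        with h5py.File(path, "r") as fh:
            cfg = WindowConfig(int(fh.attrs["window_len"]),
                               int(fh.attrs["stride"]))
            prov = pd.DataFrame({
                "participant_id": [s.decode()
                                   for s in fh["provenance/participant_id"]],
                "group": [s.decode() for s in fh["provenance/group"]],
                "segment": fh["provenance/segment"][:],
                "end_idx": fh["provenance/end_idx"][:],
            })
            return WindowDataset(fh["inputs"][:], fh["targets"][:], prov, cfg)


def make_windows(rec: GaitRecording, cfg: WindowConfig = WindowConfig()
                 ) -> WindowDataset:
    """Enumerate windows left-to-right within each valid segment."""
    inputs, targets, rows = [], [], []
    for seg_idx, (seg_start, seg_end) in enumerate(rec.segments):
        n_win = cfg.count_windows(seg_end - seg_start)
        for w in range(n_win):
            start = seg_start + w * cfg.stride
            end = start + cfg.window_len
            inputs.append(rec.imu[start:end].T)
            targets.append(rec.angles[end - 1])
            rows.append((rec.participant_id, rec.group, seg_idx, end - 1))
    shape_in = (len(inputs), 6, cfg.window_len)
    return WindowDataset(
        np.asarray(inputs, dtype=np.float32).reshape(shape_in),
        np.asarray(targets, dtype=np.float32).reshape(len(targets), 6),
        pd.DataFrame(rows, columns=PROVENANCE_COLUMNS),
        cfg)


def windows_from_recordings(recs: list[GaitRecording],
                            cfg: WindowConfig = WindowConfig(),
                            max_windows_per_participant: int | None = None,
                            ) -> WindowDataset:
    """Window every recording; optionally cap windows per participant by
    taking an evenly spaced subset (keeps coverage of the whole bout)."""
    parts = []
    for rec in recs:
        ds = make_windows(rec, cfg)
        cap = max_windows_per_participant
        if cap is not None and len(ds) > cap:
            keep = np.round(np.linspace(0, len(ds) - 1, cap)).astype(int)
            mask = np.zeros(len(ds), dtype=bool)
            mask[keep] = True
            ds = ds.subset(mask)
        parts.append(ds)
    return WindowDataset.concatenate(parts)


class DegenerateChannelError(ValueError):
    """A channel has zero variance on the training data."""


@dataclass
class Standardizer:
    """Per-channel z-score statistics for 6 inputs and 6 targets."""

    input_mean: np.ndarray
    input_sd: np.ndarray
    target_mean: np.ndarray
    target_sd: np.ndarray

    def apply_inputs(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != len(self.input_mean):
            raise ValueError("input channel count mismatch")
        return ((x - self.input_mean[None, :, None])
                / self.input_sd[None, :, None]).astype(np.float32)

    def apply_targets(self, y: np.ndarray) -> np.ndarray:
        if y.shape[1] != len(self.target_mean):
            raise ValueError("target channel count mismatch")
        return ((y - self.target_mean) / self.target_sd).astype(np.float32)

    def invert_targets(self, y: np.ndarray) -> np.ndarray:
        if y.shape[1] != len(self.target_mean):
            raise ValueError("target channel count mismatch")
        return y * self.target_sd + self.target_mean


def fit_standardizer(ds: WindowDataset, training_participants) -> Standardizer:
    """Fit z-score statistics on the training participants' windows only.

    Input statistics pool every frame of every training window per
    channel; target statistics pool the final-frame targets per channel.
    A zero-variance channel is rejected by name.
    """
    ids = set(training_participants)
    if not ids:
        raise ValueError("training participant set is empty")
    mask = ds.participant_mask(ids)
    if not mask.any():
        raise ValueError("no windows belong to the training participants")
    x = ds.inputs[mask].astype(np.float64)
    y = ds.targets[mask].astype(np.float64)
    input_mean = x.mean(axis=(0, 2))
    input_sd = x.std(axis=(0, 2))
    target_mean = y.mean(axis=0)
    target_sd = y.std(axis=0)
    for name, sd in zip(IMU_COLUMNS, input_sd):
        if sd == 0:
            raise DegenerateChannelError(f"input channel '{name}' is constant")
    for name, sd in zip(ANGLE_COLUMNS, target_sd):
        if sd == 0:
            raise DegenerateChannelError(f"target channel '{name}' is constant")
    return Standardizer(input_mean, input_sd, target_mean, target_sd)
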