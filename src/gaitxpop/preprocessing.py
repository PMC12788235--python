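"""Cleaning and synchronization of raw gait recordings.

Sensor dropouts of at most ``max_gap`` frames (default 5, i.e. 50 ms at
100 Hz) are filled by per-channel linear interpolation; longer runs are
excluded and split the recording into separate valid segments, which
downstream windowing never crosses.  Gaps touching the sequence start or
end are always excluded, since linear interpolation needs two anchors.

Two independently recorded streams are aligned via the high-amplitude
accelerometer transients produced by tapping the sensor at the start and
end of a session: the first-tap offset aligns the origins and the ratio
of inter-tap spans corrects linear clock drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import GaitRecording


class TapNotFoundError(RuntimeError):
    """No acceleration excursion above the robust threshold."""


@dataclass
class SyncResult:
    offset: int  # samples; positive = stream b starts later
    scale: float  # b's clock rate relative to a's (linear drift)
    tap_indices_a: tuple[int, int]
    tap_indices_b: tuple[int, int]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("drift scale must be positive")


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean mask."""
    padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def interpolate_gaps(rec: GaitRecording, max_gap: int = 5) -> GaitRecording:
    """Fill short IMU dropouts; exclude long ones by splitting segments.

    Runs of missing samples of length <= ``max_gap`` that are interior
    (bounded by valid samples on both sides) are linearly interpolated
    per channel and become valid.  Longer or edge-touching runs stay
    excluded.  Valid samples are never altered; the reference angle
    stream is untouched.  Afterwards ``segments`` are exactly the
    maximal runs of valid samples (empty if everything is missing).
    """
    out = rec.copy()
    n = out.n_samples
    for start, end in _missing_runs(out.missing_mask):
        length = end - start
        interior = start > 0 and end < n
        if length <= max_gap and interior:
            left, right = start - 1, end  # bounding valid samples
            frac = (np.arange(start, end) - left) / (right - left)
            out.imu[start:end] = (out.imu[left] * (1 - frac[:, None])
                                  + out.imu[right] * frac[:, None])
            out.missing_mask[start:end] = False
    out.segments = [(s, e) for s, e in _missing_runs(~out.missing_mask)]
    return out


def detect_taps(accel: np.ndarray, sample_rate: int = 100,
                search_window: float = 3.0, threshold_k: float = 8.0
                ) -> tuple[int, int]:
    """Locate the start and end tap transients in a 3-axis acceleration
    stream as the largest magnitude excursion above median + k*MAD in
    the leading and trailing search windows."""
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise ValueError("expected an (N, 3) acceleration array")
    w = int(search_window * sample_rate)
    if len(accel) <= 2 * w:
        raise ValueError("stream shorter than twice the search window")
    mag = np.linalg.norm(accel, axis=1)
    med = np.median(mag)
    mad = np.median(np.abs(mag - med))
    threshold = med + threshold_k * max(mad, 1e-12)
    taps = []
    for lo, hi in ((0, w), (len(mag) - w, len(mag))):
        seg = mag[lo:hi]
        peak = int(np.argmax(seg))
        if seg[peak] <= threshold:
            raise TapNotFoundError(
                f"no tap above median + {threshold_k}*MAD in [{lo}, {hi})")
        taps.append(lo + peak)
    return taps[0], taps[1]


def synchronize(rec_a: GaitRecording, rec_b: GaitRecording,
                search_window: float = 3.0, threshold_k: float = 8.0
                ) -> tuple[SyncResult, GaitRecording, GaitRecording]:
    """Align stream b onto stream a's time base using the two taps.

    Offset comes from first-tap alignment; the ratio of inter-tap spans
    gives a linear drift factor.  Stream b is resampled onto a's clock
    by linear interpolation and both are trimmed to common support.
    """
    taps_a = detect_taps(rec_a.imu[:, :3], rec_a.sample_rate,
                         search_window, threshold_k)
    taps_b = detect_taps(rec_b.imu[:, :3], rec_b.sample_rate,
                         search_window, threshold_k)
    span_a = taps_a[1] - taps_a[0]
    span_b = taps_b[1] - taps_b[0]
    if span_a <= 0 or span_b <= 0:
        raise ValueError("degenerate tap spans")
    scale = span_b / span_a
    offset = taps_b[0] - taps_a[0]
    # sample i on a's clock corresponds to b-index offset-free position:
    idx_a = np.arange(rec_a.n_samples, dtype=float)
    idx_b = taps_b[0] + (idx_a - taps_a[0]) * scale
    valid = (idx_b >= 0) & (idx_b <= rec_b.n_samples - 1)
    lo, hi = int(np.argmax(valid)), int(len(valid) - np.argmax(valid[::-1]))

    a_out = rec_a.copy()
    b_out = rec_b.copy()
    src = np.arange(rec_b.n_samples, dtype=float)
    b_imu = np.column_stack([
        np.interp(idx_b[lo:hi], src, rec_b.imu[:, c]) for c in range(6)])
    b_angles = np.column_stack([
        np.interp(idx_b[lo:hi], src, rec_b.angles[:, c]) for c in range(6)])
    b_missing = np.interp(idx_b[lo:hi], src,
                          rec_b.missing_mask.astype(float)) > 0.0

    a_out.imu = rec_a.imu[lo:hi]
    a_out.angles = rec_a.angles[lo:hi]
    a_out.missing_mask = rec_a.missing_mask[lo:hi]
    a_out.segments = [(0, hi - lo)]
    a_out.taps = [t - lo for t in taps_a]
    b_out.imu = b_imu
    b_out.angles = b_angles
    b_out.missing_mask = b_missing
    b_out.segments = [(0, hi - lo)]
    b_out.taps = [t - lo for t in taps_a]

    result = SyncResult(offset=int(offset), scale=float(scale),
                        tap_indices_a=taps_a, tap_indices_b=taps_b)
    return result, a_out, b_out


def preprocess_recording(rec: GaitRecording, max_gap: int = 5
                         ) -> tuple[GaitRecording, dict]:
    """Interpolate/exclude gaps and report a per-participant summary."""
    n_missing_before = int(rec.missing_mask.sum())
    cleaned = interpolate_gaps(rec, max_gap=max_gap)
    n_missing_after = int(cleaned.missing_mask.sum())
    sidecar = {
        "participant_id": rec.participant_id,
        "n_samples": rec.n_samples,
        "frames_missing": n_missing_before,
        "frames_interpolated": n_missing_before - n_missing_after,
        "frames_excluded": n_missing_after,
        "n_segments": len(cleaned.segments),
        "valid_samples": int(sum(e - s for s, e in cleaned.segments)),
    }
    return cleaned, sidecar
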