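"""Seeded multi-population synthetic gait data.

Stands in for private pelvis-IMU + motion-capture recordings.  Three
population templates (young adults n=17, older adults n=20, pre-operative
hip-osteoarthritis patients n=14) differ in cadence, range of motion,
left/right asymmetry, phase jitter and — crucially for the study design —
between-participant heterogeneity.

The generative model is deliberately abstract rather than biomechanical:
a gait phase advances at the stride frequency with a small random-walk
jitter; each joint angle is a truncated Fourier series in that phase
(K=3 harmonics), with the right leg a half-cycle out of phase and its
amplitudes attenuated by the participant's asymmetry; the six IMU
channels are linear mixtures of the first two phase harmonics plus
Gaussian sensor noise.  Angles are therefore an exact function of the
phase information carried by the IMU channels, so the regression task is
learnable by construction, with difficulty controlled by noise and
heterogeneity.  Units for the IMU channels are nominal (m/s^2, deg/s
scale) and carry no physical calibration.

All randomness flows from a single integer seed; per-participant streams
are derived by seed offsetting, so every artifact is a pure function of
(profile, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SAMPLE_RATE = 100  # Hz, fixed by the recording protocol
N_HARMONICS = 3  # angle Fourier series
JOINTS = ("hip", "knee", "ankle")
ANGLE_COLUMNS = ("hipL", "hipR", "kneeL", "kneeR", "ankleL", "ankleR")
IMU_COLUMNS = ("ax", "ay", "az", "gx", "gy", "gz")
SPEED_MULTIPLIERS = (1.0, 0.8, 1.2)  # normal, slow, fast

# Population-level map from the phase harmonics [cos p, sin p, cos 2p, sin 2p]
# to the six sensor channels; rows 0-2 are accelerometer-scale, 3-5 gyro-scale.
BASE_MIXING = np.array([
    [1.8, -0.6, 0.9, 0.3],
    [-0.4, 2.1, 0.5, -0.8],
    [0.7, 0.9, -1.5, 0.6],
    [40.0, -15.0, 20.0, 8.0],
    [-10.0, 55.0, 12.0, -18.0],
    [18.0, 22.0, -35.0, 14.0],
])

# Template Fourier phases (radians) per joint, shared across participants so a
# model trained on one set of participants transfers to another.
BASE_PHASES = {
    "hip": np.array([0.0, 0.7, 1.9]),
    "knee": np.array([1.1, 2.4, 0.3]),
    "ankle": np.array([2.2, 0.9, 2.8]),
}
AMP_FRACTIONS = np.array([0.75, 0.18, 0.07])  # of half range-of-motion
ANGLE_MEANS = {"hip": 10.0, "knee": 25.0, "ankle": 0.0}


@dataclass(frozen=True)
class PopulationProfile:
    """Distribution of gait parameters within one population."""

    name: str
    n_participants: int
    cadence_mean: float  # steps/min
    cadence_sd: float
    rom_mean: dict[str, float] = field(
        default_factory=lambda: {"hip": 40.0, "knee": 60.0, "ankle": 25.0})
    rom_sd: dict[str, float] = field(
        default_factory=lambda: {"hip": 4.0, "knee": 6.0, "ankle": 3.0})
    asymmetry_mean: float = 0.05
    asymmetry_sd: float = 0.03
    phase_jitter_sd: float = 0.01  # rad per sample
    sensor_noise_sd: float = 0.05  # relative to channel scale
    bout_duration_dist: tuple[float, float] = (150.0, 200.0)  # s per bout
    n_speed_conditions: int = 3
    heterogeneity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.cadence_mean <= 0:
            raise ValueError("cadence_mean must be positive")
        sds = [self.cadence_sd, self.asymmetry_sd, self.phase_jitter_sd,
               self.sensor_noise_sd, *self.rom_sd.values()]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        if any(v <= 0 for v in self.rom_mean.values()):
            raise ValueError("range-of-motion means must be positive")
        if self.heterogeneity_scale <= 0:
            raise ValueError("heterogeneity_scale must be positive")
        if self.n_speed_conditions not in (1, 3):
            raise ValueError("n_speed_conditions must be 1 or 3")

    @property
    def id_prefix(self) -> str:
        return {"young": "Y", "older": "O", "preop": "P"}.get(self.name, "C")


def default_profiles() -> dict[str, PopulationProfile]:
    """The three study populations.

    Heterogeneity (between-participant parameter spread) is ordered
    older > preop > young: older adults are the most heterogeneous
    walkers, pre-operative patients are pathological but share a common
    slow, cautious pattern, and young adults walk most alike.
    """
    return {
        "young": PopulationProfile(
            name="young", n_participants=17, cadence_mean=112.0, cadence_sd=5.0,
            asymmetry_mean=0.04, asymmetry_sd=0.02, phase_jitter_sd=0.008,
            sensor_noise_sd=0.05, bout_duration_dist=(150.0, 200.0),
            n_speed_conditions=3, heterogeneity_scale=1.0),
        "older": PopulationProfile(
            name="older", n_participants=20, cadence_mean=106.0, cadence_sd=6.0,
            asymmetry_mean=0.08, asymmetry_sd=0.04, phase_jitter_sd=0.015,
            sensor_noise_sd=0.05, bout_duration_dist=(150.0, 200.0),
            n_speed_conditions=3, heterogeneity_scale=2.0),
        "preop": PopulationProfile(
            name="preop", n_participants=14, cadence_mean=96.0, cadence_sd=7.0,
            rom_mean={"hip": 32.0, "knee": 50.0, "ankle": 22.0},
            asymmetry_mean=0.2, asymmetry_sd=0.06, phase_jitter_sd=0.03,
            sensor_noise_sd=0.05, bout_duration_dist=(60.0, 120.0),
            n_speed_conditions=1, heterogeneity_scale=1.5),
    }


def load_profiles(path: str | Path) -> dict[str, PopulationProfile]:
    """Read population profiles from a YAML mapping name -> fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    profiles = {}
    for name, fields in raw.items():
        fields = dict(fields)
        fields.setdefault("name", name)
        if "bout_duration_dist" in fields:
            fields["bout_duration_dist"] = tuple(fields["bout_duration_dist"])
        profiles[name] = PopulationProfile(**fields)
    return profiles


@dataclass
class ParticipantSpec:
    """One synthetic participant's gait parameters."""

    participant_id: str
    group: str
    cadence: float  # steps/min
    fourier_coeffs: dict[str, dict[str, np.ndarray]]  # joint -> mean/amp/phase
    asymmetry: float  # in [0, 1]; attenuates right-side amplitudes
    mixing_matrix: np.ndarray  # 6 x 4
    phase_jitter_sd: float
    sensor_noise_sd: float
    bout_plan: list[tuple[float, float]]  # (speed multiplier, duration s)


@dataclass
class GaitRecording:
    """One participant's synchronized IMU + joint-angle time series."""

    participant_id: str
    group: str
    imu: np.ndarray  # (N, 6): ax, ay, az, gx, gy, gz
    angles: np.ndarray  # (N, 6): hipL, hipR, kneeL, kneeR, ankleL, ankleR
    missing_mask: np.ndarray  # (N,) bool, True where IMU samples are lost
    segments: list[tuple[int, int]]  # half-open valid intervals
    sample_rate: int = SAMPLE_RATE
    taps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.imu)
        if not (len(self.angles) == len(self.missing_mask) == n):
            raise ValueError("imu, angles and missing_mask lengths differ")
        if self.sample_rate != SAMPLE_RATE:
            raise ValueError(f"sample_rate is fixed at {SAMPLE_RATE} Hz")
        self.validate_segments()

    def validate_segments(self) -> None:
        """Segments must be disjoint, sorted, and cover the valid samples."""
        covered = np.zeros(len(self.imu), dtype=bool)
        prev_end = -1
        for start, end in self.segments:
            if not (0 <= start < end <= len(self.imu)):
                raise ValueError(f"segment ({start}, {end}) out of range")
            if start <= prev_end:
                raise ValueError("segments must be sorted and disjoint")
            covered[start:end] = True
            prev_end = end

    @property
    def n_samples(self) -> int:
        return len(self.imu)

    def copy(self) -> "GaitRecording":
        return GaitRecording(
            participant_id=self.participant_id, group=self.group,
            imu=self.imu.copy(), angles=self.angles.copy(),
            missing_mask=self.missing_mask.copy(),
            segments=list(self.segments), sample_rate=self.sample_rate,
            taps=list(self.taps))


def _child_rng(seed: int, *offsets: int) -> np.random.Generator:
    return np.random.default_rng((seed, *offsets))


def sample_population(profile: PopulationProfile, seed: int
                      ) -> list[ParticipantSpec]:
    """Draw participant-level gait parameters for one population.

    Between-participant standard deviations are multiplied by
    ``heterogeneity_scale``, so parameter variance scales with its square.
    """
    rng = _child_rng(seed, 1)
    het = profile.heterogeneity_scale
    specs = []
    for i in range(profile.n_participants):
        pid = f"{profile.id_prefix}{i + 1:02d}"
        cadence = max(40.0, rng.normal(profile.cadence_mean,
                                       profile.cadence_sd * het))
        coeffs: dict[str, dict[str, np.ndarray]] = {}
        for joint in JOINTS:
            rom = max(5.0, rng.normal(profile.rom_mean[joint],
                                      profile.rom_sd[joint] * het))
            amp = AMP_FRACTIONS * (rom / 2.0)
            phase = BASE_PHASES[joint] + rng.normal(0.0, 0.15 * het, N_HARMONICS)
            coeffs[joint] = {
                "mean": np.float64(ANGLE_MEANS[joint]
                                   + rng.normal(0.0, 2.0 * het)),
                "amp": amp, "phase": phase}
        asym = float(np.clip(rng.normal(profile.asymmetry_mean,
                                        profile.asymmetry_sd * het), 0.0, 1.0))
        mixing = BASE_MIXING * (1.0 + rng.normal(0.0, 0.05 * het,
                                                 BASE_MIXING.shape))
        speeds = SPEED_MULTIPLIERS[:profile.n_speed_conditions]
        lo, hi = profile.bout_duration_dist
        bout_plan = [(s, float(rng.uniform(lo, hi))) for s in speeds]
        specs.append(ParticipantSpec(
            participant_id=pid, group=profile.name, cadence=float(cadence),
            fourier_coeffs=coeffs, asymmetry=asym, mixing_matrix=mixing,
            phase_jitter_sd=profile.phase_jitter_sd,
            sensor_noise_sd=profile.sensor_noise_sd, bout_plan=bout_plan))
    return specs


def _angles_at_phase(spec: ParticipantSpec, phase: np.ndarray) -> np.ndarray:
    """Evaluate the six joint-angle channels at the given gait phases."""
    out = np.empty((len(phase), 6))
    k = np.arange(1, N_HARMONICS + 1)
    for j, joint in enumerate(JOINTS):
        c = spec.fourier_coeffs[joint]
        # left leg at phase, right leg half a cycle later with attenuated amps
        arg_l = np.outer(phase, k) + c["phase"]
        arg_r = np.outer(phase + np.pi, k) + c["phase"]
        out[:, 2 * j] = c["mean"] + np.cos(arg_l) @ c["amp"]
        out[:, 2 * j + 1] = c["mean"] + np.cos(arg_r) @ (
            c["amp"] * (1.0 - spec.asymmetry))
    return out


def generate_recording(spec: ParticipantSpec, seed: int) -> GaitRecording:
    """Synthesize one participant's recording from their bout plan.

    The gait phase advances at ``2*pi * (cadence/120) * speed`` rad/s
    (cadence in steps/min means stride frequency cadence/120 Hz) plus a
    Gaussian random-walk jitter; the IMU is the mixing matrix applied to
    the first two phase harmonics (amplitude scaled by speed) plus noise.
    """
    if not spec.bout_plan:
        raise ValueError("bout_plan must contain at least one bout")
    rng = _child_rng(seed, 2)
    phase0 = rng.uniform(0, 2 * np.pi)
    imu_parts, angle_parts = [], []
    phase_end = phase0
    channel_scale = np.abs(BASE_MIXING).sum(axis=1)  # noise in channel units
    for speed, duration in spec.bout_plan:
        n = int(round(duration * SAMPLE_RATE))
        dphi = 2 * np.pi * (spec.cadence / 120.0) * speed / SAMPLE_RATE
        steps = dphi + rng.normal(0.0, spec.phase_jitter_sd, n)
        phase = phase_end + np.cumsum(steps)
        phase_end = phase[-1]
        harmonics = np.column_stack([
            np.cos(phase), np.sin(phase), np.cos(2 * phase), np.sin(2 * phase),
        ]) * speed
        noise = rng.normal(0.0, spec.sensor_noise_sd, (n, 6)) * channel_scale
        imu_parts.append(harmonics @ spec.mixing_matrix.T + noise)
        angle_parts.append(_angles_at_phase(spec, phase))
    imu = np.concatenate(imu_parts)
    angles = np.concatenate(angle_parts)
    n_total = len(imu)
    return GaitRecording(
        participant_id=spec.participant_id, group=spec.group,
        imu=imu, angles=angles,
        missing_mask=np.zeros(n_total, dtype=bool),
        segments=[(0, n_total)])


def inject_gaps(rec: GaitRecording, gap_rate: float, mean_gap_len: float = 3.0,
                seed: int = 0) -> GaitRecording:
    """Mark Poisson-arrival dropouts with geometric lengths as missing.

    ``gap_rate`` is the expected number of gap starts per second; gap
    lengths are geometric with the given mean (in frames), so both the
    interpolation branch (<= 5 frames) and the exclusion branch (> 5)
    occur.  Angles (the reference stream) are untouched.
    """
    if gap_rate < 0:
        raise ValueError("gap_rate must be non-negative")
    out = rec.copy()
    if gap_rate == 0:
        return out
    rng = _child_rng(seed, 3)
    p_start = gap_rate / SAMPLE_RATE
    starts = np.flatnonzero(rng.random(rec.n_samples) < p_start)
    lengths = rng.geometric(1.0 / mean_gap_len, size=len(starts))
    for start, length in zip(starts, lengths):
        out.missing_mask[start:start + length] = True
    return out


def add_sync_taps(rec: GaitRecording, amplitude: float,
                  offset_s: float = 1.0) -> GaitRecording:
    """Superimpose tap transients on the accelerometer channels.

    Mimics the operator tapping the pelvis sensor at the start and end
    of data collection to create sharp synchronization peaks.
    """
    if amplitude <= 0:
        raise ValueError("tap amplitude must be positive")
    if rec.n_samples < 4 * SAMPLE_RATE:
        raise ValueError("recording must be at least 4 s long for taps")
    out = rec.copy()
    k = int(offset_s * SAMPLE_RATE)
    pulse = amplitude * np.array([0.4, 1.0, 0.4])
    for tap in (k, rec.n_samples - 1 - k):
        lo = max(0, tap - 1)
        out.imu[lo:tap + 2, :3] += pulse[: tap + 2 - lo, None]
        out.taps.append(tap)
    return out


def generate_dataset(profiles: dict[str, PopulationProfile] | None = None,
                     seed: int = 0, gap_rate: float = 0.05,
                     tap_amplitude: float = 60.0) -> list[GaitRecording]:
    """Full study dataset: sample participants, synthesize, corrupt, tap."""
    profiles = profiles or default_profiles()
    recordings = []
    for g, (name, profile) in enumerate(sorted(profiles.items())):
        for i, spec in enumerate(sample_population(profile, seed)):
            pseed_base = (g + 1) * 1000 + i
            rec = generate_recording(spec, seed=seed + pseed_base)
            if gap_rate > 0:
                rec = inject_gaps(rec, gap_rate, seed=seed + pseed_base)
            if tap_amplitude > 0:
                rec = add_sync_taps(rec, tap_amplitude)
            recordings.append(rec)
    return recordings


# -- on-disk format ----------------------------------------------------------

CSV_COLUMNS = ("t", *IMU_COLUMNS, *ANGLE_COLUMNS)


def write_dataset(recordings: list[GaitRecording], out_dir: str | Path
                  ) -> Path:
    """One CSV per participant (missing IMU samples as empty fields) plus
    a manifest CSV (participant_id, group, n_samples, file)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for rec in recordings:
        t = np.arange(rec.n_samples) / rec.sample_rate
        imu = rec.imu.astype(object)
        imu[rec.missing_mask] = np.nan
        df = pd.DataFrame(
            np.column_stack([t, imu, rec.angles]), columns=CSV_COLUMNS)
        fname = f"{rec.participant_id}.csv"
        df.to_csv(out_dir / fname, index=False, float_format="%.6f")
        manifest_rows.append({
            "participant_id": rec.participant_id, "group": rec.group,
            "n_samples": rec.n_samples, "file": fname})
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def read_dataset(data_dir: str | Path) -> list[GaitRecording]:
    """Inverse of :func:`write_dataset`; missing IMU fields become masked."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    recordings = []
    for row in manifest.itertuples():
        df = pd.read_csv(data_dir / row.file)
        imu = df[list(IMU_COLUMNS)].to_numpy(float)
        missing = np.isnan(imu).any(axis=1)
        imu[missing] = 0.0
        recordings.append(GaitRecording(
            participant_id=row.participant_id, group=row.group,
            imu=imu, angles=df[list(ANGLE_COLUMNS)].to_numpy(float),
            missing_mask=missing, segments=[(0, len(df))]))
    return recordings


def profiles_to_yaml(profiles: dict[str, PopulationProfile],
                     path: str | Path) -> None:
    serializable = {}
    for name, prof in profiles.items():
        d = dataclasses.asdict(prof)
        d["bout_duration_dist"] = list(d["bout_duration_dist"])
        serializable[name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(serializable, fh)
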