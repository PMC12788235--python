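"""Synthetic gait generator: determinism, structure, statistical laws."""

import numpy as np
import pytest

from gaitxpop import synthetic
from gaitxpop.synthetic import (
    PopulationProfile,
    add_sync_taps,
    generate_recording,
    inject_gaps,
    sample_population,
)


def _profile(**overrides):
    base = dict(name="young", n_participants=5, cadence_mean=110.0,
                cadence_sd=5.0, n_speed_conditions=1,
                bout_duration_dist=(10.0, 12.0))
    base.update(overrides)
    return PopulationProfile(**base)


class TestSamplePopulation:
    def test_count_and_id_labelling(self):
        specs = sample_population(_profile(n_participants=17), seed=1)
        assert len(specs) == 17
        assert specs[0].participant_id == "Y01"
        assert specs[-1].participant_id == "Y17"
        assert len({s.participant_id for s in specs}) == 17

    def test_determinism(self):
        a = sample_population(_profile(), seed=3)
        b = sample_population(_profile(), seed=3)
        for sa, sb in zip(a, b):
            assert sa.cadence == sb.cadence
            np.testing.assert_array_equal(sa.mixing_matrix, sb.mixing_matrix)
            for joint in synthetic.JOINTS:
                np.testing.assert_array_equal(
                    sa.fourier_coeffs[joint]["amp"],
                    sb.fourier_coeffs[joint]["amp"])

    def test_rejects_invalid_profiles(self):
        with pytest.raises(ValueError):
            _profile(n_participants=0)
        with pytest.raises(ValueError):
            _profile(cadence_sd=-1.0)
        with pytest.raises(ValueError):
            _profile(heterogeneity_scale=0.0)

    def test_heterogeneity_scales_cadence_variance(self):
        """Doubling heterogeneity_scale multiplies the between-participant
        cadence variance by ~4 (SDs scale linearly)."""
        n = 1000
        lo = sample_population(
            _profile(n_participants=n, heterogeneity_scale=1.0), seed=9)
        hi = sample_population(
            _profile(n_participants=n, heterogeneity_scale=2.0), seed=10)
        var_lo = np.var([s.cadence for s in lo])
        var_hi = np.var([s.cadence for s in hi])
        assert var_hi / var_lo == pytest.approx(4.0, rel=0.25)

    def test_default_profiles_heterogeneity_ordering(self):
        profs = synthetic.default_profiles()
        assert (profs["older"].heterogeneity_scale
                > profs["preop"].heterogeneity_scale
                > profs["young"].heterogeneity_scale)
        assert profs["older"].n_participants == 20
        assert profs["young"].n_participants == 17
        assert profs["preop"].n_participants == 14
        assert profs["preop"].n_speed_conditions == 1


class TestGenerateRecording:
    def test_antiphase_left_right_symmetry(self):
        """With zero asymmetry and noise, the right-leg angle sequence is
        the left one advanced by half a gait cycle."""
        spec = sample_population(
            _profile(sensor_noise_sd=0.0, phase_jitter_sd=0.0), seed=2)[0]
        spec.asymmetry = 0.0
        spec.cadence = 120.0  # stride period exactly 1 s = 100 samples
        rec = generate_recording(spec, seed=4)
        half_cycle = 50  # half a stride at 100 Hz
        left = rec.angles[:-half_cycle, 0]
        right = rec.angles[half_cycle:, 1]
        assert np.max(np.abs(left - right)) < 1e-6

    def test_angles_within_fourier_amplitude_bounds(self):
        spec = sample_population(_profile(), seed=5)[0]
        rec = generate_recording(spec, seed=6)
        for j, joint in enumerate(synthetic.JOINTS):
            c = spec.fourier_coeffs[joint]
            bound = np.abs(c["amp"]).sum()
            for side in (0, 1):
                chan = rec.angles[:, 2 * j + side]
                assert chan.min() >= c["mean"] - bound - 1e-9
                assert chan.max() <= c["mean"] + bound + 1e-9

    def test_stride_period_from_autocorrelation(self):
        """Cadence 120 steps/min = 1 stride/s, so the hip autocorrelation
        peaks at a lag of 100 +- 2 samples at 100 Hz."""
        spec = sample_population(
            _profile(sensor_noise_sd=0.0, phase_jitter_sd=0.0,
                     bout_duration_dist=(10.0, 10.0)), seed=2)[0]
        spec.cadence = 120.0
        rec = generate_recording(spec, seed=4)
        x = rec.angles[:, 0] - rec.angles[:, 0].mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1:]
        peak = 50 + np.argmax(ac[50:150])
        assert abs(peak - 100) <= 2

    def test_empty_bout_plan_rejected(self):
        spec = sample_population(_profile(), seed=2)[0]
        spec.bout_plan = []
        with pytest.raises(ValueError):
            generate_recording(spec, seed=0)

    def test_determinism(self):
        spec = sample_population(_profile(), seed=2)[0]
        a = generate_recording(spec, seed=11)
        b = generate_recording(spec, seed=11)
        np.testing.assert_array_equal(a.imu, b.imu)
        np.testing.assert_array_equal(a.angles, b.angles)


class TestInjectGaps:
    def test_zero_rate_is_identity(self, quiet_recording):
        out = inject_gaps(quiet_recording, gap_rate=0.0, seed=1)
        np.testing.assert_array_equal(out.missing_mask,
                                      quiet_recording.missing_mask)
        np.testing.assert_array_equal(out.imu, quiet_recording.imu)

    def test_forced_gap_placement(self, quiet_recording):
        out = quiet_recording.copy()
        out.missing_mask[500:506] = True  # direct placement of a 6-frame gap
        assert out.missing_mask[500:506].all()
        assert not out.missing_mask[499] and not out.missing_mask[506]

    def test_angles_untouched(self, quiet_recording):
        out = inject_gaps(quiet_recording, gap_rate=0.5, seed=2)
        np.testing.assert_array_equal(out.angles, quiet_recording.angles)
        assert out.missing_mask.sum() > 0

    def test_gap_count_is_poisson(self):
        """0.1 gaps/s over 600 s -> ~60 gap starts on average, within
        3 SD of the Poisson/binomial expectation over 100 seeds."""
        from gaitxpop.preprocessing import _missing_runs

        spec = sample_population(
            _profile(bout_duration_dist=(600.0, 600.0)), seed=1)[0]
        rec = generate_recording(spec, seed=1)
        counts = []
        for seed in range(100):
            gapped = inject_gaps(rec, gap_rate=0.1, mean_gap_len=1.0,
                                 seed=seed)
            counts.append(len(_missing_runs(gapped.missing_mask)))
        mean = np.mean(counts)
        # merging of adjacent gaps only shaves a tiny fraction
        assert abs(mean - 60.0) < 3 * np.sqrt(60.0 / 100) + 1.0


class TestSyncTaps:
    def test_global_max_at_tap(self, quiet_recording):
        out = add_sync_taps(quiet_recording, amplitude=80.0)
        mag = np.linalg.norm(out.imu[:, :3], axis=1)
        assert int(np.argmax(mag)) in out.taps

    def test_two_taps_recorded(self, quiet_recording):
        out = add_sync_taps(quiet_recording, amplitude=80.0)
        assert len(out.taps) == 2
        assert out.taps == sorted(out.taps)

    def test_invalid_amplitude_or_short_recording(self, quiet_recording):
        with pytest.raises(ValueError):
            add_sync_taps(quiet_recording, amplitude=0.0)
        short = quiet_recording.copy()
        short.imu = short.imu[:300]
        short.angles = short.angles[:300]
        short.missing_mask = short.missing_mask[:300]
        short.segments = [(0, 300)]
        with pytest.raises(ValueError):
            add_sync_taps(short, amplitude=10.0)


class TestRoundTripIO:
    def test_csv_round_trip_preserves_data_and_mask(self, tmp_path,
                                                    quiet_recording):
        rec = inject_gaps(quiet_recording, gap_rate=0.1, seed=5)
        synthetic.write_dataset([rec], tmp_path)
        back = synthetic.read_dataset(tmp_path)[0]
        assert back.participant_id == rec.participant_id
        np.testing.assert_array_equal(back.missing_mask, rec.missing_mask)
        valid = ~rec.missing_mask
        np.testing.assert_allclose(back.imu[valid], rec.imu[valid], atol=1e-5)
        np.testing.assert_allclose(back.angles, rec.angles, atol=1e-5)

    def test_profiles_yaml_round_trip(self, tmp_path):
        profs = synthetic.default_profiles()
        synthetic.profiles_to_yaml(profs, tmp_path / "profiles.yaml")
        back = synthetic.load_profiles(tmp_path / "profiles.yaml")
        assert back == profs
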