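"""Synthetic cohort generator: determinism, episode statistics, signal model."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from fogdetect.dataio import ValidationError
from fogdetect.gaitsim import (
    LEG_SENSORS,
    SimConfig,
    episode_schedule,
    generate_cohort,
    inject_artifacts,
    sample_subject_params,
    simulate_trial,
    synth_recording,
)
from fogdetect.preprocess import detect_artifacts


def band_power(x, fs, lo, hi):
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1 / fs)
    return spec[(f >= lo) & (f < hi)].sum()


class TestSubjectParams:
    def test_deterministic_given_seed(self):
        config = SimConfig(seed=3)
        a = sample_subject_params(config, 5)
        b = sample_subject_params(config, 5)
        assert a == b

    def test_parameters_within_declared_ranges(self):
        config = SimConfig(seed=4)
        for i in range(100):
            p = sample_subject_params(config, i)
            assert 1.0 <= p.step_freq_hz <= 2.5
            assert 3.0 <= p.tremble_freq_hz <= 8.0
            assert 0.0 <= p.fog_time_fraction_target <= 1.0
            assert p.locomotor_amp["lumbar"] < min(
                p.locomotor_amp[s] for s in LEG_SENSORS
            )

    def test_different_seeds_give_different_params(self):
        draws = {
            sample_subject_params(SimConfig(seed=s), 0).step_freq_hz
            for s in range(100)
        }
        assert len(draws) > 90  # collisions essentially impossible


class TestEpisodeSchedule:
    def _params(self, **kw):
        p = sample_subject_params(SimConfig(seed=0), 0)
        for k, v in kw.items():
            setattr(p, k, v)
        return p

    def test_zero_target_gives_no_episodes(self):
        p = self._params(fog_time_fraction_target=0.0)
        assert episode_schedule(600.0, p, seed=1).intervals == []

    def test_realized_fraction_tracks_target(self):
        p = self._params(fog_time_fraction_target=0.10, mean_episode_s=6.0)
        fracs = [
            episode_schedule(3600.0, p, seed=s).total_fog_s() / 3600.0
            for s in range(50)
        ]
        assert 0.07 <= np.mean(fracs) <= 0.13

    def test_mean_episode_duration_converges(self):
        p = self._params(fog_time_fraction_target=0.3, mean_episode_s=5.0)
        durations = []
        s = 0
        while len(durations) < 500:
            track = episode_schedule(3600.0, p, seed=1000 + s)
            durations.extend(e - b for b, e in track.intervals)
            s += 1
        mean = np.mean(durations[:500])
        assert abs(mean - 5.0) / 5.0 < 0.20

    def test_intervals_valid_and_within_duration(self):
        p = self._params(fog_time_fraction_target=0.2)
        track = episode_schedule(120.0, p, seed=7)
        for s, e in track.intervals:
            assert 0 <= s < e <= 120.0


class TestSynthRecording:
    def _setup(self, **cfg_kw):
        config = SimConfig(
            n_subjects=1,
            trial_duration_s=60.0,
            sensors=("lumbar", "lower_leg_left", "lower_leg_right"),
            **cfg_kw,
        )
        params = sample_subject_params(config, 0)
        params.noise_sd = 0.0
        return config, params

    def test_walking_spectrum_peaks_at_step_frequency(self):
        config, params = self._setup(seed=2)
        from fogdetect.dataio import AnnotationTrack

        rec = synth_recording(params, AnnotationTrack("S", "T", []), config, seed=3)
        fs = rec.sample_rate_hz
        for si, sensor in enumerate(rec.sensors):
            if sensor == "lumbar":
                continue
            x = rec.accel[:, si, 0]
            f = np.fft.rfftfreq(len(x), 1 / fs)
            peak = f[np.argmax(np.abs(np.fft.rfft(x)))]
            assert abs(peak - params.step_freq_hz) < 0.3

    def test_trembling_fog_dominates_freeze_band(self):
        config, params = self._setup(seed=5)
        params.akinetic_prob = 0.0
        from fogdetect.dataio import AnnotationTrack

        sched = AnnotationTrack("S", "T", [(0.0, 60.0)])
        rec = synth_recording(params, sched, config, seed=6)
        fs = rec.sample_rate_hz
        for si, sensor in enumerate(rec.sensors):
            if sensor == "lumbar":
                continue
            x = rec.accel[5 * 60 : 55 * 60, si, 0]
            ratio = band_power(x, fs, 3, 8) / band_power(x, fs, 0.5, 3)
            assert ratio > 1.0

    def test_akinetic_fog_suppresses_variance(self):
        config, params = self._setup(seed=7)
        params.akinetic_prob = 1.0
        from fogdetect.dataio import AnnotationTrack

        walk = synth_recording(params, AnnotationTrack("S", "T", []), config, seed=8)
        froz = synth_recording(
            params, AnnotationTrack("S", "T", [(10.0, 50.0)]), config, seed=8
        )
        sl = slice(15 * 60, 45 * 60)
        v_fog = froz.accel[sl, 1, 0].var()
        v_walk = walk.accel[sl, 1, 0].var()
        assert v_fog < 0.10 * v_walk

    def test_left_right_legs_anti_phase_during_walking(self):
        config, params = self._setup(seed=9)
        from fogdetect.dataio import AnnotationTrack

        rec = synth_recording(params, AnnotationTrack("S", "T", []), config, seed=10)
        li = rec.sensors.index("lower_leg_left")
        ri = rec.sensors.index("lower_leg_right")
        # fundamental components should be negatively correlated
        corr = np.corrcoef(rec.accel[:, li, 0], rec.accel[:, ri, 0])[0, 1]
        assert corr < -0.3

    def test_same_seed_reproduces_arrays(self):
        config, params = self._setup(seed=11)
        from fogdetect.dataio import AnnotationTrack

        sched = AnnotationTrack("S", "T", [(5.0, 9.0)])
        a = synth_recording(params, sched, config, seed=12)
        b = synth_recording(params, sched, config, seed=12)
        np.testing.assert_array_equal(a.accel, b.accel)

    def test_schedule_beyond_duration_rejected(self):
        config, params = self._setup(seed=13)
        from fogdetect.dataio import AnnotationTrack

        with pytest.raises(ValidationError):
            synth_recording(params, AnnotationTrack("S", "T", [(0.0, 90.0)]), config)


class TestArtifacts:
    def test_rate_zero_returns_recording_unchanged(self):
        rec, _, _ = simulate_trial(SimConfig(n_subjects=1, trial_duration_s=30.0, seed=1), 0, 0)
        out, times = inject_artifacts(rec, 0.0, seed=5)
        assert times == []
        np.testing.assert_array_equal(out.accel, rec.accel)

    def test_spike_count_in_poisson_interval(self):
        config = SimConfig(n_subjects=1, trial_duration_s=600.0, seed=2, with_gyro=True)
        rec, _, _ = simulate_trial(config, 0, 0)
        _, times = inject_artifacts(rec, 2.0, seed=6)
        lam = 2.0 * 10.0
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        assert lo <= len(times) <= hi

    def test_every_spike_is_flagged_downstream(self):
        config = SimConfig(n_subjects=1, trial_duration_s=120.0, seed=3, with_gyro=True)
        rec, _, _ = simulate_trial(config, 0, 0)
        spiked, times = inject_artifacts(rec, 3.0, seed=7)
        mask = detect_artifacts(spiked)
        fs = spiked.sample_rate_hz
        for t in times:
            assert mask[int(round(t * fs))]


class TestGenerateCohort:
    def test_file_counts_match_config(self, tmp_path):
        config = SimConfig(n_subjects=10, trial_duration_s=30.0, seed=4)
        manifest = generate_cohort(config, tmp_path)
        assert len(manifest.entries) == 10
        assert len(list(tmp_path.glob("*_imu.csv"))) == 10
        assert len(list(tmp_path.glob("*_fog.csv"))) == 10

    def test_same_seed_gives_byte_identical_cohort(self, tmp_path):
        config = SimConfig(n_subjects=2, trial_duration_s=20.0, seed=5)
        generate_cohort(config, tmp_path / "a")
        generate_cohort(config, tmp_path / "b")
        for pa in sorted((tmp_path / "a").iterdir()):
            pb = tmp_path / "b" / pa.name
            ha = hashlib.sha256(pa.read_bytes()).hexdigest()
            hb = hashlib.sha256(pb.read_bytes()).hexdigest()
            assert ha == hb, pa.name

    def test_pooled_fog_fraction_near_target(self, tmp_path):
        config = SimConfig(
            n_subjects=10, trial_duration_s=600.0, seed=6,
            sensors=("lower_leg_left",),
        )
        manifest = generate_cohort(config, tmp_path)
        from fogdetect.dataio import read_annotations

        total_fog = sum(
            read_annotations(e.annotation_path).total_fog_s()
            for e in manifest.entries
        )
        frac = total_fog / (10 * 600.0)
        target = np.mean(config.fog_fraction_range)
        assert abs(frac - target) <= 0.03
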