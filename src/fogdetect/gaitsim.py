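"""Seeded synthetic gait/FOG cohort generator.

Real FOG cohorts are recorded with body-worn IMUs during gait tasks and
annotated from video; no public deposit of such raw data backs this package,
so the pipeline is exercised on a generative stand-in with the statistical
structure the analysis assumes:

* walking = a dominant locomotor oscillation at the subject's step frequency
  (1-2.5 Hz) plus its first harmonic, anti-phase between left and right legs,
  larger on leg/foot sensors than on the lumbar sensor;
* trembling-type FOG = suppressed locomotor power plus a 3-8 Hz "freeze band"
  oscillation, strongest on the lower limbs;
* akinetic FOG = near-silence (drastic variance drop);
* FOG occupies roughly 9-12 % of recorded time in episodes a few seconds
  long, alternating with walking (a two-state renewal process with
  log-normal episode durations);
* occasional artifact spikes exceeding the +/-100 m/s^2 / 20 rad/s plausible
  range, plus per-channel Gaussian sensor noise and between-subject
  parameter variability.

Transitions between states use 0.25 s raised-cosine crossfades so windows
straddling an episode edge are genuinely mixed rather than a step change.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataio import (
    SENSOR_ORDER,
    AnnotationTrack,
    CohortManifest,
    IMURecording,
    ManifestEntry,
    ValidationError,
    write_annotations_or_empty,
    write_manifest,
    write_recording,
)

LEG_SENSORS = (
    "upper_leg_left",
    "upper_leg_right",
    "lower_leg_left",
    "lower_leg_right",
    "foot_left",
    "foot_right",
)

#: relative weight of the three axes of one sensor
_AXIS_WEIGHTS = np.array([1.0, 0.55, 0.35])

#: log-normal shape parameter for episode durations (fixed, not fitted)
SIGMA_LOG_EPISODE = 0.5


def derive_seed(seed: int, *parts: object) -> int:
    """Deterministically derive a sub-seed < 2**31 from a base seed and tags."""
    key = ":".join(str(p) for p in (seed, *parts))
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SubjectParams:
    """Per-subject signal-model parameters."""

    step_freq_hz: float
    locomotor_amp: dict[str, float]  # m/s^2 per sensor; legs/feet > lumbar
    tremble_freq_hz: float
    tremble_amplitude: float  # m/s^2
    fog_time_fraction_target: float
    mean_episode_s: float
    akinetic_prob: float
    noise_sd: float  # m/s^2
    phase_left_right: float  # radians, ~pi for alternating gait

    def validate(self) -> None:
        if not (1.0 <= self.step_freq_hz <= 2.5):
            raise ValidationError("step_freq_hz outside [1.0, 2.5]")
        if not (3.0 <= self.tremble_freq_hz <= 8.0):
            raise ValidationError("tremble_freq_hz outside [3, 8]")
        for name, amp in self.locomotor_amp.items():
            if amp <= 0:
                raise ValidationError(f"non-positive locomotor amplitude for {name}")
        if self.tremble_amplitude <= 0 or self.mean_episode_s <= 0:
            raise ValidationError("amplitudes and durations must be positive")
        for frac in (self.fog_time_fraction_target, self.akinetic_prob):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError("fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass
class SimConfig:
    """Cohort-level simulation configuration; the whole cohort is a pure
    function of this object."""

    n_subjects: int = 20
    trials_per_subject: int = 1
    trial_duration_s: float = 360.0
    sample_rate_hz: float = 60.0
    sensors: tuple[str, ...] = SENSOR_ORDER
    artifact_rate_per_min: float = 0.0
    seed: int = 0
    with_gyro: bool = False
    # phenotype knobs (defaults are the study conditions; see docs/methods.md)
    fog_fraction_range: tuple[float, float] = (0.06, 0.14)
    mean_episode_range_s: tuple[float, float] = (4.0, 9.0)
    akinetic_prob: float = 0.15
    lumbar_carries_fog: bool = True
    subject_prefix: str = "S"

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.trial_duration_s < 4.0:
            raise ValidationError("trial_duration_s must be >= 4 s")
        if self.sample_rate_hz not in (60.0, 100.0, 60, 100):
            raise ValidationError("sample_rate_hz must be 60 or 100")
        for s in self.sensors:
            if s not in SENSOR_ORDER:
                raise ValidationError(f"unknown sensor {s!r}")


def sample_subject_params(config: SimConfig, subject_index: int) -> SubjectParams:
    """Draw one subject's parameters; deterministic in (seed, subject_index)."""
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "subject", subject_index))
    amp = {}
    for sensor in SENSOR_ORDER:
        if sensor == "lumbar":
            amp[sensor] = rng.uniform(1.0, 1.8)
        elif sensor.startswith("upper_leg"):
            amp[sensor] = rng.uniform(2.2, 3.2)
        elif sensor.startswith("lower_leg"):
            amp[sensor] = rng.uniform(2.8, 4.0)
        else:  # feet
            amp[sensor] = rng.uniform(3.2, 4.8)
    params = SubjectParams(
        step_freq_hz=float(rng.uniform(1.2, 2.3)),
        locomotor_amp=amp,
        tremble_freq_hz=float(rng.uniform(3.5, 7.5)),
        tremble_amplitude=float(rng.uniform(1.8, 3.2)),
        fog_time_fraction_target=float(rng.uniform(*config.fog_fraction_range)),
        mean_episode_s=float(rng.uniform(*config.mean_episode_range_s)),
        akinetic_prob=float(config.akinetic_prob),
        noise_sd=float(rng.uniform(0.2, 0.4)),
        phase_left_right=float(np.pi + rng.normal(0.0, 0.15)),
    )
    params.validate()
    return params


def episode_schedule(
    duration_s: float,
    params: SubjectParams,
    seed: int,
    subject_id: str = "S?",
    trial_id: str = "T?",
) -> AnnotationTrack:
    """Two-state alternating-renewal FOG schedule.

    Episode durations are log-normal with arithmetic mean ``mean_episode_s``
    (sigma_log fixed at 0.5); walking-segment durations are exponential with
    mean chosen so the expected FOG time fraction equals the target.
    """
    if duration_s < 4.0:
        raise ValidationError("duration must be >= 4 s")
    f = params.fog_time_fraction_target
    if f <= 0.0:
        return AnnotationTrack(subject_id, trial_id, [])
    rng = np.random.default_rng(seed)
    mu_log = np.log(params.mean_episode_s) - SIGMA_LOG_EPISODE**2 / 2
    mean_walk = params.mean_episode_s * (1.0 - f) / f
    intervals: list[tuple[float, float]] = []
    # start mid-walk on average: first walk segment from the stationary
    # forward-recurrence distribution of an exponential is exponential again
    t = float(rng.exponential(mean_walk))
    while t < duration_s:
        ep = float(rng.lognormal(mu_log, SIGMA_LOG_EPISODE))
        start = t
        end = min(t + ep, duration_s)
        if end - start > 0.25:  # drop degenerate clipped slivers
            intervals.append((start, end))
        t = t + ep + float(rng.exponential(mean_walk))
    return AnnotationTrack(subject_id, trial_id, intervals)


def _crossfade_envelope(
    n: int, fs: float, intervals: Sequence[tuple[float, float]], fade_s: float = 0.25
) -> np.ndarray:
    """Per-sample weight in [0, 1]: 1 inside the intervals, raised-cosine
    ramps of length fade_s centred on each boundary."""
    env = np.zeros(n)
    t = (np.arange(n) + 0.5) / fs
    half = fade_s / 2.0
    for start, end in intervals:
        ramp_up = np.clip((t - (start - half)) / fade_s, 0.0, 1.0)
        ramp_down = np.clip(((end + half) - t) / fade_s, 0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * ramp_up)
        w *= 0.5 - 0.5 * np.cos(np.pi * ramp_down)
        env = np.maximum(env, w)
    return env


def synth_recording(
    params: SubjectParams,
    schedule: AnnotationTrack,
    config: SimConfig,
    seed: int | None = None,
) -> IMURecording:
    """Render one trial's acceleration (and optional gyro) streams.

    During walking each channel carries the locomotor fundamental plus a 0.4x
    first harmonic; during trembling FOG the locomotor content drops to 15 %
    and a freeze-band sinusoid is added (legs/feet, plus a 30 % echo on the
    lumbar sensor when ``lumbar_carries_fog``); during akinetic FOG the
    signal drops to 5 %. Each episode's phenotype is drawn i.i.d.
    (akinetic with probability ``akinetic_prob``).
    """
    config.validate()
    params.validate()
    if seed is None:
        seed = derive_seed(config.seed, "recording", schedule.subject_id, schedule.trial_id)
    fs = float(config.sample_rate_hz)
    n = int(round(config.trial_duration_s * fs))
    if schedule.intervals and schedule.intervals[-1][1] > config.trial_duration_s + 1e-9:
        raise ValidationError("schedule extends past trial duration")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    phase0 = float(rng.uniform(0, 2 * np.pi))

    # phenotype per episode
    trembling: list[tuple[float, float]] = []
    akinetic: list[tuple[float, float]] = []
    for ival in schedule.intervals:
        (akinetic if rng.random() < params.akinetic_prob else trembling).append(ival)

    env_trem = _crossfade_envelope(n, fs, trembling)
    env_akin = _crossfade_envelope(n, fs, akinetic)

    sensors = tuple(s for s in SENSOR_ORDER if s in set(config.sensors))
    accel = np.empty((n, len(sensors), 3))
    gyro = np.empty((n, len(sensors), 3)) if config.with_gyro else None

    f0 = params.step_freq_hz
    ft = params.tremble_freq_hz
    # small per-trial frequency jitter keeps spectra from being needle-thin
    trem_phase = 2 * np.pi * ft * t

    for si, sensor in enumerate(sensors):
        if "right" in sensor:
            ph = phase0 + params.phase_left_right
        else:
            ph = phase0
        amp = params.locomotor_amp[sensor]
        walk = np.sin(2 * np.pi * f0 * t + ph) + 0.4 * np.sin(2 * (2 * np.pi * f0 * t + ph))
        is_leg = sensor in LEG_SENSORS
        if is_leg:
            trem_gain = params.tremble_amplitude
        else:
            trem_gain = 0.3 * params.tremble_amplitude if config.lumbar_carries_fog else 0.0
        if sensor == "lumbar" and not config.lumbar_carries_fog:
            # lumbar channel carries no FOG-related change at all
            locomotor_gain = np.ones(n)
            trem_env_here = np.zeros(n)
        else:
            locomotor_gain = 1.0 - 0.85 * env_trem - 0.95 * env_akin
            trem_env_here = env_trem
        trem = np.sin(trem_phase + ph * 0.5 + si)
        for ai in range(3):
            w = _AXIS_WEIGHTS[ai]
            sig = amp * w * locomotor_gain * walk + trem_gain * w * trem_env_here * trem
            sig = sig + rng.normal(0.0, params.noise_sd, n)
            accel[:, si, ai] = sig
        if gyro is not None:
            gamp = 0.3 * amp  # rad/s scale, well under the 20 rad/s artifact bound
            for ai in range(3):
                gyro[:, si, ai] = (
                    gamp * _AXIS_WEIGHTS[ai] * locomotor_gain
                    * np.cos(2 * np.pi * f0 * t + ph)
                    + rng.normal(0.0, 0.05, n)
                )

    return IMURecording(
        subject_id=schedule.subject_id,
        trial_id=schedule.trial_id,
        sample_rate_hz=fs,
        sensors=sensors,
        accel=accel,
        gyro=gyro,
    )


def inject_artifacts(
    recording: IMURecording, artifact_rate_per_min: float, seed: int
) -> tuple[IMURecording, list[float]]:
    """Insert isolated out-of-range spikes at Poisson times.

    Returns a modified copy plus the ground-truth spike times (seconds).
    Spikes exceed the 100 m/s^2 acceleration bound (and, when a gyroscope
    stream exists, the 20 rad/s angular-velocity bound) on one random sensor.
    """
    if artifact_rate_per_min < 0:
        raise ValidationError("artifact rate must be >= 0")
    if artifact_rate_per_min == 0:
        return recording, []
    rng = np.random.default_rng(seed)
    duration_min = recording.duration_s / 60.0
    count = int(rng.poisson(artifact_rate_per_min * duration_min))
    accel = recording.accel.copy()
    gyro = None if recording.gyro is None else recording.gyro.copy()
    times: list[float] = []
    fs = recording.sample_rate_hz
    for _ in range(count):
        i = int(rng.integers(0, recording.n_samples))
        si = int(rng.integers(0, len(recording.sensors)))
        ai = int(rng.integers(0, 3))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        accel[i, si, ai] = sign * rng.uniform(110.0, 150.0)
        if gyro is not None:
            gyro[i, si, ai] = sign * rng.uniform(22.0, 30.0)
        times.append(i / fs)
    out = IMURecording(
        subject_id=recording.subject_id,
        trial_id=recording.trial_id,
        sample_rate_hz=recording.sample_rate_hz,
        sensors=recording.sensors,
        accel=accel,
        gyro=gyro,
    )
    return out, sorted(times)


def simulate_trial(
    config: SimConfig, subject_index: int, trial_index: int
) -> tuple[IMURecording, AnnotationTrack, list[float]]:
    """Generate one (recording, annotation, artifact-times) triple in memory."""
    params = sample_subject_params(config, subject_index)
    subject_id = f"{config.subject_prefix}{subject_index:03d}"
    trial_id = f"T{trial_index:02d}"
    sched_seed = derive_seed(config.seed, "schedule", subject_index, trial_index)
    schedule = episode_schedule(
        config.trial_duration_s, params, sched_seed, subject_id, trial_id
    )
    rec_seed = derive_seed(config.seed, "signal", subject_index, trial_index)
    recording = synth_recording(params, schedule, config, rec_seed)
    art_seed = derive_seed(config.seed, "artifacts", subject_index, trial_index)
    recording, art_times = inject_artifacts(
        recording, config.artifact_rate_per_min, art_seed
    )
    return recording, schedule, art_times


def generate_cohort(config: SimConfig, out_dir: str | Path) -> CohortManifest:
    """Write a full cohort (recordings + annotations + manifest.json).

    Fully reproducible: two calls with the same config produce byte-identical
    files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    for subject_index in range(config.n_subjects):
        for trial_index in range(config.trials_per_subject):
            recording, schedule, _ = simulate_trial(config, subject_index, trial_index)
            stem = f"{recording.subject_id}_{recording.trial_id}"
            rec_path = out_dir / f"{stem}_imu.csv"
            ann_path = out_dir / f"{stem}_fog.csv"
            write_recording(recording, rec_path)
            write_annotations_or_empty(schedule, ann_path)
            entries.append(
                ManifestEntry(
                    subject_id=recording.subject_id,
                    trial_id=recording.trial_id,
                    recording_path=rec_path.name,
                    annotation_path=ann_path.name,
                    medication_state="off" if subject_index % 2 else "on",
                    role="train",
                )
            )
    manifest = CohortManifest(entries)
    write_manifest(manifest, out_dir / "manifest.json")
    # re-read so paths are absolute, matching read_manifest semantics
    for e in manifest.entries:
        e.recording_path = str(out_dir / e.recording_path)
        e.annotation_path = str(out_dir / e.annotation_path)
    return manifest


__all__ = [
    "SubjectParams",
    "SimConfig",
    "LEG_SENSORS",
    "derive_seed",
    "sample_subject_params",
    "episode_schedule",
    "synth_recording",
    "inject_artifacts",
    "simulate_trial",
    "generate_cohort",
]
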