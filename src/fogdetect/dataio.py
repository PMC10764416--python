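"""Data model and file formats for IMU cohorts.

A cohort is a set of subject-trial recordings plus freezing-of-gait (FOG)
interval annotations. Recordings are stored as self-describing CSV files with
a ``#``-prefixed metadata header (subject, trial, sampling rate, sensor list),
then one row per sample with columns ``<sensor>_<axis>`` — acceleration
columns first, then optional gyroscope columns. Annotations are plain CSV
interval tables (subject_id, trial_id, start_s, end_s); intervals are
half-open ``[start, end)`` in seconds, and sample ``i`` covers time
``[i/fs, (i+1)/fs)``. A manifest is a JSON list tying recordings and
annotations together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical body-location ordering used for every channel layout downstream.
SENSOR_ORDER: tuple[str, ...] = (
    "lumbar",
    "upper_leg_left",
    "upper_leg_right",
    "lower_leg_left",
    "lower_leg_right",
    "foot_left",
    "foot_right",
)

AXES: tuple[str, ...] = ("x", "y", "z")

VALID_SAMPLE_RATES: tuple[float, ...] = (60.0, 100.0)


class FormatError(ValueError):
    """A file does not follow the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates an invariant."""


def canonical_sensor_order(sensors: Sequence[str]) -> tuple[str, ...]:
    """Return *sensors* sorted into the canonical body-location order."""
    unknown = [s for s in sensors if s not in SENSOR_ORDER]
    if unknown:
        raise ValidationError(f"unknown sensor name(s): {unknown}")
    return tuple(s for s in SENSOR_ORDER if s in set(sensors))


@dataclass
class IMURecording:
    """One subject-trial multichannel sensor stream.

    ``accel`` has shape ``(n_samples, n_sensors, 3)`` in m/s^2, sensors in
    canonical order and axes ordered (x, y, z); ``gyro`` has the same shape
    in rad/s when present.
    """

    subject_id: str
    trial_id: str
    sample_rate_hz: float
    sensors: tuple[str, ...]
    accel: np.ndarray
    gyro: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sensors = tuple(self.sensors)
        self.accel = np.asarray(self.accel, dtype=np.float64)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=np.float64)
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(self.accel.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel_names(self) -> list[str]:
        return [f"{s}_{a}" for s in self.sensors for a in AXES]

    def validate(self) -> None:
        if not self.sensors:
            raise ValidationError("recording must have at least one sensor")
        if self.sensors != canonical_sensor_order(self.sensors):
            raise ValidationError(
                f"sensors must follow canonical order {SENSOR_ORDER}; got {self.sensors}"
            )
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.sample_rate_hz not in VALID_SAMPLE_RATES:
            raise ValidationError(
                f"sample_rate_hz must be one of {VALID_SAMPLE_RATES}, got {self.sample_rate_hz}"
            )
        expected = (self.accel.shape[0], len(self.sensors), 3)
        if self.accel.shape != expected:
            raise ValidationError(
                f"accel shape {self.accel.shape} does not match {expected}"
            )
        if not np.all(np.isfinite(self.accel)):
            raise ValidationError("accel contains non-finite values")
        if self.gyro is not None:
            if self.gyro.shape != expected:
                raise ValidationError(
                    f"gyro shape {self.gyro.shape} does not match {expected}"
                )
            if not np.all(np.isfinite(self.gyro)):
                raise ValidationError("gyro contains non-finite values")


@dataclass
class AnnotationTrack:
    """Sorted, non-overlapping half-open FOG intervals for one recording."""

    subject_id: str
    trial_id: str
    intervals: list[tuple[float, float]] = field(default_factory=list)
    label: str = "FOG"

    def __post_init__(self) -> None:
        self.intervals = [(float(a), float(b)) for a, b in self.intervals]
        self.validate()

    def validate(self) -> None:
        for start, end in self.intervals:
            if not (0.0 <= start < end):
                raise ValidationError(f"bad interval ({start}, {end}): need 0 <= start < end")
        for (_, e0), (s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValidationError("intervals overlap after sorting")

    def total_fog_s(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def sample_mask(self, sample_rate_hz: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample FOG mask; sample i is FOG iff its midpoint
        (i + 0.5)/fs lies inside an interval."""
        mid = (np.arange(n_samples) + 0.5) / sample_rate_hz
        mask = np.zeros(n_samples, dtype=bool)
        for start, end in self.intervals:
            mask |= (mid >= start) & (mid < end)
        return mask

    def clipped(self, duration_s: float) -> "AnnotationTrack":
        """Return a copy with intervals clipped to [0, duration_s)."""
        ivals = [
            (s, min(e, duration_s))
            for s, e in self.intervals
            if s < duration_s
        ]
        return AnnotationTrack(self.subject_id, self.trial_id, ivals, self.label)


@dataclass
class ManifestEntry:
    subject_id: str
    trial_id: str
    recording_path: str
    annotation_path: str
    medication_state: str = "on"
    role: str = "train"


@dataclass
class CohortManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.subject_id, e.trial_id) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (subject_id, trial_id) in manifest")

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.subject_id, None)
        return list(seen)

    def for_subjects(self, subjects: Sequence[str]) -> "CohortManifest":
        wanted = set(subjects)
        return CohortManifest([e for e in self.entries if e.subject_id in wanted])


# ---------------------------------------------------------------------------
# recording CSV


def write_recording(recording: IMURecording, path: str | Path) -> Path:
    """Serialize a recording at full float precision; round-trips exactly."""
    path = Path(path)
    recording.validate()
    cols = [f"{s}_{a}" for s in recording.sensors for a in AXES]
    mats = [recording.accel.reshape(recording.n_samples, -1)]
    if recording.gyro is not None:
        cols += [f"{s}_gyro_{a}" for s in recording.sensors for a in AXES]
        mats.append(recording.gyro.reshape(recording.n_samples, -1))
    data = np.hstack(mats)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject: {recording.subject_id}\n")
        fh.write(f"# trial: {recording.trial_id}\n")
        fh.write(f"# fs: {recording.sample_rate_hz:g}\n")
        fh.write(f"# sensors: {','.join(recording.sensors)}\n")
        fh.write(f"# gyro: {'yes' if recording.gyro is not None else 'no'}\n")
        fh.write(",".join(cols) + "\n")
        for row in data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    return path


def read_recording(path: str | Path) -> IMURecording:
    """Parse a recording CSV, reporting the offending line on format errors."""
    path = Path(path)
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if ":" not in body:
                raise FormatError(f"{path}:{n_meta}: malformed metadata line {line!r}")
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    for key in ("subject", "trial", "fs", "sensors"):
        if key not in meta:
            raise FormatError(f"{path}: missing metadata key '{key}' in header")
    try:
        fs = float(meta["fs"])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric fs {meta['fs']!r}") from exc
    sensors = tuple(s.strip() for s in meta["sensors"].split(",") if s.strip())
    for s in sensors:
        if s not in SENSOR_ORDER:
            raise ValidationError(f"{path}: unknown sensor name {s!r}")
    has_gyro = meta.get("gyro", "no").lower() in ("yes", "true", "1")

    try:
        df = pd.read_csv(path, comment="#", header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: inconsistent column count ({exc})") from exc

    n_chan = 3 * len(sensors)
    expected_cols = n_chan * (2 if has_gyro else 1)
    if df.shape[1] != expected_cols:
        raise FormatError(
            f"{path}: expected {expected_cols} data columns for {len(sensors)} "
            f"sensor(s) (gyro={'yes' if has_gyro else 'no'}), found {df.shape[1]}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.apply(pd.to_numeric, errors="coerce").isna().to_numpy()
        row = int(np.argwhere(bad)[0, 0])
        raise FormatError(
            f"{path}:{n_meta + 2 + row}: non-numeric cell in data row {row}"
        )
    if np.isnan(values).any():
        row = int(np.argwhere(np.isnan(values))[0, 0])
        raise FormatError(f"{path}:{n_meta + 2 + row}: NaN cell in data row {row}")

    n = values.shape[0]
    accel = values[:, :n_chan].reshape(n, len(sensors), 3)
    gyro = values[:, n_chan:].reshape(n, len(sensors), 3) if has_gyro else None
    return IMURecording(
        subject_id=meta["subject"],
        trial_id=meta["trial"],
        sample_rate_hz=fs,
        sensors=sensors,
        accel=accel,
        gyro=gyro,
    )


# ---------------------------------------------------------------------------
# annotation CSV


def merge_touching(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Sort intervals and merge any that touch or would otherwise be adjacent.

    Overlapping intervals (beyond touching) are a validation error: they
    indicate conflicting annotations rather than frame-boundary splits.
    """
    ivals = sorted((float(a), float(b)) for a, b in intervals)
    merged: list[tuple[float, float]] = []
    for start, end in ivals:
        if start >= end:
            raise ValidationError(f"bad interval ({start}, {end}): start >= end")
        if merged and start < merged[-1][1]:
            raise ValidationError(
                f"intervals {merged[-1]} and ({start}, {end}) overlap"
            )
        if merged and start == merged[-1][1]:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def write_annotations(track: AnnotationTrack, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": track.subject_id,
            "trial_id": track.trial_id,
            "start_s": [repr(s) for s, _ in track.intervals],
            "end_s": [repr(e) for _, e in track.intervals],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> AnnotationTrack:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "trial_id", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: annotation table needs columns {sorted(required)}"
        )
    if len(df) == 0:
        raise FormatError(f"{path}: empty annotation table (no identity row)")
    subject_id = str(df["subject_id"].iloc[0])
    trial_id = str(df["trial_id"].iloc[0])
    raw = list(zip(df["start_s"].astype(float), df["end_s"].astype(float)))
    # a single sentinel row with start == end == 0 encodes "no FOG"
    if len(raw) == 1 and raw[0][0] == 0.0 and raw[0][1] == 0.0:
        raw = []
    intervals = merge_touching(raw)
    return AnnotationTrack(subject_id, trial_id, intervals)


def write_annotations_or_empty(track: AnnotationTrack, path: str | Path) -> Path:
    """Like :func:`write_annotations` but writes a (0, 0) sentinel row when
    the track has no intervals, so the file still records its identity."""
    if track.intervals:
        return write_annotations(track, path)
    sentinel = AnnotationTrack.__new__(AnnotationTrack)
    sentinel.subject_id = track.subject_id
    sentinel.trial_id = track.trial_id
    sentinel.intervals = [(0.0, 0.0)]  # bypass validation for the sentinel
    sentinel.label = track.label
    return write_annotations(sentinel, path)


# ---------------------------------------------------------------------------
# manifest JSON


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "subject_id": e.subject_id,
            "trial_id": e.trial_id,
            "recording_path": e.recording_path,
            "annotation_path": e.annotation_path,
            "medication_state": e.medication_state,
            "role": e.role,
        }
        for e in manifest.entries
    ]
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    payload = json.loads(path.read_text())
    entries = [ManifestEntry(**item) for item in payload]
    # paths are stored relative to the manifest's directory
    base = path.parent
    for e in entries:
        e.recording_path = str((base / e.recording_path))
        e.annotation_path = str((base / e.annotation_path))
    for e in entries:
        if not Path(e.recording_path).exists():
            raise ValidationError(f"manifest points at missing file {e.recording_path}")
        if not Path(e.annotation_path).exists():
            raise ValidationError(f"manifest points at missing file {e.annotation_path}")
    return CohortManifest(entries)


__all__ = [
    "SENSOR_ORDER",
    "AXES",
    "FormatError",
    "ValidationError",
    "IMURecording",
    "AnnotationTrack",
    "ManifestEntry",
    "CohortManifest",
    "canonical_sensor_order",
    "merge_touching",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "write_annotations_or_empty",
    "read_manifest",
    "write_manifest",
]
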