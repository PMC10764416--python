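"""Epoching of cleaned recordings into labeled fixed-length windows.

Windows are 2 s (120 samples at 60 Hz) with 75 % overlap (0.5 s step). A
window whose FOG fraction rho is >= 25 % is positive; rho == 0 is negative;
0 < rho < 25 % is ambiguous and excluded from training (and, by default,
from evaluation as well — configurable). Windows touching any
artifact-masked sample are dropped outright so every window is exactly
120 x C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataio import (
    AnnotationTrack,
    CohortManifest,
    ValidationError,
    canonical_sensor_order,
    read_annotations,
    read_recording,
)
from .preprocess import CleanRecording, preprocess_recording

WINDOW_S = 2.0
OVERLAP = 0.75
SAMPLES_PER_WINDOW = 120  # 2 s at 60 Hz
STEP_SAMPLES = 30  # 0.5 s at 60 Hz

POS = "POS"
NEG = "NEG"
DISCARD = "DISCARD"

FOG_FRACTION_THRESHOLD = 0.25  # >= 25 % FOG labels a window positive

#: the five named sensor configurations evaluated in the ablation
SENSOR_CONFIGS: dict[str, tuple[str, ...]] = {
    "seven": (
        "lumbar",
        "upper_leg_left",
        "upper_leg_right",
        "lower_leg_left",
        "lower_leg_right",
        "foot_left",
        "foot_right",
    ),
    "six_legs_feet": (
        "upper_leg_left",
        "upper_leg_right",
        "lower_leg_left",
        "lower_leg_right",
        "foot_left",
        "foot_right",
    ),
    "lower_legs": ("lower_leg_left", "lower_leg_right"),
    "lumbar": ("lumbar",),
    "right_foot": ("foot_right",),
}


@dataclass
class Window:
    """One labeled 2-s epoch with provenance."""

    data: np.ndarray  # (120, C)
    subject_id: str
    trial_id: str
    start_s: float
    fog_fraction: float
    label: str


@dataclass
class WindowDataset:
    """Columnar container of labeled windows sharing one channel layout."""

    X: np.ndarray  # (N, 120, C) float32
    fog_fraction: np.ndarray  # (N,)
    labels: np.ndarray  # (N,) of {POS, NEG, DISCARD}
    subject_ids: np.ndarray  # (N,) str
    trial_ids: np.ndarray  # (N,) str
    start_s: np.ndarray  # (N,)
    channel_names: tuple[str, ...]
    role: str = "train"

    def __len__(self) -> int:
        return int(self.X.shape[0])

    def __getitem__(self, i: int) -> Window:
        return Window(
            data=self.X[i],
            subject_id=str(self.subject_ids[i]),
            trial_id=str(self.trial_ids[i]),
            start_s=float(self.start_s[i]),
            fog_fraction=float(self.fog_fraction[i]),
            label=str(self.labels[i]),
        )

    @property
    def n_channels(self) -> int:
        return int(self.X.shape[2])

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        out = {POS: 0, NEG: 0, DISCARD: 0}
        out.update(dict(zip(labels.tolist(), counts.tolist())))
        return out

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(str(s), None)
        return list(seen)

    def select(self, idx: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            X=self.X[idx],
            fog_fraction=self.fog_fraction[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            trial_ids=self.trial_ids[idx],
            start_s=self.start_s[idx],
            channel_names=self.channel_names,
            role=self.role,
        )

    def scorable(self, include_partial_as_neg: bool = False) -> "WindowDataset":
        """Windows usable for training/scoring: POS and NEG only by default;
        optionally re-label the ambiguous 0 < rho < 25 % windows as NEG."""
        if include_partial_as_neg:
            out = self.select(np.arange(len(self)))
            out.labels = np.where(out.labels == DISCARD, NEG, out.labels)
            return out
        return self.select(np.flatnonzero(self.labels != DISCARD))

    def y(self) -> np.ndarray:
        """Binary target vector; raises if any DISCARD windows remain."""
        if np.any(self.labels == DISCARD):
            raise ValidationError("DISCARD windows must be filtered before training")
        return (self.labels == POS).astype(np.float64)

    def restrict_channels(self, sensors: Sequence[str]) -> "WindowDataset":
        """Keep only the channels of the given sensors (canonical order)."""
        sensors = canonical_sensor_order(sensors)
        wanted = [f"{s}_{a}" for s in sensors for a in ("x", "y", "z")]
        name_to_col = {n: i for i, n in enumerate(self.channel_names)}
        missing = [n for n in wanted if n not in name_to_col]
        if missing:
            raise ValidationError(f"requested channels not present: {missing}")
        cols = [name_to_col[n] for n in wanted]
        out = self.select(np.arange(len(self)))
        out.X = np.ascontiguousarray(self.X[:, :, cols])
        out.channel_names = tuple(wanted)
        return out


def expected_window_count(n_samples: int) -> int:
    """floor((L - 120)/30) + 1 for an unmasked stream of L >= 120 samples."""
    if n_samples < SAMPLES_PER_WINDOW:
        return 0
    return (n_samples - SAMPLES_PER_WINDOW) // STEP_SAMPLES + 1


def segment(
    clean: CleanRecording,
    window_s: float = WINDOW_S,
    overlap: float = OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a cleaned 60 Hz stream into overlapping windows.

    Returns ``(starts, windows)`` where ``starts`` are sample indices and
    ``windows`` has shape (N, n_window, C). Windows covering any
    artifact-masked sample are dropped.
    """
    if clean.sample_rate_hz != 60.0:
        raise ValidationError("segment expects a 60 Hz CleanRecording")
    n_window = int(round(window_s * clean.sample_rate_hz))
    step = int(round(n_window * (1.0 - overlap)))
    if step <= 0:
        raise ValidationError("overlap too large: step would be zero")
    L = clean.n_samples
    if L < n_window:
        C = 3 * len(clean.sensors)
        return np.empty(0, dtype=np.int64), np.empty((0, n_window, C))
    starts = np.arange(0, L - n_window + 1, step, dtype=np.int64)
    flat = clean.channel_matrix()
    windows = np.stack([flat[s : s + n_window] for s in starts])
    if clean.artifact_mask.any():
        bad = np.cumsum(np.concatenate(([0], clean.artifact_mask.astype(np.int64))))
        touched = (bad[starts + n_window] - bad[starts]) > 0
        starts, windows = starts[~touched], windows[~touched]
    return starts, windows


def label_from_fraction(rho: float, role: str = "train") -> str:
    """Apply the >=25 % rule: POS at or above threshold, NEG at exactly zero,
    DISCARD in between (for every role by default; evaluation callers may
    re-score DISCARD as NEG via WindowDataset.scorable)."""
    if not (0.0 <= rho <= 1.0):
        raise ValidationError(f"fog fraction {rho} outside [0, 1]")
    if rho >= FOG_FRACTION_THRESHOLD:
        return POS
    if rho == 0.0:
        return NEG
    return DISCARD


def windows_from_clean(
    clean: CleanRecording,
    annotations: AnnotationTrack,
    role: str = "train",
) -> WindowDataset:
    """Segment one cleaned recording and label windows from the annotation
    sample mask."""
    starts, X = segment(clean)
    fog_mask = annotations.sample_mask(clean.sample_rate_hz, clean.n_samples)
    cum = np.cumsum(np.concatenate(([0], fog_mask.astype(np.int64))))
    if len(starts):
        rho = (cum[starts + SAMPLES_PER_WINDOW] - cum[starts]) / SAMPLES_PER_WINDOW
    else:
        rho = np.empty(0)
    labels = np.array([label_from_fraction(float(r), role) for r in rho], dtype=object)
    n = len(starts)
    return WindowDataset(
        X=X.astype(np.float32),
        fog_fraction=rho,
        labels=labels.astype(str) if n else np.empty(0, dtype=str),
        subject_ids=np.full(n, clean.subject_id, dtype=object),
        trial_ids=np.full(n, clean.trial_id, dtype=object),
        start_s=starts / clean.sample_rate_hz,
        channel_names=tuple(clean.channel_names()),
        role=role,
    )


def resolve_sensor_config(sensor_config: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(sensor_config, str):
        if sensor_config not in SENSOR_CONFIGS:
            raise ValidationError(
                f"unknown sensor configuration {sensor_config!r}; "
                f"choose from {sorted(SENSOR_CONFIGS)} or pass an explicit list"
            )
        return SENSOR_CONFIGS[sensor_config]
    return canonical_sensor_order(sensor_config)


def concat_datasets(parts: Sequence[WindowDataset], role: str) -> WindowDataset:
    parts = [p for p in parts if len(p)]
    if not parts:
        raise ValidationError("no windows produced for this dataset")
    names = parts[0].channel_names
    for p in parts:
        if p.channel_names != names:
            raise ValidationError("cannot concatenate datasets with different channels")
    return WindowDataset(
        X=np.concatenate([p.X for p in parts]),
        fog_fraction=np.concatenate([p.fog_fraction for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        trial_ids=np.concatenate([p.trial_ids for p in parts]),
        start_s=np.concatenate([p.start_s for p in parts]),
        channel_names=names,
        role=role,
    )


def assemble_dataset(
    manifest: CohortManifest,
    sensor_config: str | Sequence[str] = "seven",
    role: str = "train",
) -> WindowDataset:
    """Load, preprocess, window and label every trial in a manifest,
    restricted to the requested sensor configuration."""
    sensors = resolve_sensor_config(sensor_config)
    parts: list[WindowDataset] = []
    for entry in manifest.entries:
        recording = read_recording(entry.recording_path)
        missing = [s for s in sensors if s not in recording.sensors]
        if missing:
            raise ValidationError(
                f"recording {entry.subject_id}/{entry.trial_id} lacks sensors {missing}"
            )
        annotations = read_annotations(entry.annotation_path)
        clean = preprocess_recording(recording)
        ds = windows_from_clean(clean, annotations, role)
        parts.append(ds.restrict_channels(sensors) if len(ds) else ds)
    return concat_datasets(parts, role)


def save_dataset(dataset: WindowDataset, path) -> None:
    """Persist as a compressed array container plus inline metadata."""
    np.savez_compressed(
        path,
        X=dataset.X,
        fog_fraction=dataset.fog_fraction,
        labels=dataset.labels.astype(str),
        subject_ids=dataset.subject_ids.astype(str),
        trial_ids=dataset.trial_ids.astype(str),
        start_s=dataset.start_s,
        channel_names=np.array(dataset.channel_names, dtype=str),
        role=np.array(dataset.role, dtype=str),
    )


def load_dataset(path) -> WindowDataset:
    with np.load(path, allow_pickle=False) as z:
        return WindowDataset(
            X=z["X"],
            fog_fraction=z["fog_fraction"],
            labels=z["labels"].astype(object),
            subject_ids=z["subject_ids"].astype(object),
            trial_ids=z["trial_ids"].astype(object),
            start_s=z["start_s"],
            channel_names=tuple(z["channel_names"].tolist()),
            role=str(z["role"]),
        )


__all__ = [
    "WINDOW_S",
    "OVERLAP",
    "SAMPLES_PER_WINDOW",
    "STEP_SAMPLES",
    "POS",
    "NEG",
    "DISCARD",
    "FOG_FRACTION_THRESHOLD",
    "SENSOR_CONFIGS",
    "Window",
    "WindowDataset",
    "expected_window_count",
    "segment",
    "label_from_fraction",
    "windows_from_clean",
    "resolve_sensor_config",
    "concat_datasets",
    "assemble_dataset",
    "save_dataset",
    "load_dataset",
]
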