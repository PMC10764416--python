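"""Signal conditioning for raw IMU recordings.

Order of operations: artifact detection on the raw stream (spikes would be
shrunk by filtering), zero-phase band-pass filtering, then standardization to
60 Hz. Artifacts are *masked*, not spliced out, so window timing stays
aligned with the annotation clock; downstream windowing drops any window that
touches a masked sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dataio import IMURecording, ValidationError

#: acceleration magnitude above which a sample is an artifact, m/s^2
ACCEL_ARTIFACT_THRESHOLD = 100.0
#: angular-velocity magnitude above which a sample is an artifact, rad/s
GYRO_ARTIFACT_THRESHOLD = 20.0
#: guard dilation applied around every artifact sample, seconds
ARTIFACT_GUARD_S = 0.25

#: band-pass corner frequencies, Hz
BAND_LOW_HZ = 0.3
BAND_HIGH_HZ = 15.0
FILTER_ORDER = 3

TARGET_RATE_HZ = 60.0


@dataclass
class CleanRecording:
    """A conditioned recording: 60 Hz, band-passed acceleration only, plus a
    per-sample artifact mask. No masked sample may enter a downstream window."""

    subject_id: str
    trial_id: str
    sensors: tuple[str, ...]
    accel: np.ndarray  # (n_samples, n_sensors, 3)
    artifact_mask: np.ndarray  # (n_samples,), True where unusable
    sample_rate_hz: float = TARGET_RATE_HZ

    @property
    def n_samples(self) -> int:
        return int(self.accel.shape[0])

    def channel_matrix(self) -> np.ndarray:
        """(n_samples, 3 * n_sensors) view in canonical channel order."""
        return self.accel.reshape(self.n_samples, -1)

    def channel_names(self) -> list[str]:
        return [f"{s}_{a}" for s in self.sensors for a in ("x", "y", "z")]


def detect_artifacts(
    recording: IMURecording,
    accel_threshold: float = ACCEL_ARTIFACT_THRESHOLD,
    gyro_threshold: float = GYRO_ARTIFACT_THRESHOLD,
    guard_s: float = ARTIFACT_GUARD_S,
    per_axis: bool = False,
) -> np.ndarray:
    """Flag samples whose 3-axis norm (default) or any single axis exceeds
    the plausible-motion bounds, then dilate by ``guard_s`` on both sides."""
    if per_axis:
        over = np.any(np.abs(recording.accel) > accel_threshold, axis=(1, 2))
        if recording.gyro is not None:
            over |= np.any(np.abs(recording.gyro) > gyro_threshold, axis=(1, 2))
    else:
        norms = np.linalg.norm(recording.accel, axis=2)  # (n, n_sensors)
        over = np.any(norms > accel_threshold, axis=1)
        if recording.gyro is not None:
            gnorms = np.linalg.norm(recording.gyro, axis=2)
            over |= np.any(gnorms > gyro_threshold, axis=1)
    if not over.any():
        return over
    guard = int(round(guard_s * recording.sample_rate_hz))
    if guard == 0:
        return over
    # dilation via cumulative trick: mark [i-guard, i+guard] for each flag
    mask = np.zeros(recording.n_samples + 1, dtype=np.int64)
    idx = np.flatnonzero(over)
    lo = np.clip(idx - guard, 0, None)
    hi = np.clip(idx + guard + 1, None, recording.n_samples)
    np.add.at(mask, lo, 1)
    np.add.at(mask, hi, -1)
    return np.cumsum(mask[:-1]) > 0


def butter_sos(fs: float) -> np.ndarray:
    """Third-order Butterworth band-pass (0.3-15 Hz) in second-order sections."""
    return sps.butter(
        FILTER_ORDER, [BAND_LOW_HZ, BAND_HIGH_HZ], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(x: np.ndarray, fs: float, axis: int = 0) -> np.ndarray:
    """Zero-phase (forward-backward) band-pass; length-preserving.

    The causal filter is third order; the forward-backward pass doubles the
    magnitude response (effective 6th order) and cancels the phase. Edge
    transients are reduced by odd-reflection padding.
    """
    x = np.asarray(x, dtype=np.float64)
    if fs <= 30.0:
        raise ValidationError("bandpass requires fs > 30 Hz")
    min_len = 3 * (2 * FILTER_ORDER + 1)
    if x.shape[axis] <= min_len:
        raise ValidationError(
            f"signal too short for zero-phase filtering: need > {min_len} samples"
        )
    sos = butter_sos(fs)
    return sps.sosfiltfilt(sos, x, axis=axis, padtype="odd")


def resample_to_60(x: np.ndarray, fs: float, axis: int = 0) -> np.ndarray:
    """Standardize the sampling rate to 60 Hz.

    60 Hz input is returned unchanged; 100 Hz input is polyphase-resampled by
    the rational factor 3/5 (500 samples -> 300). Other rates are rejected.
    """
    x = np.asarray(x, dtype=np.float64)
    if fs == 60.0:
        return x
    if fs == 100.0:
        return sps.resample_poly(x, 3, 5, axis=axis)
    raise ValidationError(f"unsupported sample rate {fs}; expected 60 or 100 Hz")


def resample_mask_to_60(mask: np.ndarray, fs: float) -> np.ndarray:
    """Map a per-sample boolean mask to the 60 Hz clock by logical OR over
    the source samples that contribute to each output sample."""
    mask = np.asarray(mask, dtype=bool)
    if fs == 60.0:
        return mask.copy()
    if fs != 100.0:
        raise ValidationError(f"unsupported sample rate {fs}")
    n_out = int(np.ceil(mask.shape[0] * 3 / 5))
    out = np.zeros(n_out, dtype=bool)
    target = (np.arange(mask.shape[0]) * 3) // 5
    np.logical_or.at(out, target, mask)
    return out


def preprocess_recording(recording: IMURecording, per_axis: bool = False) -> CleanRecording:
    """Full conditioning chain: artifacts (raw) -> band-pass -> 60 Hz."""
    mask = detect_artifacts(recording, per_axis=per_axis)
    flat = recording.accel.reshape(recording.n_samples, -1)
    filtered = bandpass(flat, recording.sample_rate_hz, axis=0)
    resampled = resample_to_60(filtered, recording.sample_rate_hz, axis=0)
    mask60 = resample_mask_to_60(mask, recording.sample_rate_hz)
    n = resampled.shape[0]
    if mask60.shape[0] != n:  # defensive: resample_poly length bookkeeping
        fixed = np.zeros(n, dtype=bool)
        m = min(n, mask60.shape[0])
        fixed[:m] = mask60[:m]
        mask60 = fixed
    return CleanRecording(
        subject_id=recording.subject_id,
        trial_id=recording.trial_id,
        sensors=recording.sensors,
        accel=resampled.reshape(n, len(recording.sensors), 3),
        artifact_mask=mask60,
    )


__all__ = [
    "ACCEL_ARTIFACT_THRESHOLD",
    "GYRO_ARTIFACT_THRESHOLD",
    "ARTIFACT_GUARD_S",
    "BAND_LOW_HZ",
    "BAND_HIGH_HZ",
    "FILTER_ORDER",
    "TARGET_RATE_HZ",
    "CleanRecording",
    "detect_artifacts",
    "butter_sos",
    "bandpass",
    "resample_to_60",
    "resample_mask_to_60",
    "preprocess_recording",
]
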