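import numpy as np
import pytest

from fogdetect.gaitsim import SimConfig, generate_cohort
from fogdetect.windowing import WindowDataset, assemble_dataset


@pytest.fixture(scope="session")
def seven_sensor_manifest(tmp_path_factory):
    """Small seven-sensor cohort with gyro and occasional artifact spikes."""
    out = tmp_path_factory.mktemp("cohort7")
    config = SimConfig(
        n_subjects=6,
        trial_duration_s=120.0,
        artifact_rate_per_min=0.5,
        with_gyro=True,
        seed=21,
    )
    return generate_cohort(config, out)


@pytest.fixture(scope="session")
def seven_sensor_dataset(seven_sensor_manifest):
    return assemble_dataset(seven_sensor_manifest, "seven", role="train")


@pytest.fixture(scope="session")
def trembling_manifest(tmp_path_factory):
    """Lower-leg-only trembling-phenotype cohort: cleanly learnable."""
    out = tmp_path_factory.mktemp("cohort_legs")
    config = SimConfig(
        n_subjects=8,
        trial_duration_s=180.0,
        sensors=("lower_leg_left", "lower_leg_right"),
        akinetic_prob=0.0,
        seed=11,
    )
    return generate_cohort(config, out)


@pytest.fixture(scope="session")
def trembling_dataset(trembling_manifest):
    return assemble_dataset(trembling_manifest, "lower_legs", role="train")


@pytest.fixture(scope="session")
def train_val_split(trembling_dataset):
    """Grouped train/validation split of the trembling cohort (6/2 subjects)."""
    ds = trembling_dataset
    subjects = ds.subjects()
    tr = np.isin(ds.subject_ids.astype(str), subjects[:6])
    train = ds.select(np.flatnonzero(tr)).scorable()
    val = ds.select(np.flatnonzero(~tr)).scorable()
    return train, val


def make_dataset(X: np.ndarray, y: np.ndarray, subjects=None) -> WindowDataset:
    """Assemble a WindowDataset directly from arrays (test helper)."""
    n = len(y)
    labels = np.where(np.asarray(y) == 1, "POS", "NEG").astype(object)
    n_sensors = X.shape[2] // 3
    names = tuple(
        f"{s}_{a}"
        for s in ("lower_leg_left", "lower_leg_right", "lumbar", "foot_right")[:n_sensors]
        for a in "xyz"
    )
    if subjects is None:
        subjects = np.array(["s0"] * n, dtype=object)
    return WindowDataset(
        X=X.astype(np.float32),
        fog_fraction=np.asarray(y, dtype=float),
        labels=labels,
        subject_ids=np.asarray(subjects, dtype=object),
        trial_ids=np.array(["t0"] * n, dtype=object),
        start_s=np.zeros(n),
        channel_names=names,
    )
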