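#!/usr/bin/env python
"""Sensor-placement ablation with paired subject-grouped folds.

Evaluates the five sensor configurations (all seven; six leg/feet; lower
legs; lumbar only; right foot only) with the CNN, reusing one fold
assignment so the comparison is paired. Writes the ablation table and the
selected configuration (ties break toward fewer sensors) to results/.

Run analysis/01 and 02 first.
"""

from pathlib import Path

import numpy as np

from fogdetect.evaluate import (
    grouped_kfold,
    holdout_split,
    run_sensor_ablation,
    select_configuration,
    subject_fog_percent,
)
from fogdetect.models import CNNConfig, train_cnn
from fogdetect.windowing import load_dataset

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 7


def main() -> None:
    ds = load_dataset(SCRATCH / "windows_cohort.npz")
    split = holdout_split(subject_fog_percent(ds), 0.2, seed=SEED)
    train = ds.select(
        np.flatnonzero(np.isin(ds.subject_ids.astype(str), split.train_subjects))
    )
    folds = grouped_kfold(train.subjects(), k=5, seed=SEED)
    table, _ = run_sensor_ablation(
        train, lambda d: train_cnn(d, CNNConfig(epochs=10, seed=SEED)), folds
    )
    print(table.to_string(index=False))
    chosen = select_configuration(table)
    print(f"selected configuration: {chosen}")
    table.to_csv(RESULTS / "sensor_ablation.csv", index=False)
    (RESULTS / "selected_configuration.txt").write_text(chosen + "\n")
    print(f"wrote {RESULTS / 'sensor_ablation.csv'}")


if __name__ == "__main__":
    main()
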