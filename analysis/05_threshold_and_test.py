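#!/usr/bin/env python
"""Select the operating threshold and score the frozen model on both test sets.

Re-runs the cross-validation of the selected configuration to pool
out-of-fold predictions, picks the threshold maximizing the geometric mean
sqrt(sensitivity x specificity), retrains on the full training split, and
evaluates once on the hold-out subjects and once on the unseen cohort.
Writes the final metrics to results/final_metrics.json.

Run analysis/01, 02 and 04 first.
"""

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from fogdetect.evaluate import (
    assert_no_subject_leakage,
    confusion_metrics,
    cross_validate,
    gmean_threshold,
    grouped_kfold,
    holdout_split,
    subject_fog_percent,
)
from fogdetect.models import CNNConfig, train_cnn
from fogdetect.windowing import SENSOR_CONFIGS, load_dataset

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 7


def main() -> None:
    ds = load_dataset(SCRATCH / "windows_cohort.npz")
    unseen = load_dataset(SCRATCH / "windows_unseen.npz")
    chosen = (RESULTS / "selected_configuration.txt").read_text().strip()
    sensors = SENSOR_CONFIGS[chosen]
    print(f"configuration: {chosen} ({3 * len(sensors)} channels)")

    split = holdout_split(subject_fog_percent(ds), 0.2, seed=SEED)
    in_train = np.isin(ds.subject_ids.astype(str), split.train_subjects)
    train = ds.select(np.flatnonzero(in_train)).restrict_channels(sensors)
    holdout = ds.select(np.flatnonzero(~in_train)).restrict_channels(sensors)
    unseen = unseen.restrict_channels(sensors)
    assert_no_subject_leakage(train, holdout)

    folds = grouped_kfold(train.subjects(), k=5, seed=SEED)
    trainer = lambda d: train_cnn(d, CNNConfig(epochs=10, seed=SEED))
    cv = cross_validate(train, trainer, folds)
    choice = gmean_threshold(cv.pooled_labels, cv.pooled_probabilities)
    print(
        f"threshold {choice.threshold:.3f} "
        f"(g-mean {choice.gmean:.3f}, CV sens {choice.sensitivity:.2f} / "
        f"spec {choice.specificity:.2f})"
    )

    model = trainer(train.scorable())
    report = {"configuration": chosen, "threshold": asdict(choice)}
    for name, eval_ds in (("holdout", holdout), ("unseen", unseen)):
        scorable = eval_ds.scorable()
        p = model.predict_dataset(scorable)
        m = confusion_metrics(scorable.y(), p, choice.threshold)
        report[name] = asdict(m)
        print(
            f"{name}: AUC {m.auc:.3f}, sensitivity {m.sensitivity:.2f}, "
            f"specificity {m.specificity:.2f}, precision {m.precision:.2f}, "
            f"F-score {m.f_score:.2f}"
        )
    (RESULTS / "final_metrics.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    print(f"wrote {RESULTS / 'final_metrics.json'}")


if __name__ == "__main__":
    main()
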