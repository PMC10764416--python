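#!/usr/bin/env python
"""Compare the three classifier families with subject-grouped five-fold CV.

Trains the CNN, InceptionTime and MiniRocket on the seven-sensor training
windows (80 % subject split; the hold-out 20 % is untouched here), reports
the mean ROC AUC +/- SD across folds for each family, and writes the
comparison table to results/. Desk-scale training settings: the cohort is
two orders of magnitude smaller than a clinical study, so InceptionTime
runs with a thinner ensemble than its published default to keep this script
in the minutes range.

Run analysis/01 and 02 first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fogdetect.evaluate import cross_validate, grouped_kfold, holdout_split, subject_fog_percent
from fogdetect.models import (
    CNNConfig,
    InceptionConfig,
    MiniRocketConfig,
    train_cnn,
    train_inceptiontime,
    train_minirocket,
    train_spectral_baseline,
)
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
    print(
        f"{len(split.train_subjects)} training subjects, "
        f"{len(split.holdout_subjects)} held out"
    )
    folds = grouped_kfold(train.subjects(), k=5, seed=SEED)
    # InceptionTime is the costliest family on one CPU; it trains on a
    # stride-2 thinning of each fold with a 2-network ensemble and reduced
    # widths — enough to rank the families on this cleanly separable cohort.
    def train_inception_thin(d):
        thin = d.select(np.arange(0, len(d), 2))
        return train_inceptiontime(
            thin,
            InceptionConfig(n_ensemble=2, bottleneck=8, filters=8,
                            epochs=5, seed=SEED),
        )

    trainers = {
        "cnn": lambda d: train_cnn(d, CNNConfig(seed=SEED)),
        "inceptiontime": train_inception_thin,
        "minirocket": lambda d: train_minirocket(d, MiniRocketConfig(seed=SEED)),
        "spectral_baseline": train_spectral_baseline,
    }
    rows = []
    for family, trainer in trainers.items():
        cv = cross_validate(train, trainer, folds)
        rows.append(
            {
                "family": family,
                "mean_auc": cv.roc.mean_auc,
                "sd_auc": cv.roc.sd_auc,
                "fold_aucs": ";".join(f"{a:.3f}" for a in cv.roc.aucs),
            }
        )
        print(f"{family}: mean CV AUC {cv.roc.mean_auc:.3f} +/- {cv.roc.sd_auc:.3f}")
    table = pd.DataFrame(rows).sort_values("mean_auc", ascending=False)
    table.to_csv(RESULTS / "family_comparison.csv", index=False)
    print(f"best family: {table.iloc[0]['family']}")
    print(f"wrote {RESULTS / 'family_comparison.csv'}")


if __name__ == "__main__":
    main()
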