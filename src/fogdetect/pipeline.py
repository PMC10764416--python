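"""End-to-end experiment orchestration.

``run_experiment`` reproduces the full procedure on a synthetic cohort:
simulate -> preprocess -> window -> train the three families with
subject-grouped five-fold CV on all seven sensors -> select the family with
the highest mean CV AUC -> ablate sensor configurations with the selected
family (paired folds) -> select the configuration (ties toward fewer
sensors) -> choose the operating threshold by the maximum geometric mean on
the pooled CV predictions -> retrain on the full training split and score
once on the hold-out subjects and once on an unseen cohort with the frozen
threshold.

A single global seed is fanned out to per-stage seeds by hashing the stage
name, so each stage can be rerun in isolation; the emitted report is a
deterministic (byte-identical) function of the configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
import numpy as np

from . import __version__
from .dataio import ValidationError
from .evaluate import (
    CVResult,
    confusion_metrics,
    cross_validate,
    gmean_threshold,
    grouped_kfold,
    holdout_split,
    run_sensor_ablation,
    select_configuration,
    subject_fog_percent,
)
from .gaitsim import SimConfig, derive_seed, generate_cohort
from .models import (
    CNNConfig,
    InceptionConfig,
    MiniRocketConfig,
    train_cnn,
    train_inceptiontime,
    train_minirocket,
)
from .windowing import assemble_dataset

DEFAULT_CONFIGS: tuple[str, ...] = (
    "seven",
    "six_legs_feet",
    "lower_legs",
    "lumbar",
    "right_foot",
)


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; every stated training constant defaults
    to the published protocol, cohort sizes default to desk scale."""

    sim: SimConfig = field(default_factory=lambda: SimConfig(n_subjects=20, trial_duration_s=360.0))
    n_unseen_subjects: int = 5
    unseen_duration_s: float = 300.0
    cnn: CNNConfig = field(default_factory=CNNConfig)
    inception: InceptionConfig = field(default_factory=InceptionConfig)
    minirocket: MiniRocketConfig = field(default_factory=MiniRocketConfig)
    families: tuple[str, ...] = ("cnn", "inceptiontime", "minirocket")
    sensor_configs: tuple[str, ...] = DEFAULT_CONFIGS
    k_folds: int = 5
    holdout_fraction: float = 0.2
    seed: int = 0
    out_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, "stage", stage)


def _trainer(family: str, config: ExperimentConfig, seed: int):
    if family == "cnn":
        cfg = replace(config.cnn, seed=seed)
        return lambda ds: train_cnn(ds, cfg)
    if family == "inceptiontime":
        cfg = replace(config.inception, seed=seed)
        return lambda ds: train_inceptiontime(ds, cfg)
    if family == "minirocket":
        cfg = replace(config.minirocket, seed=seed)
        return lambda ds: train_minirocket(ds, cfg)
    raise ValidationError(f"unknown model family {family!r}")


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_experiment(config: ExperimentConfig, work_dir: str | Path | None = None) -> dict:
    """Execute the full chain and return the experiment report (JSON-ready)."""
    import tempfile

    if work_dir is None and config.out_dir is None:
        tmp = tempfile.TemporaryDirectory()
        work_dir = tmp.name
    else:
        tmp = None
        work_dir = Path(work_dir or config.out_dir)
    work_dir = Path(work_dir)

    try:
        # --- simulate -----------------------------------------------------
        sim = replace(config.sim, seed=config.stage_seed("simulate"))
        manifest = generate_cohort(sim, work_dir / "cohort")
        unseen_sim = replace(
            sim,
            n_subjects=config.n_unseen_subjects,
            trial_duration_s=config.unseen_duration_s,
            seed=config.stage_seed("simulate-unseen"),
            subject_prefix="U",
        )
        unseen_manifest = generate_cohort(unseen_sim, work_dir / "unseen")

        # --- preprocess + window (all seven sensors once) -----------------
        dataset = assemble_dataset(manifest, "seven", role="train")
        unseen_ds = assemble_dataset(unseen_manifest, "seven", role="unseen")

        # --- 80/20 subject split stratified by FOG occurrence -------------
        fog_pct = subject_fog_percent(dataset)
        split = holdout_split(
            fog_pct, config.holdout_fraction, config.stage_seed("holdout")
        )
        tr_mask = np.isin(dataset.subject_ids.astype(str), split.train_subjects)
        train_all = dataset.select(np.flatnonzero(tr_mask))
        holdout_all = dataset.select(np.flatnonzero(~tr_mask))

        # --- family comparison at seven sensors ---------------------------
        folds = grouped_kfold(
            train_all.subjects(), config.k_folds, config.stage_seed("folds")
        )
        family_cv: dict[str, CVResult] = {}
        for family in config.families:
            trainer = _trainer(family, config, config.stage_seed(f"train-{family}"))
            family_cv[family] = cross_validate(train_all, trainer, folds)
        selected_family = max(
            config.families, key=lambda f: family_cv[f].roc.mean_auc
        )

        # --- sensor ablation with the selected family (paired folds) ------
        trainer = _trainer(
            selected_family, config, config.stage_seed(f"ablate-{selected_family}")
        )
        ablation_table, ablation_cv = run_sensor_ablation(
            train_all, trainer, folds, config.sensor_configs
        )
        selected_config = select_configuration(ablation_table)

        # --- threshold from pooled CV predictions of the selected config --
        sel_cv = ablation_cv[selected_config]
        choice = gmean_threshold(sel_cv.pooled_labels, sel_cv.pooled_probabilities)

        # --- freeze: retrain on all training subjects, score test sets ----
        from .windowing import SENSOR_CONFIGS

        sensors = SENSOR_CONFIGS[selected_config]
        final_trainer = _trainer(
            selected_family, config, config.stage_seed("final-fit")
        )
        final_train = train_all.restrict_channels(sensors).scorable()
        final_model = final_trainer(final_train)

        def score(ds):
            sub = ds.restrict_channels(sensors).scorable()
            p = final_model.predict_dataset(sub)
            return confusion_metrics(sub.y(), p, choice.threshold)

        holdout_metrics = score(holdout_all)
        unseen_metrics = score(unseen_ds)

        report = {
            "software_version": __version__,
            "seed": config.seed,
            "config": _round_floats(asdict(config)),
            "cohort": {
                "n_subjects": sim.n_subjects,
                "n_train_subjects": len(split.train_subjects),
                "n_holdout_subjects": len(split.holdout_subjects),
                "n_unseen_subjects": unseen_sim.n_subjects,
                "n_windows_train": len(train_all),
                "n_windows_holdout": len(holdout_all),
                "n_windows_unseen": len(unseen_ds),
                "train_subjects": list(split.train_subjects),
                "holdout_subjects": list(split.holdout_subjects),
            },
            "families": {
                f: {
                    "mean_auc": round(cv.roc.mean_auc, 6),
                    "sd_auc": round(cv.roc.sd_auc, 6),
                    "fold_aucs": [round(a, 6) for a in cv.roc.aucs.tolist()],
                }
                for f, cv in family_cv.items()
            },
            "selected_family": selected_family,
            "ablation": _round_floats(ablation_table.to_dict(orient="records")),
            "selected_configuration": selected_config,
            "threshold": _round_floats(asdict(choice)),
            "holdout": _round_floats(asdict(holdout_metrics)),
            "unseen": _round_floats(asdict(unseen_metrics)),
        }
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.json").write_text(report_to_json(report))
            try:
                _plot_report(family_cv, ablation_cv, ablation_table, out)
            except Exception:  # plotting is best-effort decoration
                pass
        return report
    finally:
        if tmp is not None:
            tmp.cleanup()


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n"


def _plot_report(family_cv, ablation_cv, ablation_table, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(family_cv), figsize=(4 * len(family_cv), 4))
    if len(family_cv) == 1:
        axes = [axes]
    for ax, (family, cv) in zip(np.atleast_1d(axes), family_cv.items()):
        roc = cv.roc
        ax.plot(roc.grid_fpr, roc.mean_tpr, label=f"mean AUC={roc.mean_auc:.2f}")
        ax.fill_between(
            roc.grid_fpr,
            np.clip(roc.mean_tpr - roc.sd_tpr, 0, 1),
            np.clip(roc.mean_tpr + roc.sd_tpr, 0, 1),
            alpha=0.25,
        )
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_title(family)
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
        ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(out / "roc_families.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, cv in ablation_cv.items():
        ax.plot(cv.roc.grid_fpr, cv.roc.mean_tpr,
                label=f"{name} (AUC={cv.roc.mean_auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "roc_ablation.png", dpi=120)
    plt.close(fig)


__all__ = ["ExperimentConfig", "run_experiment", "report_to_json", "DEFAULT_CONFIGS"]
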