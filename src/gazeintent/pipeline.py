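"""End-to-end experiment orchestration.

One experiment = segment recordings into tau-second windows, assign users
to balanced cross-validation folds (MILP), build visit-intention labels
and the three feature families, balance each training fold with MLSMOTE,
select features, fit every configured multilabel model, and score the
untouched test folds with the evaluation metrics, recording the per-window
classification time.

Fold hygiene is structural: ``Heat_AOI`` is computed from training-fold
recordings only, MLSMOTE and feature selection see only training
instances, and test folds are never balanced.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import RecordingInstances, build_design_matrix, extract_instances
from .gaze_io import GazeRecording, prepare_recording
from .layout import Layout
from .metrics import EvalReport, example_based_metrics, macro_auc, per_aoi_accuracy
from .models import BEST_CONFIG, ModelConfig, fit_model
from .resample import mlsmote
from .selection import select_features
from .windows import FoldAssignment, assign_folds, segment_windows

logger = logging.getLogger("gazeintent")

SENSITIVITY_TAUS = (3.0, 5.0, 10.0, 15.0, 20.0)


@dataclass
class ExperimentConfig:
    tau_s: float = 5.0
    n_folds: int = 10
    models: list[ModelConfig] = field(default_factory=lambda: [BEST_CONFIG])
    apply_mlsmote: bool = True
    mlsmote_k: int = 5
    # Equal-width binning for MI-based selection: flooring pixel- and
    # velocity-scale features yields near-unique alphabets whose empirical
    # MI saturates, swamping genuinely informative columns.
    selection_scheme: str = "equal_width"
    threshold: float = 0.5
    seed: int = 0


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    fold_assignment: FoldAssignment
    reports: dict[str, EvalReport]
    mc_per_aoi: list[tuple[int, float]]
    mc_vector: tuple[tuple[int, ...], float]
    n_instances: int

    def table(self) -> pd.DataFrame:
        """Metric table in the usual report layout (one row per model)."""
        return pd.DataFrame([r.to_row() for r in self.reports.values()])


def run_experiment(
    recordings: list[GazeRecording],
    layout: Layout,
    config: ExperimentConfig | None = None,
) -> ExperimentResult:
    config = config or ExperimentConfig()
    recordings = [prepare_recording(r) for r in recordings]

    instances: list[RecordingInstances] = []
    window_counts: dict[str, int] = {}
    for rec in recordings:
        n_windows = len(segment_windows(rec.duration_ms, config.tau_s))
        window_counts[rec.user_id] = window_counts.get(rec.user_id, 0) + n_windows
        if n_windows < 2:
            logger.info(
                "recording %s/%s has %d windows; contributes no instances",
                rec.user_id, rec.session_id, n_windows,
            )
            continue
        instances.append(extract_instances(rec, layout, config.tau_s))
    if not instances:
        raise ValueError("no recording long enough to produce instances")

    folds = assign_folds(window_counts, config.n_folds)
    logger.info(
        "fold assignment: sums=%s objective=%.1f", folds.fold_sums, folds.objective
    )

    all_Y = np.vstack(
        [ri.labels[ri.features.index.to_numpy() - 1] for ri in instances]
    )
    from .windows import majority_class_ratio  # local import avoids cycle noise

    mc_per_aoi, mc_vector = majority_class_ratio([all_Y])

    per_model_fold: dict[str, dict[str, list[float]]] = {
        m.name: {} for m in config.models
    }
    per_model_aoi: dict[str, list[np.ndarray]] = {m.name: [] for m in config.models}
    per_model_time: dict[str, list[float]] = {m.name: [] for m in config.models}

    for k in range(config.n_folds):
        fd = build_design_matrix(instances, layout, folds, k)
        if len(fd.test_X) == 0 or len(fd.train_X) == 0:
            logger.info("fold %d has an empty side; skipped", k)
            continue
        Xtr_full = fd.train_X.to_numpy(dtype=float)
        Ytr = fd.train_Y
        if config.apply_mlsmote:
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, k)).generate_state(1)[0]
            )
            Xtr_full, Ytr = mlsmote(Xtr_full, Ytr, config.mlsmote_k, rng)
        Xte_full = fd.test_X.to_numpy(dtype=float)
        for mconf in config.models:
            sel = select_features(
                Xtr_full, Ytr, mconf.selection, mconf.n_features,
                scheme=config.selection_scheme,
            )
            names = [fd.train_X.columns[j] for j in sel]
            model = fit_model(mconf, Xtr_full[:, sel], Ytr, feature_names=names)
            Xte = Xte_full[:, sel]
            t0 = time.perf_counter()
            scores = model.scores(Xte)
            preds = model.predict(Xte, config.threshold)
            elapsed = time.perf_counter() - t0
            fold_metrics = example_based_metrics(preds, fd.test_Y)
            fold_metrics["macro_auc"] = macro_auc(scores, fd.test_Y)
            store = per_model_fold[mconf.name]
            for key, val in fold_metrics.items():
                store.setdefault(key, []).append(val)
            per_model_aoi[mconf.name].append(per_aoi_accuracy(preds, fd.test_Y))
            per_model_time[mconf.name].append(elapsed / len(Xte))

    reports = {}
    for mconf in config.models:
        name = mconf.name
        if not per_model_fold[name]:
            continue
        reports[name] = EvalReport(
            model=name,
            per_fold=per_model_fold[name],
            per_aoi=np.mean(per_model_aoi[name], axis=0),
            time_per_window_s=float(np.mean(per_model_time[name])),
        )
    return ExperimentResult(
        config=config,
        fold_assignment=folds,
        reports=reports,
        mc_per_aoi=mc_per_aoi,
        mc_vector=mc_vector,
        n_instances=len(all_Y),
    )


def sensitivity_analysis(
    recordings: list[GazeRecording],
    layout: Layout,
    config: ExperimentConfig | None = None,
    taus: tuple[float, ...] = SENSITIVITY_TAUS,
) -> dict[float, ExperimentResult]:
    """Re-run the full experiment for each window length tau."""
    config = config or ExperimentConfig()
    results = {}
    for tau in taus:
        cfg = ExperimentConfig(
            tau_s=tau,
            n_folds=config.n_folds,
            models=config.models,
            apply_mlsmote=config.apply_mlsmote,
            mlsmote_k=config.mlsmote_k,
            selection_scheme=config.selection_scheme,
            threshold=config.threshold,
            seed=config.seed,
        )
        results[tau] = run_experiment(recordings, layout, cfg)
    return results


def sensitivity_metrics_table(results: dict[float, ExperimentResult]) -> pd.DataFrame:
    """(model, metric) x tau matrix of cross-validated means."""
    rows = []
    for tau, res in results.items():
        for name, rep in res.reports.items():
            for metric, col in (
                ("macro_auc", "AUC"), ("subset_accuracy", "Exact"),
                ("f_measure", "Fscore"), ("accuracy", "Acc"), ("precision", "Pre"),
            ):
                rows.append(
                    {"model": name, "metric": col, "tau_s": tau,
                     "value": rep.mean[metric]}
                )
    df = pd.DataFrame(rows)
    return df.pivot_table(index=["model", "metric"], columns="tau_s", values="value")


def sensitivity_timing_table(results: dict[float, ExperimentResult]) -> pd.DataFrame:
    """Per-window classification time (s) per model and tau."""
    rows = []
    for tau, res in results.items():
        for name, rep in res.reports.items():
            rows.append(
                {"model": name, "tau_s": tau,
                 "time_per_window_s": rep.time_per_window_s}
            )
    df = pd.DataFrame(rows)
    return df.pivot_table(index="model", columns="tau_s", values="time_per_window_s")
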