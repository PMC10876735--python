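"""Evaluation metrics and the cross-validation harness.

Landmark detection is scored by the Euclidean displacement
E = ||g - l|| in mm between predicted (l) and annotated (g) positions,
summarised per landmark as mean and standard deviation over subjects,
and referenced against the interobserver variability E_inter (the same
statistic between two human observers) via the ratio E/E_inter.
Per-component agreement is assessed with Bland-Altman statistics (bias,
SD, 95% limits of agreement and a proportional-bias slope).
Classification is scored by accuracy.  Cohorts are split with
stratified k-fold cross-validation (default k = 5) so each fold
preserves the patient/control ratio and every subject validates exactly
once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .io import N_LANDMARKS

__all__ = [
    "FoldAssignment",
    "displacement",
    "cohort_landmark_stats",
    "bland_altman",
    "classification_accuracy",
    "stratified_kfold",
    "run_crossval",
]


@dataclass
class FoldAssignment:
    """Disjoint validation folds covering the cohort exactly once."""

    k: int
    folds: list[dict]  # each: {"train": [ids], "validation": [ids]}

    def validation_subjects(self) -> list:
        out = []
        for fold in self.folds:
            out.extend(fold["validation"])
        return out


def displacement(g, l) -> float:
    """Euclidean distance ||g - l|| in mm."""
    g = np.asarray(g, dtype=float)
    l = np.asarray(l, dtype=float)
    if g.shape != l.shape:
        raise ValueError("positions must have the same shape")
    return float(np.linalg.norm(g - l))


def _displacements_per_landmark(predictions: dict, annotations: dict) -> pd.DataFrame:
    rows = []
    for sid, pred in predictions.items():
        ref = annotations[sid]
        pred = np.asarray(pred, dtype=float)
        ref = np.asarray(ref, dtype=float)
        diff = pred - ref
        for j in range(N_LANDMARKS):
            rows.append(
                {
                    "subject_id": sid,
                    "landmark_id": j + 1,
                    "displacement_mm": float(np.linalg.norm(diff[j])),
                    "dz_mm": diff[j, 0],
                    "dy_mm": diff[j, 1],
                    "dx_mm": diff[j, 2],
                }
            )
    return pd.DataFrame(rows)


def cohort_landmark_stats(
    predictions: dict,
    annotations: dict,
    second_observer: dict | None = None,
    fold_of_subject: dict | None = None,
) -> pd.DataFrame:
    """Per-landmark displacement summary (one row per landmark).

    ``predictions``/``annotations`` map subject id to (7, 3) mm
    positions.  Columns: mean Euclidean displacement and its SD, the
    per-component signed mean shifts, and — when a second observer is
    supplied — the interobserver variability and the ratio
    mean/interobserver.  When ``fold_of_subject`` is given, statistics
    are computed per fold and averaged over folds.
    """
    if set(predictions) != set(annotations):
        raise ValueError("prediction and annotation subject sets differ")
    if second_observer is not None and set(second_observer) != set(annotations):
        raise ValueError("second-observer subject set differs from annotations")

    table = _displacements_per_landmark(predictions, annotations)
    if fold_of_subject is not None:
        table["fold"] = table["subject_id"].map(fold_of_subject)
        group_cols = ["fold", "landmark_id"]
    else:
        table["fold"] = 0
        group_cols = ["fold", "landmark_id"]
    per_fold = table.groupby(group_cols).agg(
        mean_displacement_mm=("displacement_mm", "mean"),
        sd_displacement_mm=("displacement_mm", "std"),
        mean_dz_mm=("dz_mm", "mean"),
        mean_dy_mm=("dy_mm", "mean"),
        mean_dx_mm=("dx_mm", "mean"),
    )
    report = per_fold.groupby("landmark_id").mean().reset_index()

    if second_observer is not None:
        inter = _displacements_per_landmark(second_observer, annotations)
        inter_mean = (
            inter.groupby("landmark_id")["displacement_mm"]
            .mean()
            .rename("interobserver_mm")
        )
        report = report.merge(inter_mean, on="landmark_id")
        with np.errstate(divide="ignore", invalid="ignore"):
            report["ratio"] = np.where(
                report["interobserver_mm"] > 0,
                report["mean_displacement_mm"] / report["interobserver_mm"],
                np.nan,
            )
    return report


def bland_altman(values_a, values_b) -> dict:
    """Bland-Altman agreement between paired measurements of one component.

    Differences are a - b; bias is their mean, limits of agreement are
    bias +- 1.96 SD, and the proportional-bias slope is the least-squares
    regression of the difference on the pairwise mean.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D arrays of equal length")
    if len(a) < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) > 0:
        slope = float(stats.linregress(mean, diff).slope)
    else:
        slope = 0.0
    return {
        "bias": bias,
        "sd": sd,
        "lower_limit": bias - 1.96 * sd,
        "upper_limit": bias + 1.96 * sd,
        "slope": slope,
        "n": int(len(a)),
    }


def bland_altman_table(predictions: dict, annotations: dict) -> pd.DataFrame:
    """Bland-Altman statistics for all 7 landmarks x 3 spatial components."""
    subjects = sorted(predictions)
    pred = np.stack([np.asarray(predictions[s], dtype=float) for s in subjects])
    ref = np.stack([np.asarray(annotations[s], dtype=float) for s in subjects])
    rows = []
    for j in range(N_LANDMARKS):
        for d, comp in enumerate(("z", "y", "x")):
            res = bland_altman(pred[:, j, d], ref[:, j, d])
            rows.append({"landmark_id": j + 1, "component": comp, **res})
    return pd.DataFrame(rows)


def classification_accuracy(true_labels, predicted_labels) -> float:
    """Fraction of correct classifications."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    if t.size == 0:
        raise ValueError("cannot compute accuracy of an empty label set")
    return float(np.mean(t == p))


def stratified_kfold(subject_ids, labels, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold split preserving the class ratio per fold."""
    subject_ids = list(subject_ids)
    labels = np.asarray(labels)
    if len(subject_ids) != len(labels):
        raise ValueError("subject and label counts differ")
    for cls, count in zip(*np.unique(labels, return_counts=True)):
        if count < k:
            raise ValueError(f"class {cls!r} has {count} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, val_idx in skf.split(np.zeros(len(labels)), labels):
        folds.append(
            {
                "train": [subject_ids[i] for i in train_idx],
                "validation": [subject_ids[i] for i in val_idx],
            }
        )
    return FoldAssignment(k=k, folds=folds)


def run_crossval(
    cohort,
    k: int = 5,
    seed: int = 0,
    model_config=None,
    train_config=None,
    heatmap_config=None,
    svm_augment: bool = False,
    from_annotations: bool = False,
    second_observer: dict | None = None,
):
    """Cross-validate the full pipeline (or the classifier alone).

    ``cohort`` is a sequence of (ImageStack, AnnotationSet, label); with
    ``from_annotations=True`` the network stage is skipped and the SVM
    is trained/evaluated on ground-truth landmark point clouds (the
    annotation-only pathway).  Returns a dict with the fold assignment,
    per-fold accuracies, the averaged accuracy, the per-landmark
    displacement report (network pathway only) and the averaged
    per-landmark weight summary.
    """
    from .classify import classify_many, fit_classifier, weight_summary
    from .heatmap import HeatmapConfig, extract_landmark, coarse_to_fine
    from .pointcloud import (augment_point_clouds, center_point_cloud,
                             to_point_cloud)

    heatmap_config = heatmap_config or HeatmapConfig()
    stacks = [c[0] for c in cohort]
    annotations = [c[1] for c in cohort]
    labels = [c[2] for c in cohort]
    sids = [a.subject_id for a in annotations]
    assignment = stratified_kfold(sids, labels, k=k, seed=seed)
    by_sid = {a.subject_id: (s, a, l) for s, a, l in zip(stacks, annotations, labels)}

    def gt_cloud(sid):
        stack, ann, label = by_sid[sid]
        return center_point_cloud(
            to_point_cloud(ann.landmarks, stack.geometry, sid, label)
        )

    accuracies = []
    weight_frames = []
    predictions_mm: dict[str, np.ndarray] = {}
    fold_of_subject: dict[str, int] = {}
    rng = np.random.default_rng(seed)

    for f, fold in enumerate(assignment.folds):
        if from_annotations:
            train_clouds = [gt_cloud(s) for s in fold["train"]]
            val_clouds = [gt_cloud(s) for s in fold["validation"]]
        else:
            train_clouds, val_clouds = _network_fold_clouds(
                by_sid, fold, model_config, train_config, heatmap_config,
                seed + f, predictions_mm,
            )
            for s in fold["validation"]:
                fold_of_subject[s] = f
        if svm_augment:
            train_clouds = augment_point_clouds(train_clouds, rng=rng)
        model = fit_classifier(train_clouds)
        predicted = classify_many(model, val_clouds)
        truth = [by_sid[s][2] for s in fold["validation"]]
        accuracies.append(classification_accuracy(truth, predicted))
        weight_frames.append(weight_summary(model))

    weights = (
        pd.concat(weight_frames)
        .groupby(["landmark_id", "landmark_name"], sort=True)[
            ["max_weight", "rms_weight"]
        ]
        .mean()
        .reset_index()
    )
    result = {
        "fold_assignment": assignment,
        "fold_accuracies": accuracies,
        "accuracy": float(np.mean(accuracies)),
        "weights": weights,
    }
    if not from_annotations:
        annotations_mm = {
            sid: to_point_cloud(
                by_sid[sid][1].landmarks, by_sid[sid][0].geometry, sid
            ).points
            for sid in predictions_mm
        }
        obs2 = None
        if second_observer is not None:
            obs2 = {sid: second_observer[sid] for sid in predictions_mm}
        result["landmark_report"] = cohort_landmark_stats(
            predictions_mm, annotations_mm, second_observer=obs2,
            fold_of_subject=fold_of_subject,
        )
    return result


def _network_fold_clouds(
    by_sid, fold, model_config, train_config, heatmap_config, seed, predictions_mm
):
    """Train the detection network on one fold and return centred clouds
    built from predicted landmarks (train) and annotations (train) /
    predictions (validation)."""
    from .heatmap import extract_landmark, coarse_to_fine
    from .model import build_model, build_training_set, predict_heatmaps
    from .pointcloud import center_point_cloud, to_point_cloud
    from .model import train_model

    train_stacks = [by_sid[s][0] for s in fold["train"]]
    train_anns = [by_sid[s][1] for s in fold["train"]]
    pairs = build_training_set(train_stacks, train_anns, model_config, heatmap_config)
    net = build_model(model_config, seed=seed)
    net, _ = train_model(net, pairs, train_config)

    def predicted_cloud(sid):
        stack, ann, label = by_sid[sid]
        heatmaps = predict_heatmaps(net, stack)
        coarse = np.array([extract_landmark(h) for h in heatmaps], dtype=float)
        fine = coarse_to_fine(coarse, factor=model_config.final_pool)
        pc = to_point_cloud(fine, stack.geometry, sid, label)
        return pc

    train_clouds = []
    for s in fold["train"]:
        stack, ann, label = by_sid[s]
        train_clouds.append(
            center_point_cloud(to_point_cloud(ann.landmarks, stack.geometry, s, label))
        )
    val_clouds = []
    for s in fold["validation"]:
        pc = predicted_cloud(s)
        predictions_mm[s] = pc.points
        val_clouds.append(center_point_cloud(pc))
    return train_clouds, val_clouds
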