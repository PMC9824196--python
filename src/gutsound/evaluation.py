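"""Detector evaluation: the four frame-level metrics, holdout evaluation,
and subject-grouped k-fold cross-validation.

Metrics (on frame counts):

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    F measure   = 2 * precision * sensitivity / (precision + sensitivity)

TP/TN are correctly classified bowel-sound / non-bowel-sound frames; FP/FN
are falsely recognized and falsely rejected bowel-sound frames. Division-
by-zero cases yield an explicit ``None`` marker rather than 0 or NaN.

Splits are always grouped by subject: every recording of a subject lives in
exactly one fold, so no identity leaks between train and test.
"""
from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dataset import ClipData, FrameDataset, stack_frames, subjects_of
from .errors import ConfigError, ValidationError
from .intervals import FrameLabels, IntervalTrack, frame_labels_to_intervals
from .models import Detector, DetectorConfig, binarize, build_detector, predict_frames, train

log = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "f_measure")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    """The four metrics; ``None`` marks an undefined (0/0) value."""

    accuracy: Optional[float]
    precision: Optional[float]
    sensitivity: Optional[float]
    f_measure: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _as_binary(x) -> np.ndarray:
    if isinstance(x, FrameLabels):
        x = x.values
    arr = np.asarray(x).ravel()
    return arr.astype(bool)


def confusion(true, pred) -> ConfusionCounts:
    """Count frame outcomes; inputs are binary vectors or FrameLabels."""
    t, p = _as_binary(true), _as_binary(pred)
    if len(t) != len(p):
        raise ValidationError(f"length mismatch: {len(t)} true vs {len(p)} predicted frames")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the four metrics exactly; 0/0 cases become ``None``."""
    if c.total == 0:
        raise ValidationError("cannot compute metrics on zero frames")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f_measure = None
    else:
        f_measure = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(accuracy, precision, sensitivity, f_measure)


@dataclass(frozen=True)
class MetricsSummary:
    """Mean +/- SD of each metric across folds or repeats (None-aware)."""

    mean: MetricsReport
    sd: MetricsReport
    n: int

    @staticmethod
    def from_reports(reports: Sequence[MetricsReport]) -> "MetricsSummary":
        means, sds = {}, {}
        for name in METRIC_NAMES:
            vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
            means[name] = statistics.fmean(vals) if vals else None
            sds[name] = statistics.pstdev(vals) if len(vals) > 1 else (0.0 if vals else None)
        return MetricsSummary(MetricsReport(**means), MetricsReport(**sds), n=len(reports))


# ---------------------------------------------------------------------------
# Subject-grouped fold plans

@dataclass(frozen=True)
class FoldPlan:
    """Partition of subjects into k folds; every clip follows its subject."""

    k: int
    assignment: Dict[str, int]
    repeats: int = 1

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if not folds <= set(range(self.k)):
            raise ValidationError("fold indices must lie in [0, k)")

    def fold_subjects(self, fold: int) -> List[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def fold_sizes(self) -> List[int]:
        return [len(self.fold_subjects(f)) for f in range(self.k)]


def make_fold_plan(subjects: Sequence[str], k: int = 9, seed: int = 0,
                   repeats: int = 1) -> FoldPlan:
    """Shuffle subjects and deal them round-robin into k near-equal folds."""
    subjects = list(subjects)
    if len(set(subjects)) != len(subjects):
        raise ValidationError("duplicate subject ids")
    if k < 2:
        raise ConfigError("k: need at least 2 folds")
    if k > len(subjects):
        raise ConfigError(f"k={k} exceeds the {len(subjects)} available subjects")
    order = list(subjects)
    np.random.default_rng(seed).shuffle(order)
    return FoldPlan(k=k, assignment={s: i % k for i, s in enumerate(order)},
                    repeats=repeats)


def holdout_split(plan: FoldPlan, test_fold: int = 0) -> Tuple[List[str], List[str]]:
    """(train_subjects, test_subjects) for one fixed split."""
    if not (0 <= test_fold < plan.k):
        raise ConfigError(f"test_fold {test_fold} outside [0, {plan.k})")
    test = plan.fold_subjects(test_fold)
    train = sorted(s for s in plan.assignment if plan.assignment[s] != test_fold)
    return train, test


def _select(dataset: FrameDataset, subjects: Sequence[str]) -> FrameDataset:
    wanted = set(subjects)
    return [c for c in dataset if c.subject_id in wanted]


@dataclass
class SplitResult:
    """Outcome of one train/test split."""

    report: MetricsReport
    per_clip_reports: Dict[str, MetricsReport]
    predicted_tracks: Dict[str, IntervalTrack]
    truth_tracks: Dict[str, IntervalTrack]
    detector: Detector


def evaluate_split(
    config: DetectorConfig,
    dataset: FrameDataset,
    train_subjects: Sequence[str],
    test_subjects: Sequence[str],
    iterations: Optional[int] = None,
    average: str = "micro",
) -> SplitResult:
    """Train on one subject set, test on a disjoint one.

    Metrics are pooled over all test frames (micro) by default; with
    ``average='macro'`` the per-clip metrics are averaged instead. Predicted
    frame labels are also decoded to interval tracks (with the 10 ms
    unification applied) for downstream motility analysis.
    """
    overlap = set(train_subjects) & set(test_subjects)
    assert not overlap, f"subject leakage between train and test: {sorted(overlap)}"
    train_clips = _select(dataset, train_subjects)
    test_clips = _select(dataset, test_subjects)
    if not train_clips or not test_clips:
        raise ValidationError("empty train or test set for this split")

    x_train, y_train = stack_frames(train_clips)
    detector = build_detector(config)
    train(detector, x_train, y_train, iterations=iterations)

    pooled = ConfusionCounts(0, 0, 0, 0)
    per_clip, predicted_tracks, truth_tracks = {}, {}, {}
    for clip in test_clips:
        probs = predict_frames(detector, clip.patches)
        pred = binarize(probs, config.threshold, grid=clip.grid)
        c = confusion(clip.labels, pred)
        pooled = pooled + c
        per_clip[clip.clip_id] = metrics(c)
        predicted_tracks[clip.clip_id] = frame_labels_to_intervals(pred)
        truth_tracks[clip.clip_id] = clip.truth

    if average == "micro":
        report = metrics(pooled)
    elif average == "macro":
        report = MetricsSummary.from_reports(list(per_clip.values())).mean
    else:
        raise ConfigError(f"average: {average!r} is not 'micro' or 'macro'")
    return SplitResult(report, per_clip, predicted_tracks, truth_tracks, detector)


def holdout_evaluate(
    config: DetectorConfig,
    dataset: FrameDataset,
    plan: FoldPlan,
    test_fold: int = 0,
    repeats: int = 5,
    iterations: Optional[int] = None,
    average: str = "micro",
) -> Tuple[List[SplitResult], MetricsSummary]:
    """One fixed train/test split, repeated with fresh training seeds.

    The split itself stays fixed across repeats; only the training seed
    changes, so the spread reflects training variance, not split variance.
    """
    train_subj, test_subj = holdout_split(plan, test_fold)
    results = []
    for r in range(repeats):
        cfg = replace(config, seed=config.seed + r)
        results.append(
            evaluate_split(cfg, dataset, train_subj, test_subj, iterations, average)
        )
    summary = MetricsSummary.from_reports([res.report for res in results])
    return results, summary


def cross_validate(
    config: DetectorConfig,
    dataset: FrameDataset,
    plan: FoldPlan,
    iterations: Optional[int] = None,
    average: str = "micro",
) -> Tuple[List[SplitResult], MetricsSummary]:
    """Rotate the test fold over all k folds; report per-fold metrics and
    their mean +/- SD."""
    missing = set(subjects_of(dataset)) - set(plan.assignment)
    if missing:
        raise ConfigError(f"fold plan missing subjects: {sorted(missing)}")
    results = []
    for fold in range(plan.k):
        train_subj, test_subj = holdout_split(plan, fold)
        results.append(
            evaluate_split(config, dataset, train_subj, test_subj, iterations, average)
        )
    summary = MetricsSummary.from_reports([res.report for res in results])
    return results, summary
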