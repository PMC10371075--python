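"""Leave-one-subject-out evaluation, temporal traces, and movement rates.

The unit of classification is the sliding window (default 500 frames with
100 frames of overlap, i.e. step 400).  Evaluation holds out one subject
per fold, fits on the remaining subjects' windows, and reports the
unweighted mean of per-fold window accuracies plus a pooled 5×5 confusion
matrix.  Temporal traces order one subject's predicted labels by window
start and smooth them with a centred moving average, reproducing the
five-ascending-steps picture when the classifier is right.

The displacement-rate summary is computed on raw lab-frame positions: the
per-frame path length of a joint summed over a stage, divided by the stage
duration in minutes, converted from millimetres to metres — an absolute
activity measure comparable across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import ClassifierConfig, TrainedModel, fit
from .core_io import STAGE_NAMES, MarkerTrajectorySet, StageAnnotation
from .hjd import FeatureDataset
from .windows import WindowPlan, slide_windows

__all__ = [
    "WindowPlan",
    "slide_windows",
    "FoldRecord",
    "EvaluationResult",
    "TemporalTrace",
    "loso_evaluate",
    "temporal_trace",
    "displacement_rate",
    "cohort_displacement_rates",
    "report",
]


@dataclass
class FoldRecord:
    """Per-window outcomes for one held-out subject."""

    subject_id: str
    true: np.ndarray
    predicted: np.ndarray
    scores: np.ndarray
    window_starts: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.predicted == self.true))


@dataclass
class EvaluationResult:
    folds: list[FoldRecord]
    n_classes: int = 5

    @property
    def fold_accuracies(self) -> dict[str, float]:
        return {f.subject_id: f.accuracy for f in self.folds}

    @property
    def mean_accuracy(self) -> float:
        """Unweighted mean of per-fold (per-subject) accuracies."""
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def confusion_matrix(self) -> np.ndarray:
        """Pooled 5×5 matrix; rows true, columns predicted."""
        cm = np.zeros((self.n_classes, self.n_classes), dtype=int)
        for f in self.folds:
            np.add.at(cm, (f.true, f.predicted), 1)
        return cm


def loso_evaluate(dataset: FeatureDataset, config: ClassifierConfig) -> EvaluationResult:
    """One fold per subject: fit on the others, test on the held-out one.

    Subjects with zero windows are skipped with a warning.
    """
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    folds = []
    for subject in subjects:
        train, test = dataset.split_subject(subject)
        if len(test) == 0:
            import warnings

            warnings.warn(f"subject {subject} has no windows; fold skipped")
            continue
        model = fit(config, train)
        scores = model.scores(test.features)
        folds.append(
            FoldRecord(
                subject_id=subject,
                true=test.labels,
                predicted=np.argmax(scores, axis=1),
                scores=scores,
                window_starts=test.window_starts,
            )
        )
    return EvaluationResult(folds=folds, n_classes=config.n_classes)


@dataclass
class TemporalTrace:
    """Ordered per-window label series for one subject, with smoothing."""

    window_starts: np.ndarray
    true: np.ndarray
    predicted: np.ndarray
    span: int
    smoothed: np.ndarray = field(init=False)
    accuracy_series: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.smoothed = _centred_moving_average(self.predicted.astype(float), self.span)
        correct = (self.predicted == self.true).astype(float)
        self.accuracy_series = _centred_moving_average(correct, self.span)


def _centred_moving_average(series: np.ndarray, span: int) -> np.ndarray:
    """Centred moving average; edges use the available (shorter) span."""
    if span < 1:
        raise ValueError("span must be >= 1")
    half = span // 2
    n = len(series)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = series[lo:hi].mean()
    return out


def temporal_trace(model: TrainedModel, subject_dataset: FeatureDataset,
                   span: int = 5) -> TemporalTrace:
    """Predict one subject's windows in session order and smooth the series."""
    order = np.argsort(subject_dataset.window_starts, kind="stable")
    features = subject_dataset.features[order]
    return TemporalTrace(
        window_starts=subject_dataset.window_starts[order],
        true=subject_dataset.labels[order],
        predicted=model.predict(features),
        span=span,
    )


def displacement_rate(
    session: MarkerTrajectorySet,
    annotation: StageAnnotation,
    joints: list[str],
) -> dict[str, float]:
    """Per-stage mean movement rate of the given joints, in metres/minute.

    For each joint and stage, the summed frame-to-frame path length of the
    raw lab-frame trajectory is divided by the stage duration in minutes
    and converted from millimetres to metres; stage values average over the
    requested joints.  Requires a preprocessed (gap-free) session.
    """
    if np.isnan(session.positions).any():
        raise ValueError("session has missing values; preprocess first")
    rates: dict[str, float] = {}
    for seg in annotation.segments:
        # n frames span n-1 inter-frame intervals; a constant 1 mm/frame
        # marker at 100 Hz must come out at exactly 6.0 m/min
        minutes = (seg.n_frames - 1) / session.rate_hz / 60.0
        per_joint = []
        for joint in joints:
            traj = session.marker(joint)[seg.start_frame : seg.end_frame]
            path_mm = float(np.linalg.norm(np.diff(traj, axis=0), axis=1).sum())
            per_joint.append(path_mm / 1000.0 / minutes)
        rates[seg.stage_name] = float(np.mean(per_joint))
    return rates


def cohort_displacement_rates(
    cohort: list[tuple[MarkerTrajectorySet, StageAnnotation]],
    joints: list[str] = ["L_Foot", "R_Foot"],
) -> pd.DataFrame:
    """Mean and standard error across subjects, per stage (m/min).

    Standard error uses the n−1 denominator across subjects.
    """
    per_subject = [displacement_rate(s, a, joints) for s, a in cohort]
    rows = []
    for stage in STAGE_NAMES:
        values = np.array([r[stage] for r in per_subject if stage in r])
        if values.size == 0:
            continue
        se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else np.nan
        rows.append({"stage": stage, "mean": float(values.mean()), "se": se,
                     "n_subjects": len(values)})
    return pd.DataFrame(rows).set_index("stage")


def report(results: dict[tuple[str, str], EvaluationResult]) -> pd.DataFrame:
    """Accuracy table: joint-type rows × classifier columns, with marginals.

    ``results`` maps (joint_type, classifier_family) to an evaluation
    result.  Cells hold mean LOSO accuracy in percent; a MEAN row and
    column hold the unweighted marginal means over the filled cells.
    """
    joint_types = list(dict.fromkeys(jt for jt, _ in results))
    families = list(dict.fromkeys(fam for _, fam in results))
    table = pd.DataFrame(index=joint_types, columns=families, dtype=float)
    for (jt, fam), res in results.items():
        table.loc[jt, fam] = 100.0 * res.mean_accuracy
    table["MEAN"] = table[families].mean(axis=1, skipna=True)
    table.loc["MEAN"] = table.mean(axis=0, skipna=True)
    return table
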