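"""Domain types and CSV I/O for marker trajectories and stage annotations.

A session is a set of 3D marker trajectories sampled at a fixed rate
(millimetres, nominally 100 Hz).  A stage annotation partitions the frame
axis into up to five half-open experimental stage segments:

* ``B1`` (0) — spontaneous baseline, mobile stationary;
* ``B2`` (1) — non-contingent baseline, experimenter moves the mobile;
* ``CR1``/``CR2`` (2/3) — first/second part of the coupled phase, the
  trigger foot is tethered to the mobile;
* ``DC`` (4) — decoupled phase, tether removed.

Missing coordinates are represented as NaN internally and as empty fields
in CSV; a coordinate is never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STAGE_NAMES",
    "STAGE_TO_LABEL",
    "LABEL_TO_STAGE",
    "KEYPOINTS_12",
    "MarkerTrajectorySet",
    "StageSegment",
    "StageAnnotation",
    "ValidationReport",
    "FormatError",
    "StructuralError",
    "AnnotationError",
    "read_session",
    "write_session",
    "read_annotation",
    "write_annotation",
    "validate",
]

#: Stage names in experimental order; index in this tuple is the class label.
STAGE_NAMES = ("B1", "B2", "CR1", "CR2", "DC")
STAGE_TO_LABEL = {name: i for i, name in enumerate(STAGE_NAMES)}
LABEL_TO_STAGE = {i: name for i, name in enumerate(STAGE_NAMES)}

#: The canonical 12-keypoint marker set used throughout the pipeline.
KEYPOINTS_12 = (
    "Head",
    "C_Pelvis",
    "L_Hip",
    "R_Hip",
    "L_Shoulder",
    "R_Shoulder",
    "L_Hand",
    "R_Hand",
    "L_Knee",
    "R_Knee",
    "L_Foot",
    "R_Foot",
)


class FormatError(ValueError):
    """A file header or field does not match the expected dialect."""


class StructuralError(ValueError):
    """Frame index or array shapes violate the session invariants."""


class AnnotationError(ValueError):
    """Stage segments overlap, repeat, or use unknown stage names."""


@dataclass
class MarkerTrajectorySet:
    """3D marker trajectories for one subject.

    Parameters
    ----------
    subject_id
        Identifier for the recorded subject.
    rate_hz
        Sampling rate in Hz (Vicon default 100).
    marker_labels
        Ordered marker names; column order of ``positions``.
    positions
        ``(n_frames, n_markers, 3)`` float array in millimetres.  Missing
        coordinates are NaN.
    frame_index
        Integer frame numbers, contiguous from 0.
    """

    subject_id: str
    rate_hz: float
    marker_labels: list[str]
    positions: np.ndarray
    frame_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise StructuralError(
                f"positions must be (frames, markers, 3), got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.marker_labels):
            raise StructuralError(
                f"{len(self.marker_labels)} marker labels but "
                f"{self.positions.shape[1]} marker columns"
            )
        if self.rate_hz <= 0:
            raise StructuralError("rate_hz must be positive")
        if self.frame_index is None:
            self.frame_index = np.arange(self.n_frames)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.frame_index.shape != (self.n_frames,) or (
            self.n_frames > 0
            and not np.array_equal(
                self.frame_index, np.arange(self.frame_index[0], self.frame_index[0] + self.n_frames)
            )
        ):
            raise StructuralError("frame_index must increase contiguously by 1")
        if self.n_frames > 0 and self.frame_index[0] != 0:
            raise StructuralError("frame_index must start at 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    def marker_index(self, label: str) -> int:
        try:
            return self.marker_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown marker {label!r}") from None

    def marker(self, label: str) -> np.ndarray:
        """Return the ``(n_frames, 3)`` trajectory of one marker."""
        return self.positions[:, self.marker_index(label), :]

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            subject_id=self.subject_id,
            rate_hz=self.rate_hz,
            marker_labels=list(self.marker_labels),
            positions=self.positions.copy(),
            frame_index=self.frame_index.copy(),
        )


@dataclass(frozen=True)
class StageSegment:
    label: int
    start_frame: int
    end_frame: int  # half-open: frames start_frame .. end_frame-1
    stage_name: str

    def __post_init__(self) -> None:
        if self.stage_name not in STAGE_TO_LABEL:
            raise AnnotationError(f"unknown stage name {self.stage_name!r}")
        if self.label != STAGE_TO_LABEL[self.stage_name]:
            raise AnnotationError(
                f"label {self.label} inconsistent with stage {self.stage_name}"
            )
        if self.end_frame <= self.start_frame:
            raise AnnotationError(
                f"segment {self.stage_name}: end_frame must exceed start_frame"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class StageAnnotation:
    """Ordered, non-overlapping stage segments plus the trigger-foot side."""

    segments: list[StageSegment]
    trigger_side: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.trigger_side not in ("left", "right"):
            raise AnnotationError(f"trigger_side must be left|right, got {self.trigger_side!r}")
        self.segments = sorted(self.segments, key=lambda s: s.start_frame)
        seen: set[str] = set()
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start_frame < prev.end_frame:
                raise AnnotationError(
                    f"segments {prev.stage_name} and {cur.stage_name} overlap"
                )
        for seg in self.segments:
            if seg.stage_name in seen:
                raise AnnotationError(f"stage {seg.stage_name} annotated twice")
            seen.add(seg.stage_name)

    @property
    def trigger_foot(self) -> str:
        return "L_Foot" if self.trigger_side == "left" else "R_Foot"

    def segment_for(self, stage_name: str) -> StageSegment | None:
        for seg in self.segments:
            if seg.stage_name == stage_name:
                return seg
        return None

    def labels_per_frame(self, n_frames: int) -> np.ndarray:
        """Frame-wise label array; frames outside any segment get -1."""
        out = np.full(n_frames, -1, dtype=int)
        for seg in self.segments:
            out[seg.start_frame : min(seg.end_frame, n_frames)] = seg.label
        return out


@dataclass
class ValidationReport:
    missing_fraction: dict[str, float]
    out_of_annotation_frames: int
    absent_required_markers: list[str]
    ok: bool


# ---------------------------------------------------------------------------
# CSV I/O

def _wide_columns(markers: list[str]) -> list[str]:
    cols = ["frame"]
    for m in markers:
        cols += [f"{m}_x", f"{m}_y", f"{m}_z"]
    return cols


def read_session(
    path, dialect: str = "wide", subject_id: str | None = None, rate_hz: float = 100.0
) -> MarkerTrajectorySet:
    """Read a session CSV in wide or long dialect.

    Wide: ``frame,<marker>_x,<marker>_y,<marker>_z,...``; long:
    ``frame,marker,x,y,z`` (a frame/marker row may be absent → missing).
    Empty cells map to NaN.  Marker order follows first appearance.
    """
    if dialect not in ("wide", "long"):
        raise ValueError(f"dialect must be wide|long, got {dialect!r}")
    df = pd.read_csv(path)
    if subject_id is None:
        subject_id = str(path)
    if dialect == "wide":
        if df.columns[0] != "frame":
            raise FormatError(f"first column must be 'frame', got {df.columns[0]!r}")
        markers: list[str] = []
        for col in df.columns[1:]:
            if "_" not in col or col.rsplit("_", 1)[1] not in ("x", "y", "z"):
                raise FormatError(f"malformed wide column {col!r}")
            name = col.rsplit("_", 1)[0]
            if name not in markers:
                markers.append(name)
        expected = _wide_columns(markers)
        if list(df.columns) != expected:
            missing = [c for c in expected if c not in df.columns]
            raise FormatError(f"wide header incomplete; missing columns {missing}")
        frames = df["frame"].to_numpy(dtype=int)
        _check_contiguous(frames)
        positions = (
            df[expected[1:]].to_numpy(dtype=float).reshape(len(df), len(markers), 3)
        )
    else:
        required = ["frame", "marker", "x", "y", "z"]
        if list(df.columns) != required:
            raise FormatError(f"long header must be {required}, got {list(df.columns)}")
        markers = list(dict.fromkeys(df["marker"].astype(str)))
        frames = np.unique(df["frame"].to_numpy(dtype=int))
        _check_contiguous(frames)
        n_frames = len(frames)
        positions = np.full((n_frames, len(markers), 3), np.nan)
        midx = {m: j for j, m in enumerate(markers)}
        rows_f = df["frame"].to_numpy(dtype=int)
        rows_m = df["marker"].map(midx).to_numpy(dtype=int)
        positions[rows_f, rows_m, :] = df[["x", "y", "z"]].to_numpy(dtype=float)
    return MarkerTrajectorySet(
        subject_id=subject_id,
        rate_hz=rate_hz,
        marker_labels=markers,
        positions=positions,
        frame_index=np.arange(len(positions)),
    )


def _check_contiguous(frames: np.ndarray) -> None:
    if len(frames) == 0:
        raise StructuralError("session has no frames")
    if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
        raise StructuralError("frame column must be contiguous integers starting at 0")


def write_session(session: MarkerTrajectorySet, path, dialect: str = "wide") -> None:
    """Write a session CSV; NaN coordinates become empty fields."""
    if dialect == "wide":
        data = {"frame": session.frame_index}
        for j, m in enumerate(session.marker_labels):
            for k, ax in enumerate("xyz"):
                data[f"{m}_{ax}"] = session.positions[:, j, k]
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f", na_rep="")
    elif dialect == "long":
        n_f, n_m = session.n_frames, session.n_markers
        frames = np.repeat(session.frame_index, n_m)
        markers = np.tile(np.asarray(session.marker_labels, dtype=object), n_f)
        xyz = session.positions.reshape(n_f * n_m, 3)
        df = pd.DataFrame(
            {"frame": frames, "marker": markers, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]}
        )
        # drop rows where the whole marker is absent in that frame
        df = df[~np.all(np.isnan(xyz), axis=1)]
        df.to_csv(path, index=False, float_format="%.6f", na_rep="")
    else:
        raise ValueError(f"dialect must be wide|long, got {dialect!r}")


def read_annotation(path) -> StageAnnotation:
    """Read a stage annotation CSV: ``stage_name,start_frame,end_frame,trigger_side``."""
    df = pd.read_csv(path)
    required = {"stage_name", "start_frame", "end_frame", "trigger_side"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation header must contain {sorted(required)}")
    sides = set(df["trigger_side"].astype(str))
    if len(sides) != 1:
        raise AnnotationError(f"trigger_side must be constant per file, got {sides}")
    segments = []
    for _, row in df.iterrows():
        name = str(row["stage_name"])
        if name not in STAGE_TO_LABEL:
            raise AnnotationError(f"unknown stage name {name!r}")
        segments.append(
            StageSegment(
                label=STAGE_TO_LABEL[name],
                start_frame=int(row["start_frame"]),
                end_frame=int(row["end_frame"]),
                stage_name=name,
            )
        )
    return StageAnnotation(segments=segments, trigger_side=sides.pop())


def write_annotation(annotation: StageAnnotation, path) -> None:
    rows = [
        {
            "stage_name": s.stage_name,
            "start_frame": s.start_frame,
            "end_frame": s.end_frame,
            "trigger_side": annotation.trigger_side,
        }
        for s in annotation.segments
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def validate(
    session: MarkerTrajectorySet,
    annotation: StageAnnotation,
    required_markers: list[str] = list(KEYPOINTS_12),
) -> ValidationReport:
    """Check a session against an annotation and the required marker set.

    ``ok`` is true iff all required markers are present and every annotated
    segment lies inside the recorded frame range.
    """
    missing_fraction = {
        m: float(np.isnan(session.marker(m)).mean()) if m in session.marker_labels else 1.0
        for m in session.marker_labels
    }
    absent = [m for m in required_markers if m not in session.marker_labels]
    out_of_range = 0
    for seg in annotation.segments:
        if seg.end_frame > session.n_frames:
            out_of_range += seg.end_frame - max(seg.start_frame, session.n_frames)
        if seg.start_frame < 0:
            out_of_range += -seg.start_frame
    return ValidationReport(
        missing_fraction=missing_fraction,
        out_of_annotation_frames=out_of_range,
        absent_required_markers=absent,
        ok=not absent and out_of_range == 0,
    )
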