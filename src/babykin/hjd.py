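"""Histogram-of-Joint-Displacement (HJD) pose descriptors.

Marker positions are re-expressed in a per-frame body-centred frame rooted
at the pelvis, making the descriptors invariant to where the capture volume
origin is and how the infant is oriented in it.  The direction of each
joint's pelvis-rooted displacement is then quantised into a spherical bin
(azimuth × elevation grid; the radius is ignored), and an HJD counts how
many frames of a window the joint spends in each bin — a compact occupancy
signature of posture and movement topology over that window.

Per-joint histograms are fused either by concatenation into a 1D vector or
by row-stacking into a parts × bins matrix; the 2D matrix is exactly the
row-major reshape of the 1D fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import MarkerTrajectorySet, StageAnnotation
from .windows import WindowPlan, slide_windows

__all__ = [
    "SphericalBinning",
    "BodyFrame",
    "HJD",
    "FeatureDataset",
    "GeometryError",
    "PART_SETS",
    "body_frame_at",
    "center_to_root",
    "to_bin",
    "bin_indices",
    "compute_hjd",
    "fuse_1d",
    "fuse_2d",
    "build_dataset",
]


class GeometryError(ValueError):
    """Degenerate marker geometry (coincident pelvis markers, collinear head)."""


#: Named joint subsets for feature fusion.
PART_SETS = {
    "left_hand": ["L_Hand"],
    "right_hand": ["R_Hand"],
    "hands": ["L_Hand", "R_Hand"],
    "left_knee": ["L_Knee"],
    "right_knee": ["R_Knee"],
    "knees": ["L_Knee", "R_Knee"],
    "left_foot": ["L_Foot"],
    "right_foot": ["R_Foot"],
    "feet": ["L_Foot", "R_Foot"],
    "full_body": ["L_Hand", "R_Hand", "L_Knee", "R_Knee", "L_Foot", "R_Foot"],
}


@dataclass
class SphericalBinning:
    """Equal-angle azimuth × elevation partition of the unit sphere.

    Azimuth covers [−π, π) in ``n_azimuth`` half-open arcs; elevation covers
    [−π/2, π/2] in ``n_elevation`` arcs, half-open on the upper edge except
    the last, which is closed so the grid tiles the sphere exactly once.
    Bin index = elevation_bin × n_azimuth + azimuth_bin.  Zero-length
    displacement vectors have no direction; they are assigned the bin
    containing (azimuth 0, elevation 0) and counted in
    ``zero_vector_count``.
    """

    n_azimuth: int = 8
    n_elevation: int = 8
    zero_vector_count: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.n_azimuth < 1 or self.n_elevation < 1 or self.n_bins < 2:
            raise ValueError("need n_azimuth, n_elevation >= 1 and at least 2 bins")

    @property
    def n_bins(self) -> int:
        return self.n_azimuth * self.n_elevation

    def compatible(self, other: "SphericalBinning") -> bool:
        return (self.n_azimuth, self.n_elevation) == (other.n_azimuth, other.n_elevation)


@dataclass(frozen=True)
class BodyFrame:
    """Orthonormal right-handed frame anchored at the pelvis.

    lateral: left→right pelvis direction; longitudinal: pelvis→head,
    orthogonalised against lateral; normal: lateral × longitudinal.
    Body coordinates are (x, y, z) = (lateral, longitudinal, normal).
    """

    origin: np.ndarray
    lateral: np.ndarray
    longitudinal: np.ndarray
    normal: np.ndarray

    def to_body(self, point: np.ndarray) -> np.ndarray:
        d = np.asarray(point) - self.origin
        return np.array([d @ self.lateral, d @ self.longitudinal, d @ self.normal])


_ROOT = "C_Pelvis"
_HEAD = "Head"


def _lateral_pair(session: MarkerTrajectorySet) -> tuple[str, str]:
    # dedicated pelvis markers if placed, else the hips stand in
    if "L_Pelvis" in session.marker_labels and "R_Pelvis" in session.marker_labels:
        return "L_Pelvis", "R_Pelvis"
    if "L_Hip" in session.marker_labels and "R_Hip" in session.marker_labels:
        return "L_Hip", "R_Hip"
    raise GeometryError("no lateral marker pair (L/R_Pelvis or L/R_Hip) present")


def _axes_all_frames(session: MarkerTrajectorySet) -> np.ndarray:
    """(n_frames, 3, 3) rotation matrices, rows = lateral/longitudinal/normal."""
    left, right = _lateral_pair(session)
    lat = session.marker(right) - session.marker(left)
    lat_norm = np.linalg.norm(lat, axis=1)
    if np.any(lat_norm < 1e-9) or np.any(~np.isfinite(lat_norm)):
        raise GeometryError("pelvis markers coincident or missing at some frame")
    lat = lat / lat_norm[:, None]
    head = session.marker(_HEAD) - session.marker(_ROOT)
    lon = head - (head * lat).sum(axis=1)[:, None] * lat
    lon_norm = np.linalg.norm(lon, axis=1)
    if np.any(lon_norm < 1e-9) or np.any(~np.isfinite(lon_norm)):
        raise GeometryError("head collinear with the lateral axis at some frame")
    lon = lon / lon_norm[:, None]
    nrm = np.cross(lat, lon)
    return np.stack([lat, lon, nrm], axis=1)


def body_frame_at(session: MarkerTrajectorySet, frame: int) -> BodyFrame:
    """The body-centred frame at one frame (recomputed per frame)."""
    sub = MarkerTrajectorySet(
        subject_id=session.subject_id,
        rate_hz=session.rate_hz,
        marker_labels=list(session.marker_labels),
        positions=session.positions[frame : frame + 1],
        frame_index=np.array([0]),
    )
    axes = _axes_all_frames(sub)[0]
    return BodyFrame(
        origin=session.marker(_ROOT)[frame].copy(),
        lateral=axes[0],
        longitudinal=axes[1],
        normal=axes[2],
    )


def center_to_root(
    session: MarkerTrajectorySet, joints: list[str]
) -> dict[str, np.ndarray]:
    """Pelvis-rooted body-frame displacement of each joint, per frame.

    Requires a preprocessed session (no missing values).  The pelvis itself
    maps to the zero vector.
    """
    if np.isnan(session.positions).any():
        raise ValueError("session has missing values; preprocess first")
    axes = _axes_all_frames(session)
    root = session.marker(_ROOT)
    out = {}
    for joint in joints:
        d_lab = session.marker(joint) - root  # KeyError for unknown joints
        out[joint] = np.einsum("fij,fj->fi", axes, d_lab)
    return out


def bin_indices(vectors: np.ndarray, binning: SphericalBinning) -> np.ndarray:
    """Vectorised spherical bin assignment for (..., 3) displacement vectors."""
    v = np.asarray(vectors, dtype=float)
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    r = np.linalg.norm(v, axis=-1)
    zero = r == 0
    n_zero = int(np.count_nonzero(zero))
    if n_zero:
        binning.zero_vector_count += n_zero
    alpha = np.arctan2(y, x)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arcsin(np.clip(np.where(zero, 0.0, z / np.where(zero, 1.0, r)), -1.0, 1.0))
    az = np.floor((alpha + np.pi) / (2 * np.pi / binning.n_azimuth)).astype(int)
    az %= binning.n_azimuth  # alpha == +pi wraps onto the [-pi, ...) edge
    el = np.floor((theta + np.pi / 2) / (np.pi / binning.n_elevation)).astype(int)
    el = np.minimum(el, binning.n_elevation - 1)  # top elevation bin closed
    return el * binning.n_azimuth + az


def to_bin(displacement: np.ndarray, binning: SphericalBinning) -> int:
    """Bin index of a single body-frame displacement vector."""
    return int(bin_indices(np.asarray(displacement, dtype=float), binning))


@dataclass
class HJD:
    """Occupancy histogram of one joint over one window.

    ``counts[b]`` is the number of window frames whose displacement
    direction falls in bin ``b``; counts sum to the window length.
    """

    joint: str
    counts: np.ndarray
    window: tuple[int, int]
    binning: SphericalBinning

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.binning.n_bins,):
            raise ValueError("counts length must equal n_bins")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


def compute_hjd(
    displacements: np.ndarray,
    window: tuple[int, int],
    binning: SphericalBinning,
    joint: str = "",
) -> HJD:
    """Histogram the spherical bins of per-frame displacements over a window."""
    start, end = window
    if end <= start:
        raise ValueError(f"empty window {window}")
    if start < 0 or end > len(displacements):
        raise ValueError(f"window {window} outside sequence of {len(displacements)} frames")
    bins = bin_indices(displacements[start:end], binning)
    counts = np.bincount(bins, minlength=binning.n_bins)
    return HJD(joint=joint, counts=counts, window=window, binning=binning)


def _check_fusable(hjds: list[HJD]) -> None:
    if not hjds:
        raise ValueError("need at least one histogram")
    first = hjds[0]
    for h in hjds[1:]:
        if not h.binning.compatible(first.binning):
            raise ValueError("histograms use different binnings")
        if h.window != first.window:
            raise ValueError("histograms cover different windows")


def _normalised(h: HJD, normalise: str) -> np.ndarray:
    if normalise == "counts":
        return h.counts.astype(float)
    if normalise == "proportion":
        return h.counts / h.counts.sum()
    raise ValueError(f"normalise must be counts|proportion, got {normalise!r}")


def fuse_1d(hjds: list[HJD], normalise: str = "counts") -> np.ndarray:
    """Concatenate per-part histograms into one vector (parts × bins long)."""
    _check_fusable(hjds)
    return np.concatenate([_normalised(h, normalise) for h in hjds])


def fuse_2d(hjds: list[HJD], normalise: str = "counts") -> np.ndarray:
    """Stack per-part histograms as rows of a parts × bins matrix.

    Equals the row-major reshape of :func:`fuse_1d` on the same input.
    """
    _check_fusable(hjds)
    return np.stack([_normalised(h, normalise) for h in hjds])


@dataclass
class FeatureDataset:
    """Windowed HJD samples from a cohort, ready for classification."""

    features: np.ndarray  # (n, d) for single/fused1d, (n, parts, bins) for fused2d
    labels: np.ndarray  # (n,) ints 0..4
    subject_ids: np.ndarray  # (n,) strings
    window_starts: np.ndarray  # (n,) session-absolute start frames
    feature_kind: str  # single | fused1d | fused2d
    parts: list[str]
    binning: SphericalBinning

    def __post_init__(self) -> None:
        n = len(self.features)
        if not (len(self.labels) == len(self.subject_ids) == len(self.window_starts) == n):
            raise ValueError("metadata arrays must match the number of samples")
        if n and not np.isin(self.labels, np.arange(5)).all():
            raise ValueError("labels must lie in 0..4")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.subject_ids.tolist()))

    def restrict(self, mask: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            features=self.features[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            window_starts=self.window_starts[mask],
            feature_kind=self.feature_kind,
            parts=self.parts,
            binning=self.binning,
        )

    def split_subject(self, subject_id: str) -> tuple["FeatureDataset", "FeatureDataset"]:
        """(train, test) split holding out one subject."""
        held = self.subject_ids == subject_id
        return self.restrict(~held), self.restrict(held)


def build_dataset(
    cohort: list[tuple[MarkerTrajectorySet, StageAnnotation]],
    feature_kind: str = "fused1d",
    parts: list[str] | str = "feet",
    plan: WindowPlan = WindowPlan(),
    binning: SphericalBinning | None = None,
    normalise: str = "counts",
) -> FeatureDataset:
    """Window every stage segment of every session and compute fused HJDs.

    Windows are generated within each stage segment independently and never
    span a stage boundary, so each sample carries a single stage label.
    Segments shorter than the window width contribute no samples.
    """
    if isinstance(parts, str):
        parts = PART_SETS[parts]
    if binning is None:
        binning = SphericalBinning()
    if feature_kind not in ("single", "fused1d", "fused2d"):
        raise ValueError(f"unknown feature_kind {feature_kind!r}")
    if feature_kind == "single" and len(parts) != 1:
        raise ValueError("feature_kind 'single' requires exactly one part")

    feats, labels, subjects, starts = [], [], [], []
    for session, annotation in cohort:
        disp = center_to_root(session, parts)
        joint_bins = {j: bin_indices(disp[j], binning) for j in parts}
        for seg in annotation.segments:
            for w_start, w_end in slide_windows(seg.n_frames, plan):
                a, b = seg.start_frame + w_start, seg.start_frame + w_end
                hjds = [
                    HJD(j, np.bincount(joint_bins[j][a:b], minlength=binning.n_bins),
                        (a, b), binning)
                    for j in parts
                ]
                if feature_kind == "fused2d":
                    feats.append(fuse_2d(hjds, normalise))
                else:
                    feats.append(fuse_1d(hjds, normalise))
                labels.append(seg.label)
                subjects.append(session.subject_id)
                starts.append(a)

    return FeatureDataset(
        features=np.asarray(feats),
        labels=np.asarray(labels, dtype=int),
        subject_ids=np.asarray(subjects, dtype=object),
        window_starts=np.asarray(starts, dtype=int),
        feature_kind=feature_kind,
        parts=list(parts),
        binning=binning,
    )
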