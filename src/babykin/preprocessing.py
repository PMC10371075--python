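"""Marker-stream cleaning: three-sigma outlier rejection and spline gap filling.

Each coordinate stream (one marker, one axis) is treated independently.
First, samples outside mean ± sigma_mult·σ of the stream are set missing —
a single pass, with the mean and standard deviation computed once over the
observed values of the whole stream, contaminants included.  Missing runs
(original gaps plus rejected samples) are then filled with a natural cubic
spline through the observed samples; observed samples are never altered.
Leading/trailing gaps are filled by extending the nearest observed value,
since cubic extrapolation diverges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core_io import MarkerTrajectorySet

__all__ = [
    "CleaningParams",
    "EmptyStreamError",
    "InsufficientDataError",
    "three_sigma_clean",
    "spline_interpolate",
    "preprocess_session",
]


class EmptyStreamError(ValueError):
    """Stream has fewer than 2 observed values; no statistics can be formed."""


class InsufficientDataError(ValueError):
    """Fewer than 4 observed values; a cubic spline cannot be fitted."""


@dataclass(frozen=True)
class CleaningParams:
    """Parameters of the per-stream cleaning pass.

    sigma_mult
        Half-width of the acceptance band in standard deviations (default 3).
    max_gap_frames
        Longest missing run that will be spline-filled; ``None`` = unlimited.
        Longer runs are still filled by nearest-value extension only at the
        edges; interior runs above the limit raise.
    """

    sigma_mult: float = 3.0
    max_gap_frames: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_mult <= 0:
            raise ValueError("sigma_mult must be positive")


def three_sigma_clean(
    stream: np.ndarray, params: CleaningParams = CleaningParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Flag values outside mean ± sigma_mult·σ of the stream as missing.

    The mean and σ (population, ddof=0) are computed once over the observed
    values — contaminants included, no re-estimation.  Values strictly
    outside the band are set NaN.  Returns (cleaned copy, flagged indices).
    """
    stream = np.asarray(stream, dtype=float)
    observed = np.isfinite(stream)
    if observed.sum() < 2:
        raise EmptyStreamError("need at least 2 observed values")
    mean = stream[observed].mean()
    sigma = stream[observed].std()
    out = stream.copy()
    flagged = observed & ((stream > mean + params.sigma_mult * sigma)
                          | (stream < mean - params.sigma_mult * sigma))
    out[flagged] = np.nan
    return out, np.flatnonzero(flagged)


def spline_interpolate(
    stream: np.ndarray,
    frame_index: np.ndarray | None = None,
    max_gap_frames: int | None = None,
) -> np.ndarray:
    """Fill missing samples with a natural cubic spline through observed ones.

    Observed samples are preserved exactly.  Leading and trailing gaps are
    filled with the nearest observed value.  With ``max_gap_frames`` set,
    an interior gap longer than the limit raises ``InsufficientDataError``.
    """
    stream = np.asarray(stream, dtype=float)
    n = len(stream)
    if frame_index is None:
        frame_index = np.arange(n)
    observed = np.isfinite(stream)
    n_obs = int(observed.sum())
    if n_obs == n:
        return stream.copy()
    if n_obs < 4:
        raise InsufficientDataError(f"cubic spline needs >= 4 observed values, have {n_obs}")
    obs_idx = np.flatnonzero(observed)
    if max_gap_frames is not None:
        interior_gaps = np.diff(obs_idx) - 1
        if interior_gaps.size and interior_gaps.max() > max_gap_frames:
            raise InsufficientDataError(
                f"interior gap of {int(interior_gaps.max())} frames exceeds "
                f"max_gap_frames={max_gap_frames}"
            )
    spline = CubicSpline(frame_index[obs_idx], stream[obs_idx], bc_type="natural")
    out = stream.copy()
    first, last = obs_idx[0], obs_idx[-1]
    interior = ~observed & (np.arange(n) > first) & (np.arange(n) < last)
    out[interior] = spline(frame_index[interior])
    out[:first] = stream[first]
    out[last + 1 :] = stream[last]
    return out


def preprocess_session(
    session: MarkerTrajectorySet, params: CleaningParams = CleaningParams()
) -> MarkerTrajectorySet:
    """Clean then gap-fill every coordinate stream of a session.

    Per marker and axis independently: three-sigma rejection first (its NaNs
    feed the spline), then cubic interpolation.  The result has no missing
    values.  Stream-level errors are re-raised with the marker/axis attached.
    """
    out = session.copy()
    for j, marker in enumerate(session.marker_labels):
        for ax, ax_name in enumerate("xyz"):
            stream = session.positions[:, j, ax]
            try:
                cleaned, _ = three_sigma_clean(stream, params)
                out.positions[:, j, ax] = spline_interpolate(
                    cleaned, session.frame_index, params.max_gap_frames
                )
            except (EmptyStreamError, InsufficientDataError) as err:
                raise type(err)(f"{marker}/{ax_name}: {err}") from err
    return out
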