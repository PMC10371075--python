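"""Synthetic five-stage motion-capture sessions.

The generator emulates the phenomenology of a mobile conjugate reinforcement
(MCR) session recorded with a 12-keypoint marker set at 100 Hz:

* a slow pelvis drift shared by all markers (the infant shifts on the
  mattress but does not locomote);
* per-limb band-limited oscillation around anatomical rest offsets —
  a sum of 2–4 seeded random-phase sinusoids plus Gaussian jitter;
* stage-dependent dynamics: overall activity shrinks in the non-contingent
  baseline (B2); during the coupled stages (CR1/CR2) the trigger foot's
  motion concentrates on the vertical axis and grows in amplitude (kicking
  the tethered mobile); after decoupling (DC) the trigger foot is more
  active and directionally dispersed than in any other stage.

The kinematic model is phenomenological, not biomechanical: the downstream
pipeline consumes positions only, and what matters is that the stage
structure is recoverable, with a movement-rate profile ordered
B2 < {B1, CR1, CR2} < DC for the feet.

Separate operations inject burst missingness (marker occlusion) and spike
outliers (reflection artefacts) with ground-truth masks so that the
preprocessing stage can be tested against a known contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    KEYPOINTS_12,
    STAGE_NAMES,
    STAGE_TO_LABEL,
    MarkerTrajectorySet,
    StageAnnotation,
    StageSegment,
)

__all__ = [
    "StagePhase",
    "StageDynamics",
    "SyntheticConfig",
    "CohortSpec",
    "default_stage_dynamics",
    "default_rest_offsets",
    "generate_session",
    "generate_cohort",
    "inject_missing",
    "inject_outliers",
]


class ConfigError(ValueError):
    """Invalid synthetic-generation configuration."""


def _rng(seed: int, *counters: int) -> np.random.Generator:
    """Counter-based sub-seed derivation.

    Each (seed, counters...) pair maps to an independent generator, so
    adding subjects or purposes never reshuffles the streams of existing
    ones.  Purpose codes: 0 session, 1 missingness, 2 outliers.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=counters))


@dataclass(frozen=True)
class StagePhase:
    """Dynamics of one experimental stage.

    amplitude_mm maps each limb marker to its oscillation amplitude (the
    per-axis spread is amplitude × sqrt(axis weight)).  Axis weights are
    (x, y, z) fractions of oscillation variance and must sum to 1.  The
    trigger-foot overrides express the tether: they replace the foot's
    weights and scale its amplitude during the relevant stages.
    """

    amplitude_mm: dict[str, float]
    axis_weights: tuple[float, float, float]
    oscillation_hz: float
    noise_sd_mm: float
    trigger_axis_weights: tuple[float, float, float] | None = None
    trigger_amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        for w in (self.axis_weights, self.trigger_axis_weights):
            if w is None:
                continue
            if min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
                raise ConfigError(f"axis weights must be nonnegative and sum to 1, got {w}")
        if any(a < 0 for a in self.amplitude_mm.values()):
            raise ConfigError("amplitudes must be nonnegative")
        if self.oscillation_hz <= 0 or self.noise_sd_mm < 0:
            raise ConfigError("oscillation_hz must be > 0 and noise_sd_mm >= 0")


#: limb markers that oscillate visibly; the torso moves with the pelvis only
_LIMB_BASE_AMPLITUDE = {
    "Head": 5.0,
    "L_Shoulder": 8.0,
    "R_Shoulder": 8.0,
    "L_Hip": 4.0,
    "R_Hip": 4.0,
    "L_Hand": 25.0,
    "R_Hand": 25.0,
    "L_Knee": 20.0,
    "R_Knee": 20.0,
    "L_Foot": 30.0,
    "R_Foot": 30.0,
}

_ISO = (1 / 3, 1 / 3, 1 / 3)


def _scaled(scale: float) -> dict[str, float]:
    return {m: a * scale for m, a in _LIMB_BASE_AMPLITUDE.items()}


def default_stage_dynamics() -> "StageDynamics":
    """Stage dynamics sized so the stages are separable but not trivially so.

    Feet movement-rate ordering by construction: B2 (global damping) is the
    quietest; B1 and the coupled stages are comparable; DC is the most
    active.  During CR1/CR2 three quarters of the trigger foot's oscillation
    variance sits on the vertical axis (tether direction); in DC the foot's
    directions disperse again.
    """
    return StageDynamics(
        phases={
            "B1": StagePhase(_scaled(1.0), _ISO, 0.8, 0.3),
            "B2": StagePhase(_scaled(0.45), _ISO, 0.7, 0.2),
            "CR1": StagePhase(
                _scaled(0.9),
                _ISO,
                0.9,
                0.25,
                trigger_axis_weights=(0.125, 0.125, 0.75),
                trigger_amplitude_scale=1.25,
            ),
            "CR2": StagePhase(
                _scaled(0.95),
                _ISO,
                1.0,
                0.25,
                trigger_axis_weights=(0.15, 0.15, 0.70),
                trigger_amplitude_scale=1.35,
            ),
            "DC": StagePhase(
                _scaled(1.15),
                _ISO,
                1.0,
                0.35,
                trigger_axis_weights=_ISO,
                trigger_amplitude_scale=1.6,
            ),
        }
    )


@dataclass(frozen=True)
class StageDynamics:
    """Per-stage :class:`StagePhase` parameters for all five stages."""

    phases: dict[str, StagePhase]

    def __post_init__(self) -> None:
        missing = set(STAGE_NAMES) - set(self.phases)
        if missing:
            raise ConfigError(f"stage dynamics missing stages {sorted(missing)}")


def default_rest_offsets() -> dict[str, tuple[float, float, float]]:
    """Anatomical rest offsets (mm) from the pelvis for a supine infant.

    x lateral (left negative), y toward the head, z up off the mattress.
    """
    return {
        "Head": (0.0, 250.0, 30.0),
        "C_Pelvis": (0.0, 0.0, 0.0),
        "L_Hip": (-45.0, 10.0, 0.0),
        "R_Hip": (45.0, 10.0, 0.0),
        "L_Shoulder": (-70.0, 180.0, 20.0),
        "R_Shoulder": (70.0, 180.0, 20.0),
        "L_Hand": (-110.0, 120.0, 40.0),
        "R_Hand": (110.0, 120.0, 40.0),
        "L_Knee": (-60.0, -120.0, 40.0),
        "R_Knee": (60.0, -120.0, 40.0),
        "L_Foot": (-70.0, -230.0, 50.0),
        "R_Foot": (70.0, -230.0, 50.0),
    }


def _default_stage_frames() -> dict[str, int]:
    # 2 min baselines and decoupled phase, 1 min per coupled sub-stage, 100 Hz
    return {"B1": 12000, "B2": 12000, "CR1": 6000, "CR2": 6000, "DC": 12000}


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic session."""

    n_frames: dict[str, int] = field(default_factory=_default_stage_frames)
    rate_hz: float = 100.0
    rest_offsets_mm: dict[str, tuple[float, float, float]] = field(
        default_factory=default_rest_offsets
    )
    trigger_side: str = "left"
    stage_dynamics: StageDynamics = field(default_factory=default_stage_dynamics)
    pelvis_drift_sd_mm: float = 10.0
    amplitude_scale: float = 1.0  # between-subject global modifiers
    frequency_scale: float = 1.0
    seed: int = 0
    subject_id: str = "S1"

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_frames.values()):
            raise ConfigError("stage frame counts must be positive")
        if set(self.n_frames) - set(STAGE_NAMES):
            raise ConfigError(f"unknown stages in n_frames: {set(self.n_frames) - set(STAGE_NAMES)}")
        if self.trigger_side not in ("left", "right"):
            raise ConfigError("trigger_side must be left|right")
        if self.pelvis_drift_sd_mm < 0 or self.rate_hz <= 0:
            raise ConfigError("pelvis_drift_sd_mm >= 0 and rate_hz > 0 required")
        offs = list(self.rest_offsets_mm.values())
        for i in range(len(offs)):
            for j in range(i + 1, len(offs)):
                if np.allclose(offs[i], offs[j]):
                    raise ConfigError("rest offsets must be pairwise distinct")


@dataclass
class CohortSpec:
    """A cohort of jittered subjects; trigger side alternates L,R,L,R,..."""

    n_subjects: int = 5
    base_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    between_subject_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("leave-one-subject-out needs at least 2 subjects")
        if self.between_subject_jitter < 0:
            raise ConfigError("between_subject_jitter must be nonnegative")


def _band_limited(
    rng: np.random.Generator, n: int, rate_hz: float, amp: float, weights, f0: float
) -> np.ndarray:
    """(n, 3) oscillation: per axis a sum of 2–4 random-phase sinusoids.

    Sinusoid amplitudes are scaled so the per-axis variance equals
    amp² × weight / 2 regardless of how many components are drawn.
    """
    t = np.arange(n) / rate_hz
    out = np.empty((n, 3))
    for ax in range(3):
        k = int(rng.integers(2, 5))
        freqs = f0 * rng.uniform(0.6, 1.4, size=k)
        phases = rng.uniform(0, 2 * np.pi, size=k)
        a = amp * np.sqrt(weights[ax]) / np.sqrt(k)
        out[:, ax] = a * np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases).sum(axis=1)
    return out


def generate_session(config: SyntheticConfig) -> tuple[MarkerTrajectorySet, StageAnnotation]:
    """Generate one session and its matching annotation, deterministically."""
    rng = _rng(config.seed, 0)
    stage_order = [s for s in STAGE_NAMES if s in config.n_frames]
    total = sum(config.n_frames[s] for s in stage_order)
    trigger_marker = "L_Foot" if config.trigger_side == "left" else "R_Foot"

    # shared slow pelvis drift: two low-frequency sinusoids per axis
    t = np.arange(total) / config.rate_hz
    pelvis = np.zeros((total, 3))
    for ax in range(3):
        for _ in range(2):
            f = rng.uniform(0.01, 0.04)
            ph = rng.uniform(0, 2 * np.pi)
            pelvis[:, ax] += config.pelvis_drift_sd_mm * rng.uniform(0.5, 1.0) * np.sin(
                2 * np.pi * f * t + ph
            )

    markers = list(KEYPOINTS_12)
    positions = np.empty((total, len(markers), 3))
    segments = []
    start = 0
    for stage in stage_order:
        n = config.n_frames[stage]
        phase = config.stage_dynamics.phases[stage]
        sl = slice(start, start + n)
        for j, m in enumerate(markers):
            rest = np.asarray(config.rest_offsets_mm[m])
            amp = phase.amplitude_mm.get(m, 0.0) * config.amplitude_scale
            weights = phase.axis_weights
            if m == trigger_marker:
                amp *= phase.trigger_amplitude_scale
                if phase.trigger_axis_weights is not None:
                    weights = phase.trigger_axis_weights
            osc = _band_limited(
                rng, n, config.rate_hz, amp, weights,
                phase.oscillation_hz * config.frequency_scale,
            )
            noise = rng.normal(0.0, phase.noise_sd_mm, size=(n, 3))
            positions[sl, j, :] = pelvis[sl] + rest + osc + noise
        segments.append(
            StageSegment(
                label=STAGE_TO_LABEL[stage],
                start_frame=start,
                end_frame=start + n,
                stage_name=stage,
            )
        )
        start += n

    session = MarkerTrajectorySet(
        subject_id=config.subject_id,
        rate_hz=config.rate_hz,
        marker_labels=markers,
        positions=positions,
        frame_index=np.arange(total),
    )
    return session, StageAnnotation(segments=segments, trigger_side=config.trigger_side)


def generate_cohort(spec: CohortSpec) -> list[tuple[MarkerTrajectorySet, StageAnnotation]]:
    """Generate ``n_subjects`` sessions with jittered dynamics.

    The trigger side alternates left, right, left, ... across subjects.
    Between-subject jitter multiplies every amplitude and oscillation
    frequency by an independent factor in 1 ± jitter.
    """
    out = []
    for i in range(spec.n_subjects):
        rng = _rng(spec.seed, i, 9)  # purpose 9: subject-level jitter draws
        jit = spec.between_subject_jitter
        cfg = replace(
            spec.base_config,
            trigger_side="left" if i % 2 == 0 else "right",
            amplitude_scale=float(1.0 + jit * rng.uniform(-1, 1)),
            frequency_scale=float(1.0 + jit * rng.uniform(-1, 1)),
            seed=int(_rng(spec.seed, i, 0).integers(0, 2**31 - 1)),
            subject_id=f"S{i + 1}",
        )
        out.append(generate_session(cfg))
    return out


def inject_missing(
    session: MarkerTrajectorySet,
    burst_rate: float,
    burst_len_range: tuple[int, int],
    seed: int,
) -> MarkerTrajectorySet:
    """Set contiguous whole-marker runs to missing (occlusion bursts).

    Per marker, the number of bursts is Poisson with mean
    ``burst_rate × n_frames / 1000``; each burst length is uniform over
    ``burst_len_range`` (inclusive).  Expected missing fraction is
    approximately ``burst_rate × mean(burst_len) / 1000``.  The input
    session is not modified.
    """
    if burst_rate < 0:
        raise ConfigError("burst_rate must be nonnegative")
    out = session.copy()
    if burst_rate == 0:
        return out
    rng = _rng(seed, 1)
    lo, hi = burst_len_range
    n = session.n_frames
    for j in range(session.n_markers):
        n_bursts = rng.poisson(burst_rate * n / 1000.0)
        for _ in range(n_bursts):
            length = int(rng.integers(lo, hi + 1))
            s = int(rng.integers(0, max(1, n - length)))
            out.positions[s : s + length, j, :] = np.nan
    return out


def inject_outliers(
    session: MarkerTrajectorySet,
    rate: float,
    magnitude_sd_mult: float,
    seed: int,
) -> tuple[MarkerTrajectorySet, np.ndarray]:
    """Displace isolated samples by ±mult×σ of their own coordinate stream.

    Returns the contaminated copy and the boolean ground-truth mask
    (frames × markers × 3).  ``rate`` is the expected number of spikes per
    1000 frames per coordinate stream.
    """
    if rate < 0:
        raise ConfigError("rate must be nonnegative")
    out = session.copy()
    mask = np.zeros(session.positions.shape, dtype=bool)
    if rate == 0:
        return out, mask
    rng = _rng(seed, 2)
    n = session.n_frames
    for j in range(session.n_markers):
        for ax in range(3):
            stream = out.positions[:, j, ax]
            observed = np.isfinite(stream)
            sd = float(np.nanstd(stream))
            k = min(rng.poisson(rate * n / 1000.0), observed.sum())
            if k == 0 or sd == 0:
                continue
            idx = rng.choice(np.flatnonzero(observed), size=k, replace=False)
            signs = rng.choice([-1.0, 1.0], size=k)
            stream[idx] += signs * magnitude_sd_mult * sd
            mask[idx, j, ax] = True
    return out, mask
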