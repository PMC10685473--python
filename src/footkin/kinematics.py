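"""Filtering, intersegmental Cardan angles, MLA geometry and gait-cycle tools.

Intersegmental rotation is measured distal-relative-to-proximal and
decomposed with the x-z-y Cardan sequence: the first rotation (about the
segment x-axis) is sagittal dorsi/plantar flexion, the second (about z)
frontal inversion/eversion, the third (about y) transverse
internal/external rotation.  Raw Cardan angles follow the right-handed
frame axes; the clinical sign conventions (dorsiflexion / inversion /
internal-rotation positive, or the plantarflexion-positive variant used
for kinetics) are applied by an explicit per-side sign map at output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .frames import (
    JOINTS,
    SegmentPoseSeries,
    compute_virtual_markers,
    load_segment_definitions,
    pose_time_series,
)
from .trial_io import (
    ForcePlateRecord,
    MarkerTrajectories,
    TrialConfig,
    default_registry,
    resample_force_to_markers,
)

__all__ = [
    "JointAngleSeries",
    "MLASeries",
    "GaitEvents",
    "butterworth_lowpass",
    "cardan_xzy",
    "compose_cardan_xzy",
    "relative_rotation",
    "mla_ratio",
    "detect_gait_events",
    "normalize_gait_cycle",
    "joint_angle_pipeline",
    "angle_sign_map",
    "PLANES",
]

#: Reported angle planes, in Cardan extraction order.
PLANES = ("sagittal", "frontal", "transverse")

#: Human-readable motion labels per joint and plane (hallux frontal-plane
#: output is conventionally labelled abduction/adduction).
MOTION_LABELS = {
    "sagittal": "dorsiflexion/plantarflexion",
    "frontal": "inversion/eversion",
    "transverse": "internal/external rotation",
    ("mtp1", "transverse"): "abduction/adduction",
}


@dataclass
class JointAngleSeries:
    """One joint's angles (deg) over time; 101 samples when normalized."""

    joint: str
    sagittal: np.ndarray
    frontal: np.ndarray
    transverse: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.normalized and len(self.sagittal) != 101:
            raise ValueError("normalized series must hold exactly 101 samples")

    def plane(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class MLASeries:
    """Medial longitudinal arch geometry over time (mm and dimensionless)."""

    length: np.ndarray
    height: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        return self.height / self.length


@dataclass
class GaitEvents:
    """Heel-strike, toe-off and cycle-end frame indices at the marker rate."""

    heel_strike: int
    toe_off: int
    cycle_end: int
    extrapolated_end: bool = False

    def __post_init__(self) -> None:
        if not (self.heel_strike < self.toe_off < self.cycle_end):
            raise ValueError("events must satisfy heel_strike < toe_off < cycle_end")

    @property
    def stance_fraction(self) -> float:
        return (self.toe_off - self.heel_strike) / (self.cycle_end - self.heel_strike)


def butterworth_lowpass(series: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase low-pass Butterworth (4th-order effective) per column.

    Implemented as a 2nd-order filter run forward and backward, which
    squares the magnitude response (effective order 4) and cancels phase
    lag, so event timing is not shifted.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < cutoff < rate / 2:
        raise ValueError(f"cutoff must lie in (0, {rate / 2}) Hz")
    sos = signal.butter(2, cutoff, fs=rate, output="sos")
    padlen = 3 * 2 * 2  # 3 * order per pass direction
    minimum = padlen + 1
    if len(series) < minimum:
        raise ValueError(f"series too short to filter: need at least {minimum} samples")
    return signal.sosfiltfilt(sos, series, axis=0)


def _filter_markers(traj: MarkerTrajectories, cutoff: float | None) -> MarkerTrajectories:
    if cutoff is None:
        return traj
    out = traj.copy()
    for label in out.labels:
        if out.gaps[label].any():
            continue  # gapped markers are left unfiltered (and unusable downstream)
        out.positions[label] = butterworth_lowpass(out.positions[label], cutoff, out.rate)
    return out


# ---------------------------------------------------------------------------
# Cardan x-z-y


def compose_cardan_xzy(alpha_x: float, beta_z: float, gamma_y: float) -> np.ndarray:
    """Rotation matrix Rx(alpha) @ Rz(beta) @ Ry(gamma), angles in degrees."""
    a, b, g = np.deg2rad([alpha_x, beta_z, gamma_y])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    rz = np.array([[cb, -sb, 0], [sb, cb, 0], [0, 0, 1]])
    ry = np.array([[cg, 0, sg], [0, 1, 0], [-sg, 0, cg]])
    return rx @ rz @ ry


def cardan_xzy(R: np.ndarray, check: bool = True) -> np.ndarray:
    """Extract x-z-y Cardan angles (deg) from rotation matrices.

    Accepts a single (3, 3) matrix or an (n, 3, 3) stack and returns
    (3,) or (n, 3) angles (alpha_x, beta_z, gamma_y) such that
    ``R = Rx(alpha) @ Rz(beta) @ Ry(gamma)``.  Near the |beta| = 90 deg
    gimbal singularity a warning is emitted and angles are still returned.
    """
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    Rs = R[None] if single else R
    finite = np.isfinite(Rs).all(axis=(1, 2))
    if check and finite.any():
        RtR = np.einsum("nij,nik->njk", Rs[finite], Rs[finite])
        if not np.allclose(RtR, np.eye(3), atol=1e-6):
            raise ValueError("input is not orthonormal")
        if not np.allclose(np.linalg.det(Rs[finite]), 1.0, atol=1e-6):
            raise ValueError("input determinant is not +1")
    # R[0,1] = -sin(beta); R[1,1]=cos(a)cos(b), R[2,1]=sin(a)cos(b);
    # R[0,0]=cos(b)cos(g), R[0,2]=cos(b)sin(g)
    sb = np.clip(-Rs[:, 0, 1], -1.0, 1.0)
    beta = np.arcsin(sb)
    alpha = np.arctan2(Rs[:, 2, 1], Rs[:, 1, 1])
    gamma = np.arctan2(Rs[:, 0, 2], Rs[:, 0, 0])
    if finite.any() and (np.abs(np.abs(beta[finite]) - np.pi / 2) < np.deg2rad(0.1)).any():
        import warnings

        warnings.warn("Cardan x-z-y extraction near gimbal lock (|beta_z| ~ 90 deg)",
                      stacklevel=2)
    out = np.degrees(np.stack([alpha, beta, gamma], axis=1))
    out[~finite] = np.nan
    return out[0] if single else out


def relative_rotation(child: SegmentPoseSeries | np.ndarray,
                      parent: SegmentPoseSeries | np.ndarray) -> np.ndarray:
    """Distal-relative-to-proximal orientation series: R = R_parent^T R_child."""
    Rc = child.orientation if isinstance(child, SegmentPoseSeries) else np.asarray(child)
    Rp = parent.orientation if isinstance(parent, SegmentPoseSeries) else np.asarray(parent)
    if Rc.shape != Rp.shape:
        raise ValueError("child and parent orientation series must have equal shape")
    return np.einsum("nji,njk->nik", Rp, Rc)


# ---------------------------------------------------------------------------
# MLA


def mla_ratio(BC: np.ndarray, MTH1: np.ndarray, NV: np.ndarray) -> MLASeries:
    """Medial longitudinal arch length, height and height/length ratio.

    Length is the BC-to-1MTH distance; height is the perpendicular
    distance from NV to the BC-1MTH line.
    """
    BC = np.atleast_2d(np.asarray(BC, dtype=float))
    MTH1 = np.atleast_2d(np.asarray(MTH1, dtype=float))
    NV = np.atleast_2d(np.asarray(NV, dtype=float))
    axis = MTH1 - BC
    length = np.linalg.norm(axis, axis=1)
    if np.nanmin(length) < 1e-9:
        raise ValueError("degenerate MLA: BC and 1MTH coincide")
    u = axis / length[:, None]
    v = NV - BC
    height = np.linalg.norm(v - (np.sum(v * u, axis=1)[:, None]) * u, axis=1)
    return MLASeries(length=length, height=height)


# ---------------------------------------------------------------------------
# events and normalization


def detect_gait_events(fp: ForcePlateRecord, threshold: float = 20.0,
                       hysteresis: float = 5.0,
                       default_stance_fraction: float = 0.60) -> GaitEvents:
    """Locate heel strike / toe off / cycle end from the vertical force.

    Heel strike is the first sample where |F_vertical| rises above the
    threshold; toe off the first subsequent fall below threshold minus the
    hysteresis band.  The cycle ends at the next ipsilateral heel strike
    if the record contains one, otherwise it is extrapolated from the
    default stance fraction (stance is ~60% of the cycle on average).
    """
    fv = np.abs(fp.vertical_force)
    above = fv > threshold
    if not above.any():
        raise ValueError("no foot contact found above threshold")
    hs = int(np.argmax(above))
    below = fv[hs:] < (threshold - hysteresis)
    if not below.any():
        raise ValueError("no toe off found: contact never ends")
    to = hs + int(np.argmax(below))
    rising_again = above[to:]
    if rising_again.any():
        end = to + int(np.argmax(rising_again))
        extrapolated = False
    else:
        end = hs + int(round((to - hs) / default_stance_fraction))
        extrapolated = True
    end = min(end, fp.n_samples - 1) if not extrapolated else end
    return GaitEvents(heel_strike=hs, toe_off=to, cycle_end=end,
                      extrapolated_end=extrapolated)


def normalize_gait_cycle(series: np.ndarray, events: GaitEvents) -> np.ndarray:
    """Linearly re-sample one gait cycle onto 101 points (0..100% of cycle)."""
    series = np.asarray(series, dtype=float)
    hs, end = events.heel_strike, events.cycle_end
    if end - hs < 2:
        raise ValueError("cycle must span at least 2 frames")
    if end > len(series) - 1:
        raise ValueError(f"cycle end frame {end} beyond series length {len(series)}")
    window = series[hs:end + 1]
    if not np.isfinite(window).all():
        raise ValueError("gaps inside the gait cycle; refusing to interpolate across them")
    grid = hs + (end - hs) * np.linspace(0.0, 1.0, 101)
    frames = np.arange(hs, end + 1, dtype=float)
    if series.ndim == 1:
        return np.interp(grid, frames, window)
    return np.column_stack([np.interp(grid, frames, window[:, k])
                            for k in range(series.shape[1])])


# ---------------------------------------------------------------------------
# sign conventions and full pipeline


def angle_sign_map(side: str, convention: str = "dorsiflexion_positive") -> np.ndarray:
    """Signs turning raw Cardan angles into clinical conventions.

    ``dorsiflexion_positive``: dorsiflexion, inversion and internal rotation (or
    hallux abduction) positive -- the convention used for angle curves.
    ``plantarflexion_positive``: plantarflexion, inversion, internal rotation
    positive -- the convention used for moment curves; the two differ only
    in the sagittal plane.

    The sagittal factor is side-independent (mirroring a motion leaves
    the raw x-rotation angle unchanged), while the frontal and
    transverse factors flip with side; a mirrored left-side trial
    therefore reports the same clinical curves as its right-side twin.
    """
    if convention not in ("dorsiflexion_positive", "plantarflexion_positive"):
        raise ValueError(f"unknown convention {convention!r}")
    s = 1.0 if side == "right" else -1.0
    sag = -1.0 if convention == "dorsiflexion_positive" else 1.0
    return np.array([sag, s, -s])


@dataclass
class AnglePipelineResult:
    """Everything the kinematic pipeline produces for one trial."""

    angles: dict[str, JointAngleSeries]          # normalized, clinical signs
    raw_angles: dict[str, np.ndarray]            # per-frame raw Cardan triples
    mla: MLASeries                               # normalized (101) series
    mla_raw: MLASeries                           # per-frame series
    events: GaitEvents
    poses: dict[str, SegmentPoseSeries]
    markers: MarkerTrajectories                  # filtered, virtuals appended
    force: ForcePlateRecord                      # resampled to marker rate
    side: str = "right"


def joint_angle_pipeline(traj: MarkerTrajectories, fp: ForcePlateRecord,
                         config: TrialConfig, convention: str = "dorsiflexion_positive",
                         static_offsets: dict[str, np.ndarray] | None = None,
                         ) -> AnglePipelineResult:
    """Filter, build frames, extract joint angles and MLA, and normalize.

    Stages: marker low-pass -> virtual markers -> segment frames ->
    distal-to-proximal rotations -> Cardan x-z-y angles -> gait events
    (from the vertical force) -> 101-point cycle normalization.

    ``static_offsets`` optionally maps joint name -> (sagittal, frontal,
    transverse) reference angles (deg, clinical convention, e.g. from a
    quiet-standing calibration trial) subtracted from the reported
    curves.  Off by default: raw relative angles are reported.
    """
    registry = default_registry(config.side)
    absent = [m for m in registry.required if m not in traj.positions]
    if absent:
        from .trial_io import MissingMarkerError

        raise MissingMarkerError(absent)
    try:
        filtered = _filter_markers(traj, config.filter_cutoff)
    except ValueError as exc:
        raise ValueError(f"filtering stage: {exc}") from exc
    try:
        markers = compute_virtual_markers(filtered, registry)
    except KeyError as exc:
        raise KeyError(f"virtual-marker stage: {exc}") from exc
    defs = load_segment_definitions(side=config.side)
    try:
        poses = pose_time_series(markers, defs)
    except Exception as exc:
        raise type(exc)(f"frame stage: {exc}") from exc
    fp60 = resample_force_to_markers(fp, markers.rate, config.contact_threshold)
    try:
        events = detect_gait_events(fp60, config.contact_threshold)
    except ValueError as exc:
        raise ValueError(f"event stage: {exc}") from exc

    signs = angle_sign_map(config.side, convention)
    angles: dict[str, JointAngleSeries] = {}
    raw: dict[str, np.ndarray] = {}
    for joint, (prox, dist) in JOINTS.items():
        rel = relative_rotation(poses[dist], poses[prox])
        triples = cardan_xzy(rel, check=False)
        raw[joint] = triples
        try:
            norm = normalize_gait_cycle(triples, events)
        except ValueError as exc:
            raise ValueError(f"normalization stage ({joint}): {exc}") from exc
        clinical = norm * signs
        if static_offsets and joint in static_offsets:
            clinical = clinical - np.asarray(static_offsets[joint], dtype=float)
        angles[joint] = JointAngleSeries(
            joint=joint, sagittal=clinical[:, 0], frontal=clinical[:, 1],
            transverse=clinical[:, 2], normalized=True,
        )
    mla_raw = mla_ratio(markers.positions["BC"], markers.positions["1MTH"],
                        markers.positions["NV"])
    mla = MLASeries(
        length=normalize_gait_cycle(mla_raw.length, events),
        height=normalize_gait_cycle(mla_raw.height, events),
    )
    return AnglePipelineResult(
        angles=angles, raw_angles=raw, mla=mla, mla_raw=mla_raw, events=events,
        poses=poses, markers=markers, force=fp60, side=config.side,
    )
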