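"""Anthropometrics, Newton-Euler inverse dynamics and CPcross masking.

The foot is modelled as a chain of four rigid segments (hindfoot, midfoot,
forefoot, hallux) articulating at the ankle, Chopart, Lisfranc and first
metatarsophalangeal joints.  A single force plate measures the total
ground reaction; at each joint the net intersegmental force and moment
are obtained from the Newton-Euler equations of the distal free body
(all segments distal to the joint), with the full plate load applied to
that free body and the segments' inertial terms included.

Because a single plate cannot partition load between segments that are
simultaneously grounded, the CPcross convention is provided: a joint's
kinetics are reported only from the moment the centre of pressure has
crossed anterior to that joint's centre, which is when the distal free
body plausibly carries the whole plate load.

Units: inputs in mm/N/N*mm (lab convention); this module converts to SI
internally.  Moments are reported mass-normalized (N*m/kg), powers in
W/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .frames import JOINTS, SegmentPoseSeries
from .kinematics import GaitEvents, normalize_gait_cycle
from .trial_io import ForcePlateRecord

__all__ = [
    "AnthropometricModel",
    "SegmentInertialState",
    "JointKineticsSeries",
    "build_anthropometrics",
    "segment_inertial_state",
    "inverse_dynamics",
    "joint_power",
    "cpcross_mask",
    "moment_sign_map",
    "FOOT_MASS_FRACTION",
    "TOE_VOLUME_FRACTION",
    "RADII_OF_GYRATION",
    "GRAVITY",
]

#: Foot mass as a fraction of body mass (segment inertia literature).
FOOT_MASS_FRACTION = 0.0137
#: Toe (hallux) volume fraction tau of the whole foot (cadaver volumetry).
TOE_VOLUME_FRACTION = 0.08
#: Radii of gyration as fractions of segment long-axis length, per local
#: axis (x medio-lateral, y vertical, z longitudinal).
RADII_OF_GYRATION = (0.257, 0.245, 0.124)
#: Gravitational acceleration, m/s^2, along -Y (lab vertical).
GRAVITY = 9.81

#: Segments distal to each joint (the free body the joint load acts on).
DISTAL_SEGMENTS = {
    "ankle": ("hindfoot", "midfoot", "forefoot", "hallux"),
    "chopart": ("midfoot", "forefoot", "hallux"),
    "lisfranc": ("forefoot", "hallux"),
    "mtp1": ("hallux",),
}

#: The segment whose Table-style frame Origin serves as the joint centre.
JOINT_CENTER_SEGMENT = {
    "ankle": "midfoot",    # midfoot origin == V_Ankle_JC
    "chopart": "midfoot",  # shares the ankle-joint-centre origin
    "lisfranc": "forefoot",  # V_MidNC
    "mtp1": "hallux",      # 1MTH
}


@dataclass(frozen=True)
class AnthropometricModel:
    """Segment masses and inertial parameters for the four-segment foot.

    The whole foot receives ``foot_mass_fraction`` of body mass.  Segment
    masses follow the volumetric apportioning rule: the hindfoot is half
    of the non-toe foot volume, midfoot and forefoot a quarter each, and
    the hallux the toe fraction tau -- all at homogeneous density.
    Centres of mass sit halfway along each segment's long axis; moments
    of inertia use per-axis radii of gyration expressed as fractions of
    segment length.
    """

    body_mass: float
    foot_mass_fraction: float = FOOT_MASS_FRACTION
    toe_volume_fraction: float = TOE_VOLUME_FRACTION
    radii_of_gyration: tuple[float, float, float] = RADII_OF_GYRATION
    segment_masses: dict[str, float] = field(default_factory=dict)

    @property
    def foot_mass(self) -> float:
        return self.body_mass * self.foot_mass_fraction


def build_anthropometrics(body_mass: float, **overrides) -> AnthropometricModel:
    """Apportion foot-segment masses from body mass.

    Overrides: ``foot_mass_fraction``, ``toe_volume_fraction`` (tau, must
    lie in (0, 0.5); 0 is accepted for a toeless limiting model),
    ``radii_of_gyration``.
    """
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    fmf = float(overrides.pop("foot_mass_fraction", FOOT_MASS_FRACTION))
    tau = float(overrides.pop("toe_volume_fraction", TOE_VOLUME_FRACTION))
    radii = tuple(overrides.pop("radii_of_gyration", RADII_OF_GYRATION))
    if overrides:
        raise TypeError(f"unknown anthropometric overrides: {sorted(overrides)}")
    if not 0 <= tau < 0.5:
        raise ValueError("toe volume fraction tau must lie in [0, 0.5)")
    if not all(0 < r < 1 for r in radii):
        raise ValueError("radii of gyration must be fractions in (0, 1)")
    foot = body_mass * fmf
    masses = {
        "hindfoot": 0.5 * (1.0 - tau) * foot,
        "midfoot": 0.25 * (1.0 - tau) * foot,
        "forefoot": 0.25 * (1.0 - tau) * foot,
        "hallux": tau * foot,
    }
    return AnthropometricModel(
        body_mass=body_mass, foot_mass_fraction=fmf, toe_volume_fraction=tau,
        radii_of_gyration=radii, segment_masses=masses,
    )


@dataclass
class SegmentInertialState:
    """COM kinematics and angular state of one segment, SI units.

    com/com_vel/com_acc in m, m/s, m/s^2 (lab frame); omega/alpha in
    rad/s, rad/s^2 (lab frame); inertia is the constant diagonal tensor
    in the segment frame, kg*m^2.
    """

    name: str
    mass: float
    com: np.ndarray
    com_vel: np.ndarray
    com_acc: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    orientation: np.ndarray
    inertia: np.ndarray

    def omega_segment(self) -> np.ndarray:
        return np.einsum("nji,nj->ni", self.orientation, self.omega)

    def alpha_segment(self) -> np.ndarray:
        return np.einsum("nji,nj->ni", self.orientation, self.alpha)


def _angular_velocity(R: np.ndarray, rate: float) -> np.ndarray:
    """Lab-frame angular velocity from an orientation series: skew(Rdot R^T)."""
    Rdot = np.gradient(R, 1.0 / rate, axis=0)
    W = np.einsum("nij,nkj->nik", Rdot, R)  # Rdot @ R^T
    return np.stack([W[:, 2, 1] - W[:, 1, 2],
                     W[:, 0, 2] - W[:, 2, 0],
                     W[:, 1, 0] - W[:, 0, 1]], axis=1) * 0.5


def segment_inertial_state(pose: SegmentPoseSeries, anthro: AnthropometricModel,
                           rate: float) -> SegmentInertialState:
    """Differentiate one segment's pose into COM and angular kinematics.

    COM is the midpoint of the segment long axis; linear and angular
    derivatives use central finite differences at the marker rate (the
    angular velocity from the skew part of Rdot R^T).
    """
    if pose.n_frames < 5:
        raise ValueError("analysis window must span at least 5 frames")
    if not pose.valid.all():
        raise ValueError(f"segment {pose.name!r}: pose series has gaps")
    mass = anthro.segment_masses[pose.name]
    com = 0.5 * (pose.origin + pose.axis_end) * 1e-3  # mm -> m
    dt = 1.0 / rate
    vel = np.gradient(com, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    omega = _angular_velocity(pose.orientation, rate)
    alpha = np.gradient(omega, dt, axis=0)
    length_m = float(np.mean(pose.long_axis_length)) * 1e-3
    radii = np.asarray(anthro.radii_of_gyration)
    inertia = np.diag(mass * (radii * length_m) ** 2)
    return SegmentInertialState(
        name=pose.name, mass=mass, com=com, com_vel=vel, com_acc=acc,
        omega=omega, alpha=alpha, orientation=pose.orientation, inertia=inertia,
    )


@dataclass
class JointKineticsSeries:
    """Mass-normalized joint moments and power over the gait cycle.

    moment: (101, 3) clinical-plane components (sagittal, frontal,
    transverse; N*m/kg).  moment_lab: (101, 3) lab-frame vector for
    composition checks.  power: (101,) W/kg.  masked: per-sample CPcross
    visibility flag (True = hidden); crossing_index is the percent-cycle
    at which the CoP crossed anterior to the joint centre (None if
    never).
    """

    joint: str
    moment: np.ndarray
    moment_lab: np.ndarray
    power: np.ndarray
    masked: np.ndarray | None = None
    crossing_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.moment) != 101 or len(self.power) != 101:
            raise ValueError("normalized kinetics series must hold 101 samples")
        if self.masked is None:
            self.masked = np.zeros(101, dtype=bool)


def joint_power(moment_lab: np.ndarray, omega_child: np.ndarray,
                omega_parent: np.ndarray, body_mass: float) -> np.ndarray:
    """Joint power P = M . (omega_child - omega_parent) / body mass (W/kg).

    All inputs must share one frame (the lab frame in the pipeline).
    """
    moment_lab = np.asarray(moment_lab, dtype=float)
    omega_child = np.asarray(omega_child, dtype=float)
    omega_parent = np.asarray(omega_parent, dtype=float)
    if not (moment_lab.shape == omega_child.shape == omega_parent.shape):
        raise ValueError("moment and angular-velocity series must share shape/frame")
    return np.einsum("ni,ni->n", moment_lab, omega_child - omega_parent) / body_mass


def moment_sign_map(side: str, convention: str = "plantarflexion_positive") -> np.ndarray:
    """Signs turning anatomical moment components into clinical conventions.

    Matches the angle sign map: the sagittal factor depends only on the
    convention (+1 plantarflexion-positive, -1 dorsiflexion-positive)
    while frontal and transverse flip with side, so mirrored trials
    report identical clinical moment curves.
    """
    from .kinematics import angle_sign_map

    return angle_sign_map(side, convention)


def _external_load_si(fp: ForcePlateRecord, threshold: float):
    """Force (N), CoP (m) and free vertical moment vector (N*m) per frame.

    Outside contact the external load is zero.  Inside contact a missing
    CoP is an error (the moment arm would be undefined).
    """
    loaded = np.abs(fp.vertical_force) >= threshold
    if (loaded & ~fp.cop_valid).any():
        bad = int(np.argmax(loaded & ~fp.cop_valid))
        raise ValueError(f"CoP missing at loaded sample {bad} (|Fv| above threshold)")
    force = np.where(loaded[:, None], fp.force, 0.0)
    cop_m = np.where(loaded[:, None], fp.cop * 1e-3, 0.0)
    tz_vec = np.zeros((fp.n_samples, 3))
    tz_vec[:, 1] = np.where(loaded, fp.tz * 1e-3, 0.0)  # N*mm -> N*m
    return force, cop_m, tz_vec, loaded


def inverse_dynamics(poses: dict[str, SegmentPoseSeries], anthro: AnthropometricModel,
                     fp: ForcePlateRecord, events: GaitEvents, rate: float,
                     contact_threshold: float = 20.0, side: str = "right",
                     convention: str = "plantarflexion_positive",
                     states: dict[str, SegmentInertialState] | None = None,
                     ) -> dict[str, JointKineticsSeries]:
    """Net joint moments and powers for the four foot joints (unmasked).

    For joint J with centre c_J and distal segment set D(J):

        M_J = sum_{i in D(J)} [ R_i (I_i a_i + w_i x I_i w_i) +
                                (com_i - c_J) x m_i (a_i - g) ]
              - (CoP - c_J) x F_grf  -  T_free

    with the full single-plate ground reaction applied to every joint's
    distal free body.  Moments are resolved into the proximal segment's
    anatomical axes, mass-normalized, and signed per the clinical moment
    convention (plantarflexion / inversion / internal rotation positive).
    """
    from .frames import load_segment_definitions

    if states is None:
        states = {
            name: segment_inertial_state(poses[name], anthro, rate)
            for name in ("hindfoot", "midfoot", "forefoot", "hallux")
        }
    shank_omega = _angular_velocity(poses["shank"].orientation, rate)
    force, cop_m, tz_vec, _ = _external_load_si(fp, contact_threshold)
    g_vec = np.array([0.0, -GRAVITY, 0.0])
    defs = load_segment_definitions(side=side)
    signs = moment_sign_map(side, convention)

    out: dict[str, JointKineticsSeries] = {}
    for joint, (prox, _dist) in JOINTS.items():
        center = poses[JOINT_CENTER_SEGMENT[joint]].origin * 1e-3  # m
        n = len(center)
        M = np.zeros((n, 3))
        for seg in DISTAL_SEGMENTS[joint]:
            st = states[seg]
            ws = st.omega_segment()
            als = st.alpha_segment()
            euler_seg = als @ st.inertia.T + np.cross(ws, ws @ st.inertia.T)
            euler_lab = np.einsum("nij,nj->ni", st.orientation, euler_seg)
            M += euler_lab
            M += np.cross(st.com - center, st.mass * (st.com_acc - g_vec))
        M -= np.cross(cop_m - center, force)
        M -= tz_vec
        # powers: relative angular velocity of the joint's own child segment
        child = JOINTS[joint][1]
        omega_parent = shank_omega if prox == "shank" else states[prox].omega
        P = joint_power(M, states[child].omega, omega_parent, anthro.body_mass)

        Mn = normalize_gait_cycle(M, events) / anthro.body_mass
        Pn = normalize_gait_cycle(P, events)
        # resolve into the proximal segment's anatomical axes at each sample
        Rp = normalize_orientation_series(poses[prox].orientation, events)
        axes = _anatomical_axis_matrix(defs[prox].anatomical_axes)
        local_axes = np.einsum("nij,jk->nik", Rp, axes)  # columns: ml, ap, vert in lab
        comp = np.einsum("nji,nj->ni", local_axes, Mn)   # components on those axes
        clinical = comp * signs  # (ml, ap, vert) -> (sagittal, frontal, transverse)
        out[joint] = JointKineticsSeries(
            joint=joint, moment=clinical, moment_lab=Mn, power=Pn,
        )
    return out


def _anatomical_axis_matrix(mapping: dict[str, str]) -> np.ndarray:
    """Columns (ml, ap, vert) as signed local-axis unit vectors."""
    basis = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
             "z": np.array([0, 0, 1.0])}
    cols = []
    for key in ("ml", "ap", "vert"):
        token = mapping[key]
        sign = -1.0 if token.startswith("-") else 1.0
        cols.append(sign * basis[token.lstrip("+-")])
    return np.column_stack(cols)


def normalize_orientation_series(R: np.ndarray, events: GaitEvents) -> np.ndarray:
    """Nearest-frame sampling of an orientation series onto the 101-pt grid.

    Orientations are not linearly interpolable; nearest-frame sampling is
    adequate for resolving moment components (axes vary slowly at 60 Hz).
    """
    hs, end = events.heel_strike, events.cycle_end
    grid = hs + (end - hs) * np.linspace(0.0, 1.0, 101)
    idx = np.clip(np.round(grid).astype(int), 0, len(R) - 1)
    return R[idx]


def cpcross_mask(kinetics: dict[str, JointKineticsSeries], fp: ForcePlateRecord,
                 poses: dict[str, SegmentPoseSeries], events: GaitEvents,
                 progression_axis: np.ndarray | None = None,
                 ) -> dict[str, JointKineticsSeries]:
    """Apply CPcross visibility masking to normalized joint kinetics.

    For each joint the crossing index is the first percent-cycle sample at
    which the (valid) centre of pressure lies anterior to the joint centre
    along the progression axis; samples before it are flagged masked.
    Values are never altered, only flagged.  If the CoP never crosses a
    joint, that joint is fully masked and a warning is emitted.

    The progression axis defaults to the horizontal displacement of the
    heel (BC-derived hindfoot origin) over stance.
    """
    import warnings

    hs, to, end = events.heel_strike, events.toe_off, events.cycle_end
    if progression_axis is None:
        heel = poses["hindfoot"].origin
        disp = heel[min(to, len(heel) - 1)] - heel[hs]
        disp[1] = 0.0  # horizontal progression only
        norm = np.linalg.norm(disp)
        if norm < 1e-9:
            raise ValueError("cannot estimate progression axis: heel does not advance")
        progression_axis = disp / norm
    progression_axis = np.asarray(progression_axis, dtype=float)

    grid = hs + (end - hs) * np.linspace(0.0, 1.0, 101)
    t_in = np.arange(fp.n_samples, dtype=float)
    cop = np.column_stack([
        np.interp(grid, t_in[fp.cop_valid], fp.cop[fp.cop_valid, k])
        for k in range(3)
    ])
    valid = np.interp(grid, t_in, fp.cop_valid.astype(float)) >= 1.0 - 1e-9

    out: dict[str, JointKineticsSeries] = {}
    for joint, series in kinetics.items():
        center = normalize_position_series(poses[JOINT_CENTER_SEGMENT[joint]].origin,
                                           events)
        ahead = valid & (np.einsum("ni,i->n", cop - center, progression_axis) > 0)
        if ahead.any():
            k = int(np.argmax(ahead))
            masked = np.zeros(101, dtype=bool)
            masked[:k] = True
            crossing = k
        else:
            warnings.warn(f"CoP never crosses anterior to {joint}; fully masked",
                          stacklevel=2)
            masked = np.ones(101, dtype=bool)
            crossing = None
        out[joint] = replace(series, masked=masked, crossing_index=crossing)
    return out


def normalize_position_series(pos: np.ndarray, events: GaitEvents) -> np.ndarray:
    """Linear re-sampling of a position series onto the 101-point grid."""
    return normalize_gait_cycle(pos, events)
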