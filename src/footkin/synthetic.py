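"""Forward model of a walking trial for the four-segment foot.

The generator animates a rigid shank plus the four foot segments with
prescribed joint-angle waveforms, attaches the marker set rigidly to the
segments, and fabricates a plausible single-plate ground reaction
(double-hump vertical profile, heel-to-toe centre-of-pressure path).
Everything the measurement pipeline is supposed to recover is stored as
ground truth, so the full pipeline can be validated as the inverse of a
known forward model.

Model-consistency note: the forefoot and hallux frames take their Plane
marker from the parent segment (NV sits on the midfoot, 23T on the
forefoot), so the long-axis twist of those two segments is not an
independent degree of freedom of the marker model.  The generator
realises prescribed Lisfranc and first-MTP rotations through the same
plane projection the frame construction implies and records the realised
rotations as ground truth; for the ankle and Chopart joints the realised
rotation equals the prescription exactly.

The generator prescribes kinematics and ground reaction independently
(no forward-dynamics consistency between them); ground-truth joint
moments for validating the inverse dynamics are computed by a separate
plain-loop free-body implementation (:func:`naive_inverse_dynamics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from .frames import JOINTS, SegmentPoseSeries, build_segment_frame, load_segment_definitions
from .kinematics import angle_sign_map, cardan_xzy, compose_cardan_xzy
from .kinetics import DISTAL_SEGMENTS, JOINT_CENTER_SEGMENT, GRAVITY, AnthropometricModel
from .trial_io import ForcePlateRecord, MarkerTrajectories

__all__ = [
    "PlaneWave",
    "SyntheticTrialSpec",
    "GroundTruth",
    "generate_trial",
    "healthy_default_spec",
    "naive_inverse_dynamics",
    "NEUTRAL_GEOMETRY",
]

#: Neutral (standing) marker positions, right foot, mm.  Lab frame:
#: X anterior, Y up, Z to the subject's left; heel roughly at the origin.
NEUTRAL_GEOMETRY: dict[str, tuple[float, float, float]] = {
    "KNE_LAT": (-28.0, 470.0, -50.0),
    "KNE_MED": (-28.0, 470.0, 50.0),
    "MM": (-28.0, 78.0, 40.0),
    "LM": (-28.0, 72.0, -42.0),
    "TC": (-72.0, 58.0, 0.0),
    "BC": (-68.0, 15.0, 0.0),
    "TH": (15.0, 68.0, 8.0),
    "NV": (30.0, 52.0, 28.0),
    "CB": (25.0, 30.0, -38.0),
    "1MTH": (120.0, 30.0, 38.0),
    "5MTH": (105.0, 25.0, -48.0),
    "23T": (128.0, 32.0, -2.0),
    "HLX": (175.0, 22.0, 38.0),
}

#: Which generator segment each marker is rigidly attached to.
MARKER_ATTACHMENT = {
    "KNE_LAT": "shank", "KNE_MED": "shank",
    "MM": "hindfoot", "LM": "hindfoot", "TC": "hindfoot", "BC": "hindfoot",
    "TH": "midfoot", "NV": "midfoot", "CB": "midfoot",
    "1MTH": "forefoot", "5MTH": "forefoot", "23T": "forefoot",
    "HLX": "hallux",
}

#: Rotation pivot of each joint = the distal segment's frame Origin point.
JOINT_PIVOTS = {
    "ankle": "V_Ankle_JC",
    "chopart": "V_Ankle_JC",
    "lisfranc": "V_MidNC",
    "mtp1": "1MTH",
}


@dataclass
class PlaneWave:
    """One joint-plane waveform over the gait cycle.

    ``keypoints`` are (cycle fraction, unitless value) pairs interpolated
    by a periodic cubic spline, then rescaled so the range over the cycle
    equals ``rom`` (degrees) with zero mean; the segment's neutral-posture
    angle is added on top at generation time.  Values are in the clinical
    angle convention (dorsiflexion / inversion / internal-rotation or
    abduction positive).
    """

    rom: float
    keypoints: list[tuple[float, float]] = field(default_factory=list)

    def __call__(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float) % 1.0
        if self.rom == 0 or len(self.keypoints) < 2:
            return np.zeros_like(u)
        pts = sorted((float(a) % 1.0, float(b)) for a, b in self.keypoints)
        xs = np.array([p[0] for p in pts] + [pts[0][0] + 1.0])
        ys = np.array([p[1] for p in pts] + [pts[0][1]])
        spline = CubicSpline(xs, ys, bc_type="periodic")
        fine = spline(xs[0] + np.linspace(0, 1, 2001))
        rng = fine.max() - fine.min()
        if rng < 1e-12:
            return np.zeros_like(u)
        vals = spline(xs[0] + (u - xs[0]) % 1.0)
        return (vals - fine.mean()) * (self.rom / rng)


@dataclass
class SyntheticTrialSpec:
    """Full description of one synthetic walking trial."""

    stance_fraction: float = 0.60
    cadence: float = 111.8            # steps/min; cycle = 120/cadence s
    walking_speed: float = 1.22       # m/s
    body_mass: float = 64.0           # kg
    marker_noise_sd: float = 0.0      # mm, isotropic
    seed: int = 0
    side: str = "right"
    marker_rate: float = 60.0
    plate_rate: float = 1200.0
    lead_time: float = 0.15           # s before heel strike
    tail_time: float = 0.30           # s after the cycle ends
    shank_tilt_deg: float = 8.0
    vertical_bob_mm: float = 8.0
    geometry: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(NEUTRAL_GEOMETRY))
    waveforms: dict[str, dict[str, PlaneWave]] = field(default_factory=dict)
    # vertical GRF profile: BW * (p*sin(pi*u) + q*sin(3*pi*u)) over stance
    grf_p: float = 1.40
    grf_q: float = 0.45
    cop_shape_power: float = 0.7      # heel-to-toe progression exponent

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance fraction must lie in (0, 1)")
        if self.marker_noise_sd < 0:
            raise ValueError("marker noise SD must be non-negative")
        for seg in ("hindfoot", "midfoot", "forefoot"):
            pass  # geometry degeneracy is checked at generation time

    @property
    def cycle_duration(self) -> float:
        return 120.0 / self.cadence

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["geometry"] = {k: list(map(float, v)) for k, v in raw["geometry"].items()}
        raw["waveforms"] = {
            j: {p: {"rom": w["rom"],
                    "keypoints": [list(map(float, kp)) for kp in w["keypoints"]]}
               for p, w in planes.items()}
            for j, planes in raw["waveforms"].items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTrialSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["geometry"] = {k: tuple(v) for k, v in raw.get("geometry", {}).items()}
        raw["waveforms"] = {
            j: {p: PlaneWave(rom=w["rom"],
                             keypoints=[tuple(kp) for kp in w["keypoints"]])
               for p, w in planes.items()}
            for j, planes in raw.get("waveforms", {}).items()
        }
        return cls(**raw)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline should recover."""

    raw_angles: dict[str, np.ndarray]        # per-frame raw Cardan triples (deg)
    clinical_angles: dict[str, np.ndarray]   # per-frame, clinical sign convention
    prescribed_clinical: dict[str, np.ndarray]  # the input waveform evaluations
    poses: dict[str, SegmentPoseSeries]      # exact segment poses (no noise)
    heel_strike_time: float
    toe_off_time: float
    cycle_end_time: float
    stance_fraction: float
    cop_path: np.ndarray                     # (n_marker_frames, 3), NaN off-contact
    marker_rate: float


def _mirror_geometry(geometry: dict) -> dict:
    """Left-foot neutral geometry: mirror every marker across the sagittal plane."""
    return {label: (x, y, -z) for label, (x, y, z) in geometry.items()}


def _neutral_frames(points: dict[str, np.ndarray], side: str):
    """Segment frames of the neutral pose, via the model's own construction."""
    defs = load_segment_definitions(side=side)
    frames = {}
    for name, d in defs.items():
        frames[name] = build_segment_frame(
            points[d.origin_marker], points[d.long_axis_marker],
            points[d.plane_marker], d.rx, d.ry, d.rz,
        )
    return defs, frames


def _plane_projected_frame(origin: np.ndarray, z_dir: np.ndarray, plane_pt: np.ndarray,
                           rx: float, ry: float, rz: float) -> np.ndarray:
    """The frame the marker model can realise for a desired long-axis direction."""
    return build_segment_frame(origin, origin + z_dir, plane_pt, rx, ry, rz)


def generate_trial(spec: SyntheticTrialSpec):
    """Generate (MarkerTrajectories, ForcePlateRecord, GroundTruth)."""
    geometry = (dict(spec.geometry) if spec.side == "right"
                else _mirror_geometry(spec.geometry))
    pts0 = {k: np.asarray(v, dtype=float) for k, v in geometry.items()}
    pts0["V_Ankle_JC"] = 0.5 * (pts0["MM"] + pts0["LM"])
    pts0["V_MidNC"] = 0.5 * (pts0["NV"] + pts0["CB"])
    pts0["V_1_5MTH"] = 0.5 * (pts0["1MTH"] + pts0["5MTH"])
    pts0["V_Knee_JC"] = 0.5 * (pts0["KNE_MED"] + pts0["KNE_LAT"])
    defs, F0 = _neutral_frames(pts0, spec.side)

    T = spec.cycle_duration
    t_hs = spec.lead_time
    t_to = t_hs + spec.stance_fraction * T
    t_end = t_hs + T
    duration = t_end + spec.tail_time
    n_frames = int(np.floor(duration * spec.marker_rate)) + 1
    t = np.arange(n_frames) / spec.marker_rate
    u = (t - t_hs) / T  # cycle fraction; waveforms are periodic in u

    signs = angle_sign_map(spec.side, "dorsiflexion_positive")

    # neutral raw Cardan angles of each joint
    neutral_raw = {}
    for joint, (prox, dist) in JOINTS.items():
        neutral_raw[joint] = cardan_xzy(F0[prox].T @ F0[dist])

    # prescribed raw angle curves = neutral + clinical waveform mapped to raw
    raw_presc: dict[str, np.ndarray] = {}
    presc_clin: dict[str, np.ndarray] = {}
    for joint in JOINTS:
        planes = spec.waveforms.get(joint, {})
        clin = np.zeros((n_frames, 3))
        for k, plane in enumerate(("sagittal", "frontal", "transverse")):
            wave = planes.get(plane)
            if wave is not None:
                clin[:, k] = wave(u)
        presc_clin[joint] = clin
        raw_presc[joint] = neutral_raw[joint][None, :] + clin * signs[None, :]

    # shank trajectory: forward progression, slight bob, small sagittal tilt
    ankle0 = pts0["V_Ankle_JC"]
    tilt = np.deg2rad(spec.shank_tilt_deg) * np.sin(2 * np.pi * u)
    c, s = np.cos(tilt), np.sin(tilt)
    R_sh = np.zeros((n_frames, 3, 3))
    R_sh[:, 0, 0] = c
    R_sh[:, 0, 1] = -s
    R_sh[:, 1, 0] = s
    R_sh[:, 1, 1] = c
    R_sh[:, 2, 2] = 1.0
    drift = np.zeros((n_frames, 3))
    drift[:, 0] = spec.walking_speed * 1000.0 * t
    drift[:, 1] = spec.vertical_bob_mm * (1 - np.cos(4 * np.pi * u)) / 2
    ankle_jc = ankle0[None, :] + drift

    positions: dict[str, np.ndarray] = {}

    def attach(labels, pivot_now, pivot_0, R_body):
        for lab in labels:
            positions[lab] = pivot_now + np.einsum(
                "nij,j->ni", R_body, pts0[lab] - pivot_0)

    # shank: rotate about the ankle joint centre
    R_sh_body = np.einsum("nij,jk->nik", R_sh, np.eye(3))
    attach(("KNE_LAT", "KNE_MED"), ankle_jc, ankle0, R_sh_body)
    F_sh = np.einsum("nij,jk->nik", R_sh_body, F0["shank"])

    # hindfoot: exact realisation of the prescribed ankle rotation
    C_ankle = np.stack([compose_cardan_xzy(*a) for a in raw_presc["ankle"]])
    F_hf = np.einsum("nij,njk->nik", F_sh, C_ankle)
    R_hf_body = np.einsum("nij,kj->nik", F_hf, F0["hindfoot"])
    attach(("MM", "LM", "TC", "BC"), ankle_jc, ankle0, R_hf_body)

    # midfoot: pivot is also the ankle joint centre (its frame Origin)
    C_chop = np.stack([compose_cardan_xzy(*a) for a in raw_presc["chopart"]])
    F_mf = np.einsum("nij,njk->nik", F_hf, C_chop)
    R_mf_body = np.einsum("nij,kj->nik", F_mf, F0["midfoot"])
    attach(("TH", "NV", "CB"), ankle_jc, ankle0, R_mf_body)
    midnc = 0.5 * (positions["NV"] + positions["CB"])

    # forefoot: desired rotation, then plane projection through NV (midfoot)
    C_lis = np.stack([compose_cardan_xzy(*a) for a in raw_presc["lisfranc"]])
    F_ff_des = np.einsum("nij,njk->nik", F_mf, C_lis)
    d_ff = defs["forefoot"]
    L_ff = np.linalg.norm(pts0["V_1_5MTH"] - pts0["V_MidNC"])
    F_ff = np.stack([
        _plane_projected_frame(midnc[i], F_ff_des[i, :, 2] * L_ff, positions["NV"][i],
                               d_ff.rx, d_ff.ry, d_ff.rz)
        for i in range(n_frames)
    ])
    R_ff_body = np.einsum("nij,kj->nik", F_ff, F0["forefoot"])
    attach(("1MTH", "5MTH", "23T"), midnc, pts0["V_MidNC"], R_ff_body)

    # hallux: plane projection through 23T (forefoot)
    C_mtp = np.stack([compose_cardan_xzy(*a) for a in raw_presc["mtp1"]])
    F_hx_des = np.einsum("nij,njk->nik", F_ff, C_mtp)
    d_hx = defs["hallux"]
    L_hx = np.linalg.norm(pts0["HLX"] - pts0["1MTH"])
    F_hx = np.stack([
        _plane_projected_frame(positions["1MTH"][i], F_hx_des[i, :, 2] * L_hx,
                               positions["23T"][i], d_hx.rx, d_hx.ry, d_hx.rz)
        for i in range(n_frames)
    ])
    R_hx_body = np.einsum("nij,kj->nik", F_hx, F0["hallux"])
    attach(("HLX",), positions["1MTH"], pts0["1MTH"], R_hx_body)

    # ground-truth poses (exact, noise-free) using the model's frame origins
    frame_series = {"shank": F_sh, "hindfoot": F_hf, "midfoot": F_mf,
                    "forefoot": F_ff, "hallux": F_hx}
    origin_points = {"shank": "V_Knee_JC", "hindfoot": "BC", "midfoot": "V_Ankle_JC",
                     "forefoot": "V_MidNC", "hallux": "1MTH"}
    axis_points = {"shank": "V_Ankle_JC", "hindfoot": "V_Ankle_JC", "midfoot": "TH",
                   "forefoot": "V_1_5MTH", "hallux": "HLX"}
    virt = {"V_Ankle_JC": 0.5 * (positions["MM"] + positions["LM"]),
            "V_MidNC": midnc,
            "V_1_5MTH": 0.5 * (positions["1MTH"] + positions["5MTH"]),
            "V_Knee_JC": 0.5 * (positions["KNE_MED"] + positions["KNE_LAT"])}

    def point_series(name):
        return virt[name] if name in virt else positions[name]

    gt_poses = {
        seg: SegmentPoseSeries(name=seg, orientation=frame_series[seg],
                               origin=point_series(origin_points[seg]).copy(),
                               axis_end=point_series(axis_points[seg]).copy())
        for seg in frame_series
    }

    # ground-truth angles: realised rotations (== prescription for ankle/Chopart)
    raw_gt, clin_gt = {}, {}
    for joint, (prox, dist) in JOINTS.items():
        rel = np.einsum("nji,njk->nik", frame_series[prox], frame_series[dist])
        raw = cardan_xzy(rel, check=False)
        raw_gt[joint] = raw
        clin_gt[joint] = (raw - neutral_raw[joint][None, :]) * signs[None, :]

    # ground reaction at the plate rate
    n_plate = int(np.floor(duration * spec.plate_rate)) + 1
    tp = np.arange(n_plate) / spec.plate_rate
    up = (tp - t_hs) / T
    bw = spec.body_mass * GRAVITY

    def stance_phase(uu):
        us = np.where((uu >= 0) & (uu % 1.0 < spec.stance_fraction),
                      (uu % 1.0) / spec.stance_fraction, np.nan)
        us[uu < 0] = np.nan
        return us

    us = stance_phase(up)
    contact = np.isfinite(us)
    fy = np.zeros(n_plate)
    fy[contact] = bw * (spec.grf_p * np.sin(np.pi * us[contact])
                        + spec.grf_q * np.sin(3 * np.pi * us[contact]))
    fx = np.zeros(n_plate)
    fx[contact] = -0.16 * bw * np.sin(2 * np.pi * us[contact])
    lat = 1.0 if spec.side == "right" else -1.0  # medial shear mirrors with side
    fz = np.zeros(n_plate)
    fz[contact] = lat * 0.05 * bw * np.sin(np.pi * us[contact])
    force = np.column_stack([fx, fy, fz])
    tz = np.zeros(n_plate)
    tz[contact] = lat * 500.0 * (spec.body_mass / 70.0) * np.sin(2 * np.pi * us[contact])

    # CoP: anchored to the moving foot, easing from heel (BC) to hallux
    def ground(label):
        p = positions[label].copy()
        p[:, 1] = 0.0
        return p

    heel_g = np.column_stack([np.interp(tp, t, ground("BC")[:, k]) for k in range(3)])
    toe_g = np.column_stack([np.interp(tp, t, ground("HLX")[:, k]) for k in range(3)])
    w = np.zeros(n_plate)
    w[contact] = us[contact] ** spec.cop_shape_power
    cop = np.full((n_plate, 3), np.nan)
    cop[contact] = ((1 - w[contact, None]) * heel_g[contact]
                    + w[contact, None] * toe_g[contact])
    fp = ForcePlateRecord(force=force, cop=cop, tz=tz, rate=spec.plate_rate)

    # marker-rate CoP for the ground truth
    um = stance_phase(u.copy())
    cm = np.isfinite(um)
    wm = np.zeros(n_frames)
    wm[cm] = um[cm] ** spec.cop_shape_power
    cop_m = np.full((n_frames, 3), np.nan)
    cop_m[cm] = ((1 - wm[cm, None]) * ground("BC")[cm]
                 + wm[cm, None] * ground("HLX")[cm])

    # optional marker noise
    rng = np.random.default_rng(spec.seed)
    noisy = {}
    for lab, pos in positions.items():
        p = pos.copy()
        if spec.marker_noise_sd > 0:
            p = p + rng.normal(0.0, spec.marker_noise_sd, size=p.shape)
        noisy[lab] = p
    traj = MarkerTrajectories(positions=noisy, rate=spec.marker_rate)

    gt = GroundTruth(
        raw_angles=raw_gt, clinical_angles=clin_gt, prescribed_clinical=presc_clin,
        poses=gt_poses, heel_strike_time=t_hs, toe_off_time=t_to,
        cycle_end_time=t_end, stance_fraction=spec.stance_fraction,
        cop_path=cop_m, marker_rate=spec.marker_rate,
    )
    return traj, fp, gt


def healthy_default_spec(seed: int = 0, **overrides) -> SyntheticTrialSpec:
    """Trial spec emulating a healthy adult walking at self-selected speed.

    Range-of-motion defaults follow healthy multi-segment foot gait:
    large sagittal hallux motion (~37 deg, dorsiflexing through push-off),
    ~26 deg hindfoot sagittal motion, a small (~6 deg) reversed-trend
    midfoot sagittal excursion, and an arch that compresses through
    stance so the MLA height/length ratio dips shortly before toe off.
    """
    waves = {
        "ankle": {
            "sagittal": PlaneWave(26.3, [(0.0, 0.1), (0.07, -0.45), (0.2, 0.05),
                                         (0.45, 0.85), (0.55, 0.55), (0.65, -1.0),
                                         (0.8, 0.25), (0.9, 0.3)]),
            "frontal": PlaneWave(6.56, [(0.0, 0.3), (0.1, -0.6), (0.45, 0.5),
                                        (0.65, 1.0), (0.8, -0.3)]),
            "transverse": PlaneWave(2.71, [(0.0, 0.2), (0.15, -0.8), (0.5, 0.6),
                                           (0.75, -0.2)]),
        },
        "chopart": {
            "sagittal": PlaneWave(6.46, [(0.0, -0.1), (0.15, 0.05), (0.40, 0.75),
                                         (0.54, 1.0), (0.66, -0.45), (0.8, -0.2)]),
            "frontal": PlaneWave(3.93, [(0.0, 0.0), (0.2, -0.6), (0.5, 0.7),
                                        (0.7, -0.4)]),
            "transverse": PlaneWave(3.71, [(0.0, 0.3), (0.25, -0.5), (0.55, 0.8),
                                           (0.75, -0.3)]),
        },
        "lisfranc": {
            "sagittal": PlaneWave(14.17, [(0.0, -0.15), (0.15, 0.0), (0.40, 0.35),
                                          (0.55, 1.0), (0.68, -0.35), (0.85, -0.15)]),
            "frontal": PlaneWave(2.82, [(0.0, 0.1), (0.3, -0.5), (0.6, 0.6),
                                        (0.8, -0.2)]),
            "transverse": PlaneWave(7.48, [(0.0, -0.1), (0.3, 0.4), (0.55, 1.0),
                                           (0.75, -0.6)]),
        },
        "mtp1": {
            "sagittal": PlaneWave(37.29, [(0.0, -0.25), (0.15, -0.45), (0.40, -0.35),
                                          (0.58, 1.0), (0.70, 0.35), (0.85, -0.3)]),
            "transverse": PlaneWave(11.63, [(0.0, 0.2), (0.3, 0.05), (0.55, -0.9),
                                            (0.75, 0.6)]),
        },
    }
    return SyntheticTrialSpec(seed=seed, waveforms=waves, **overrides)


# ---------------------------------------------------------------------------
# independent free-body oracle for the inverse dynamics


def _central_diff(series: np.ndarray, dt: float) -> np.ndarray:
    """Plain-loop central differences matching numpy.gradient's stencil."""
    out = np.empty_like(series)
    n = len(series)
    for i in range(n):
        if i == 0:
            out[i] = (series[1] - series[0]) / dt
        elif i == n - 1:
            out[i] = (series[-1] - series[-2]) / dt
        else:
            out[i] = (series[i + 1] - series[i - 1]) / (2 * dt)
    return out


def naive_inverse_dynamics(poses: dict[str, SegmentPoseSeries],
                           anthro: AnthropometricModel, fp: ForcePlateRecord,
                           rate: float, contact_threshold: float = 20.0,
                           ) -> dict[str, np.ndarray]:
    """Brute-force per-frame Newton-Euler free-body moments (lab frame, N*m).

    Deliberately scalar and loop-based: one free body per joint per frame,
    summing inertial, gravitational and external contributions term by
    term.  Serves as the independent oracle for the vectorised
    implementation; returns un-normalized lab-frame moment series.
    """
    dt = 1.0 / rate
    g = np.array([0.0, -GRAVITY, 0.0])
    n = next(iter(poses.values())).n_frames

    seg_data = {}
    for seg in ("hindfoot", "midfoot", "forefoot", "hallux"):
        pose = poses[seg]
        mass = anthro.segment_masses[seg]
        com = 0.5 * (pose.origin + pose.axis_end) * 1e-3
        acc = _central_diff(_central_diff(com, dt), dt)
        R = pose.orientation
        Rdot = _central_diff(R.reshape(n, 9), dt).reshape(n, 3, 3)
        omega = np.empty((n, 3))
        for i in range(n):
            W = Rdot[i] @ R[i].T
            omega[i] = 0.5 * np.array([W[2, 1] - W[1, 2],
                                       W[0, 2] - W[2, 0],
                                       W[1, 0] - W[0, 1]])
        alpha = _central_diff(omega, dt)
        L = float(np.mean(np.linalg.norm(pose.axis_end - pose.origin, axis=1))) * 1e-3
        radii = np.asarray(anthro.radii_of_gyration)
        I = np.diag(mass * (radii * L) ** 2)
        seg_data[seg] = (mass, com, acc, R, omega, alpha, I)

    moments: dict[str, np.ndarray] = {}
    for joint, segs in DISTAL_SEGMENTS.items():
        center = poses[JOINT_CENTER_SEGMENT[joint]].origin * 1e-3
        M = np.zeros((n, 3))
        for i in range(n):
            total = np.zeros(3)
            for seg in segs:
                mass, com, acc, R, omega, alpha, I = seg_data[seg]
                w_s = R[i].T @ omega[i]
                a_s = R[i].T @ alpha[i]
                euler = R[i] @ (I @ a_s + np.cross(w_s, I @ w_s))
                total = total + euler
                total = total + np.cross(com[i] - center[i], mass * (acc[i] - g))
            if abs(fp.force[i, 1]) >= contact_threshold:
                cop = fp.cop[i] * 1e-3
                total = total - np.cross(cop - center[i], fp.force[i])
                total = total - np.array([0.0, fp.tz[i] * 1e-3, 0.0])
            M[i] = total
        moments[joint] = M
    return moments
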