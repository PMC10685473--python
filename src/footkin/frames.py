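"""Virtual markers and per-frame segment-fixed coordinate frames.

Each body segment is defined by three points (Origin, Long-Axis, Plane)
plus small fixed attitude offsets, mirroring how optical motion-capture
skeleton builders define segments:

* the z-axis runs from the Origin marker to the Long-Axis marker
  (proximal to distal end of the segment);
* the Plane marker spans the y-z plane with them; the x-axis is the
  normal of that plane, ``x = unit((plane - origin) x z)``;
* ``y = z x x`` completes the right-handed triad;
* the RX/RY/RZ offsets then re-orient the attitude about the segment's own
  axes (intrinsic, order X, Y, Z) so that all foot segments share common
  anatomical directions in neutral stance.  The offsets rotate the
  attitude by ``-theta`` about each axis (equivalently: they rotate the
  segment's coordinate data by ``+theta``); this is the sense under which
  the catalogued offsets bring the four foot segments into mutual
  alignment, which is their stated purpose.

In neutral standing the resulting foot-segment axes are: x medio-lateral
(to the subject's right for a right foot), y vertical up, z anterior.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .trial_io import MarkerTrajectories, MarkerSetRegistry, default_registry

__all__ = [
    "SegmentDefinition",
    "SegmentPoseSeries",
    "DegenerateFrameError",
    "compute_virtual_markers",
    "build_segment_frame",
    "build_segment_frame_series",
    "pose_time_series",
    "load_segment_definitions",
    "SEGMENT_ORDER",
    "JOINTS",
]

#: Topological order of the model's segments (parent first).
SEGMENT_ORDER = ("shank", "hindfoot", "midfoot", "forefoot", "hallux")

#: joint name -> (proximal segment, distal segment)
JOINTS = {
    "ankle": ("shank", "hindfoot"),
    "chopart": ("hindfoot", "midfoot"),
    "lisfranc": ("midfoot", "forefoot"),
    "mtp1": ("forefoot", "hallux"),
}


class DegenerateFrameError(ValueError):
    """Raised when the three defining markers are (near-)collinear."""


@dataclass(frozen=True)
class SegmentDefinition:
    """Origin/Long-Axis/Plane markers and attitude offsets for one segment."""

    name: str
    parent: str
    origin_marker: str
    long_axis_marker: str
    plane_marker: str
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    anatomical_axes: dict[str, str] = field(
        default_factory=lambda: {"ml": "x", "ap": "z", "vert": "y"}
    )

    def __post_init__(self) -> None:
        markers = {self.origin_marker, self.long_axis_marker, self.plane_marker}
        if len(markers) != 3:
            raise ValueError(f"segment {self.name!r}: the three markers must be distinct")
        for ang in (self.rx, self.ry, self.rz):
            if not (-180.0 < ang <= 180.0):
                raise ValueError(f"segment {self.name!r}: offsets must lie in (-180, 180]")

    def mirrored(self) -> "SegmentDefinition":
        """The opposite-side definition (RZ offset sign flipped)."""
        rz = -self.rz if self.rz != 180.0 else 180.0
        return SegmentDefinition(
            name=self.name, parent=self.parent, origin_marker=self.origin_marker,
            long_axis_marker=self.long_axis_marker, plane_marker=self.plane_marker,
            rx=self.rx, ry=self.ry, rz=rz, anatomical_axes=dict(self.anatomical_axes),
        )


@dataclass
class SegmentPoseSeries:
    """Per-frame orthonormal orientation (lab <- segment) and origin (mm)."""

    name: str
    orientation: np.ndarray           # (n, 3, 3)
    origin: np.ndarray                # (n, 3) mm
    axis_end: np.ndarray              # (n, 3) mm, position of the Long-Axis point

    def __post_init__(self) -> None:
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis_end = np.asarray(self.axis_end, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.origin)

    @property
    def long_axis_length(self) -> np.ndarray:
        return np.linalg.norm(self.axis_end - self.origin, axis=1)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.orientation).all(axis=(1, 2))


def load_segment_definitions(path: str | Path | None = None,
                             side: str = "right") -> dict[str, SegmentDefinition]:
    """Load the packaged (or a user-supplied) segment definition table."""
    if path is None:
        resource = importlib.resources.files("footkin").joinpath(
            "data/segment_definitions.yaml"
        )
        raw = yaml.safe_load(resource.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    defs = {}
    for row in raw["segments"]:
        d = SegmentDefinition(
            name=row["name"], parent=row["parent"], origin_marker=row["origin"],
            long_axis_marker=row["long_axis"], plane_marker=row["plane"],
            rx=float(row.get("rx", 0)), ry=float(row.get("ry", 0)),
            rz=float(row.get("rz", 0)),
            anatomical_axes=dict(row.get("anatomical_axes",
                                         {"ml": "x", "ap": "z", "vert": "y"})),
        )
        if side == "left":
            d = d.mirrored()
        defs[d.name] = d
    return defs


def compute_virtual_markers(traj: MarkerTrajectories,
                            registry: MarkerSetRegistry | None = None) -> MarkerTrajectories:
    """Append the model's virtual (midpoint) markers to a trajectory set.

    V_Ankle_JC is the inter-malleolar midpoint, V_MidNC the
    navicular-cuboid midpoint, V_1_5MTH the midpoint of the first and
    fifth metatarsal heads, V_Knee_JC the knee-marker midpoint.  A frame
    gapped in either parent marker is gapped in the virtual marker.
    """
    registry = registry or default_registry()
    out = traj.copy()
    for name, (a, b) in registry.virtual.items():
        if a not in out.positions or b not in out.positions:
            missing = [m for m in (a, b) if m not in out.positions]
            raise KeyError(f"virtual marker {name!r} needs {missing}")
        out.positions[name] = 0.5 * (out.positions[a] + out.positions[b])
        out.gaps[name] = out.gaps[a] | out.gaps[b]
        out.positions[name][out.gaps[name]] = np.nan
    return out


def _offset_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Attitude offset: intrinsic rotations by -rx, -ry, -rz about own X, Y, Z."""
    def rot(axis: int, deg: float) -> np.ndarray:
        a = np.deg2rad(-deg)
        c, s = np.cos(a), np.sin(a)
        m = np.eye(3)
        i, j = [(1, 2), (2, 0), (0, 1)][axis]
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -s
        m[j, i] = s
        return m

    return rot(0, rx) @ rot(1, ry) @ rot(2, rz)


def build_segment_frame_series(origin: np.ndarray, long_axis: np.ndarray,
                               plane: np.ndarray, rx: float = 0.0, ry: float = 0.0,
                               rz: float = 0.0) -> np.ndarray:
    """Vectorised frame construction over (n, 3) point series -> (n, 3, 3).

    Frames with any NaN input, or with (near-)collinear markers, come out
    as NaN.  Raises :class:`DegenerateFrameError` only if *every* frame is
    degenerate while inputs are finite.
    """
    origin = np.atleast_2d(np.asarray(origin, dtype=float))
    long_axis = np.atleast_2d(np.asarray(long_axis, dtype=float))
    plane = np.atleast_2d(np.asarray(plane, dtype=float))
    z = long_axis - origin
    zn = np.linalg.norm(z, axis=1, keepdims=True)
    p = plane - origin
    with np.errstate(invalid="ignore", divide="ignore"):
        z = z / zn
        x = np.cross(p, z)
        xn = np.linalg.norm(x, axis=1, keepdims=True)
        scale = np.maximum(zn, np.linalg.norm(p, axis=1, keepdims=True))
        degenerate = (xn[:, 0] < 1e-9 * scale[:, 0]) | (zn[:, 0] < 1e-12)
        x = x / xn
    y = np.cross(z, x)
    R = np.stack([x, y, z], axis=2)  # columns are the axes
    R[degenerate] = np.nan
    finite_inputs = (np.isfinite(origin).all(axis=1)
                     & np.isfinite(long_axis).all(axis=1)
                     & np.isfinite(plane).all(axis=1))
    if (degenerate & finite_inputs).all() and len(R) > 0 and finite_inputs.any():
        raise DegenerateFrameError("defining markers are collinear in every frame")
    return R @ _offset_matrix(rx, ry, rz)


def build_segment_frame(origin, long_axis, plane, rx: float = 0.0, ry: float = 0.0,
                        rz: float = 0.0) -> np.ndarray:
    """Single-frame convenience wrapper around the series constructor."""
    R = build_segment_frame_series(
        np.asarray(origin)[None], np.asarray(long_axis)[None],
        np.asarray(plane)[None], rx, ry, rz,
    )[0]
    if not np.isfinite(R).all():
        raise DegenerateFrameError("defining markers are collinear")
    return R


def pose_time_series(traj: MarkerTrajectories,
                     defs: dict[str, SegmentDefinition]) -> dict[str, SegmentPoseSeries]:
    """Build every segment's pose series (virtual markers must be present)."""
    poses: dict[str, SegmentPoseSeries] = {}
    order = [s for s in SEGMENT_ORDER if s in defs] + [
        s for s in defs if s not in SEGMENT_ORDER
    ]
    for name in order:
        d = defs[name]
        if d.parent not in ("Global", None) and d.parent not in poses:
            raise ValueError(f"segment {name!r}: parent {d.parent!r} not built yet")
        try:
            o = traj.positions[d.origin_marker]
            la = traj.positions[d.long_axis_marker]
            p = traj.positions[d.plane_marker]
        except KeyError as exc:
            raise KeyError(
                f"segment {name!r}: defining marker {exc.args[0]!r} absent "
                "(were virtual markers computed?)"
            ) from None
        R = build_segment_frame_series(o, la, p, d.rx, d.ry, d.rz)
        poses[name] = SegmentPoseSeries(name=name, orientation=R, origin=o.copy(),
                                        axis_end=la.copy())
    return poses
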