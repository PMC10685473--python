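"""Trial input/output: marker trajectories, force-plate records, configuration.

Internal conventions
--------------------
* Lab frame: right-handed, X along the walking direction, Y vertical up,
  Z to the subject's left.  File axes that disagree are remapped through
  :attr:`TrialConfig.axis_map`.
* Marker positions are stored in millimetres; forces in newtons; the free
  vertical moment in newton-millimetres.  Conversion to SI happens only
  inside the kinetics computations.

Supported marker dialects: TRC (tab-separated, Motion Analysis/OpenSim
style) and a long-format CSV with columns ``time, marker, x, y, z``.
Force-plate CSV carries either pre-computed CoP columns
(``time, Fx, Fy, Fz, COPx, COPy, COPz, Tz``) or raw plate channels
(``time, Fx, Fy, Fz, Mx, My, Mz``) from which the CoP is solved.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

__all__ = [
    "MarkerTrajectories",
    "MarkerSetRegistry",
    "ForcePlateRecord",
    "TrialConfig",
    "FormatError",
    "MissingMarkerError",
    "load_marker_trajectories",
    "load_force_plate",
    "resample_force_to_markers",
    "write_marker_csv",
    "write_marker_trc",
    "write_force_csv",
    "default_registry",
]

#: The eleven physical foot markers of the modified DuPont marker set.
FOOT_MARKERS = (
    "TC",    # top (proximal posterior) calcaneus
    "BC",    # bottom (distal posterior) calcaneus
    "MM",    # medial malleolus
    "LM",    # lateral malleolus
    "TH",    # talar head (added to the original DuPont set for the midfoot)
    "NV",    # navicular
    "CB",    # cuboid
    "1MTH",  # first metatarsal head
    "5MTH",  # fifth metatarsal head
    "23T",   # between the 2nd and 3rd metatarsal heads
    "HLX",   # hallux nail bed
)

#: Shank reference markers (knee pair; full lower-body marker set is not needed).
SHANK_MARKERS = ("KNE_LAT", "KNE_MED")

#: Virtual marker rules: name -> pair of markers whose midpoint defines it.
VIRTUAL_RULES = {
    "V_Ankle_JC": ("MM", "LM"),
    "V_MidNC": ("NV", "CB"),
    "V_1_5MTH": ("1MTH", "5MTH"),
    "V_Knee_JC": ("KNE_MED", "KNE_LAT"),
}


class FormatError(ValueError):
    """Raised when a file cannot be parsed in any supported dialect."""


class MissingMarkerError(KeyError):
    """Raised when required canonical markers are absent after label mapping."""

    def __init__(self, missing: Sequence[str]):
        self.missing = tuple(missing)
        super().__init__(f"required markers missing: {', '.join(self.missing)}")


@dataclass
class MarkerTrajectories:
    """Labelled 3-D marker time series.

    positions maps canonical label -> (n_frames, 3) array in mm (lab frame);
    gaps maps label -> boolean (n_frames,) array, True where the marker is
    missing (positions are NaN there).
    """

    positions: dict[str, np.ndarray]
    rate: float
    gaps: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = {len(p) for p in self.positions.values()}
        if len(lengths) > 1:
            raise ValueError("all marker series must have equal length")
        for label, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.ndim != 2 or pos.shape[1] != 3:
                raise ValueError(f"marker {label!r}: positions must be (n, 3)")
            self.positions[label] = pos
            if label not in self.gaps:
                self.gaps[label] = ~np.isfinite(pos).all(axis=1)
            ok = ~self.gaps[label]
            if not np.isfinite(pos[ok]).all():
                raise ValueError(f"marker {label!r}: non-finite coordinates outside gaps")

    @property
    def labels(self) -> list[str]:
        return list(self.positions)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.positions.values())))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def copy(self) -> "MarkerTrajectories":
        return MarkerTrajectories(
            positions={k: v.copy() for k, v in self.positions.items()},
            rate=self.rate,
            gaps={k: v.copy() for k, v in self.gaps.items()},
        )


@dataclass(frozen=True)
class MarkerSetRegistry:
    """Marker-set registry for one foot: physical names and virtual rules."""

    physical: tuple[str, ...]
    shank: tuple[str, ...]
    virtual: Mapping[str, tuple[str, str]]
    side: str = "right"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if len(set(self.physical)) != 11:
            raise ValueError("the foot marker set has exactly eleven physical markers")
        known = set(self.physical) | set(self.shank)
        for name, (a, b) in self.virtual.items():
            if a not in known or b not in known:
                raise ValueError(f"virtual marker {name!r} references unknown markers")
            known.add(name)

    @property
    def required(self) -> tuple[str, ...]:
        return self.physical + self.shank


def default_registry(side: str = "right") -> MarkerSetRegistry:
    """The modified DuPont registry: 11 foot markers, knee pair, 4 virtuals."""
    return MarkerSetRegistry(
        physical=FOOT_MARKERS, shank=SHANK_MARKERS, virtual=dict(VIRTUAL_RULES), side=side
    )


@dataclass
class ForcePlateRecord:
    """Ground reaction force, centre of pressure and free vertical moment.

    force: (n, 3) N, lab frame, action on the subject (vertical component
    positive up during contact).  cop: (n, 3) mm, NaN (and ``cop_valid``
    False) wherever |vertical force| is below the contact threshold.
    tz: (n,) free vertical moment, N*mm.
    """

    force: np.ndarray
    cop: np.ndarray
    tz: np.ndarray
    rate: float
    cop_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.cop = np.asarray(self.cop, dtype=float)
        self.tz = np.asarray(self.tz, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.force)
        if not (len(self.cop) == len(self.tz) == n):
            raise ValueError("force, cop and tz series must have equal length")
        if self.cop_valid is None:
            self.cop_valid = np.isfinite(self.cop).all(axis=1)
        self.cop_valid = np.asarray(self.cop_valid, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.force)

    @property
    def vertical_force(self) -> np.ndarray:
        return self.force[:, 1]


_AXIS_VECTORS = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


def _axis_matrix(axis_map: Sequence[str]) -> np.ndarray:
    """Signed-permutation matrix sending file axes to lab axes.

    ``axis_map = (a1, a2, a3)`` declares that file axis i maps to lab
    direction ``ai`` (one of ``x, y, z`` with optional leading ``-``).
    """
    if len(axis_map) != 3:
        raise ValueError("axis_map needs three entries")
    cols = []
    for token in axis_map:
        token = token.strip().lower()
        sign = -1.0 if token.startswith("-") else 1.0
        name = token.lstrip("+-")
        if name not in _AXIS_VECTORS:
            raise ValueError(f"bad axis token {token!r}")
        cols.append(sign * _AXIS_VECTORS[name])
    mat = np.column_stack(cols)
    if abs(np.linalg.det(mat)) != 1.0:
        raise ValueError("axis_map must be a permutation of x, y, z")
    return mat


@dataclass
class TrialConfig:
    """Per-trial configuration.

    label_map maps file labels to canonical labels (identity by default).
    filter_cutoff is the marker low-pass cutoff in Hz (None disables).
    grf_cutoff is an optional GRF low-pass, off by default.
    axis_map declares how file axes map onto the internal lab frame.
    """

    body_mass: float = 70.0
    side: str = "right"
    label_map: dict[str, str] = field(default_factory=dict)
    filter_cutoff: float | None = 6.0
    grf_cutoff: float | None = None
    contact_threshold: float = 20.0
    axis_map: tuple[str, str, str] = ("x", "y", "z")
    max_gap_frames: int = 5
    anthropometrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body mass must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        _axis_matrix(self.axis_map)  # validate

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "axis_map" in raw:
            raw["axis_map"] = tuple(raw["axis_map"])
        return cls(**raw)

    def canonical(self, label: str) -> str:
        return self.label_map.get(label, label)


# ---------------------------------------------------------------------------
# marker loading


def _interpolate_short_gaps(traj: MarkerTrajectories, max_gap: int,
                            required: Sequence[str]) -> MarkerTrajectories:
    """Linearly fill gaps of <= max_gap frames; long gaps in required markers err."""
    out = traj.copy()
    idx = np.arange(traj.n_frames)
    for label in out.labels:
        gap = out.gaps[label]
        if not gap.any():
            continue
        # find contiguous gap runs
        runs = []
        start = None
        for i, g in enumerate(gap):
            if g and start is None:
                start = i
            elif not g and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(gap)))
        pos = out.positions[label]
        for a, b in runs:
            length = b - a
            interior = a > 0 and b < len(gap)
            if length <= max_gap and interior:
                for k in range(3):
                    pos[a:b, k] = np.interp(idx[a:b], idx[~gap], pos[~gap, k])
                gap[a:b] = False
            elif label in required:
                raise ValueError(
                    f"marker {label!r}: gap of {length} frames at {a} exceeds "
                    f"the {max_gap}-frame interpolation limit"
                )
    return out


def _finish_markers(positions: dict[str, np.ndarray], rate: float,
                    config: TrialConfig, unit_scale: float,
                    required: Sequence[str] | None) -> MarkerTrajectories:
    mat = _axis_matrix(config.axis_map)
    mapped: dict[str, np.ndarray] = {}
    for label, pos in positions.items():
        canon = config.canonical(label)
        if canon in mapped:
            raise FormatError(f"label map sends two file labels to {canon!r}")
        mapped[canon] = (unit_scale * np.asarray(pos, dtype=float)) @ mat.T
    required = tuple(required) if required is not None else ()
    missing = [m for m in required if m not in mapped]
    if missing:
        raise MissingMarkerError(missing)
    traj = MarkerTrajectories(positions=mapped, rate=rate)
    return _interpolate_short_gaps(traj, config.max_gap_frames, required)


def _load_trc(path: Path, config: TrialConfig,
              required: Sequence[str] | None) -> MarkerTrajectories:
    lines = path.read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{path}: not a TRC file")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    meta = dict(zip(header_keys, header_vals))
    rate = float(meta["DataRate"])
    units = meta.get("Units", "mm").strip().lower()
    unit_scale = {"mm": 1.0, "m": 1000.0, "cm": 10.0}.get(units)
    if unit_scale is None:
        raise FormatError(f"{path}: unknown TRC units {units!r}")
    label_row = lines[3].split("\t")
    labels = [lab for lab in label_row[2:] if lab.strip()]
    data = np.genfromtxt(
        _stdio.StringIO("\n".join(ln for ln in lines[5:] if ln.strip())),
        delimiter="\t",
    )
    data = np.atleast_2d(data)
    expected = 2 + 3 * len(labels)
    if data.shape[1] < expected:
        raise FormatError(f"{path}: TRC data width {data.shape[1]} < {expected}")
    positions = {
        lab: data[:, 2 + 3 * i: 5 + 3 * i] for i, lab in enumerate(labels)
    }
    return _finish_markers(positions, rate, config, unit_scale, required)


def _load_long_csv(path: Path, config: TrialConfig,
                   required: Sequence[str] | None) -> MarkerTrajectories:
    df = pd.read_csv(path)
    needed = {"time", "marker", "x", "y", "z"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: long CSV needs columns {sorted(needed)}")
    times = np.sort(df["time"].unique())
    if len(times) < 2:
        rate = 1.0
    else:
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError(f"{path}: non-uniform time stamps")
        rate = 1.0 / dt[0]
    positions = {}
    for label, grp in df.groupby("marker", sort=False):
        grp = grp.set_index("time").reindex(times)
        positions[str(label)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
    return _finish_markers(positions, rate, config, 1.0, required)


def load_marker_trajectories(path: str | Path, config: TrialConfig,
                             required: Sequence[str] | None = None,
                             ) -> MarkerTrajectories:
    """Read marker data (TRC or long CSV) into canonical labels and mm.

    ``required`` lists canonical markers that must be present after label
    mapping; absentees raise :class:`MissingMarkerError` naming them.
    Pass ``footkin.default_registry(side).required`` to demand the full
    model marker set (the analysis pipeline does this itself).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".trc":
        return _load_trc(path, config, required)
    if suffix == ".csv":
        return _load_long_csv(path, config, required)
    raise FormatError(
        f"{path}: unsupported marker format {suffix!r}; supported dialects are "
        ".trc and long-format .csv (columns time, marker, x, y, z)"
    )


def write_marker_csv(traj: MarkerTrajectories, path: str | Path) -> None:
    """Write the long-format CSV dialect (time, marker, x, y, z)."""
    rows = []
    times = traj.times
    for label in traj.labels:
        pos = traj.positions[label]
        for i, t in enumerate(times):
            rows.append((t, label, pos[i, 0], pos[i, 1], pos[i, 2]))
    df = pd.DataFrame(rows, columns=["time", "marker", "x", "y", "z"])
    df.to_csv(path, index=False, float_format="%.9f")


def write_marker_trc(traj: MarkerTrajectories, path: str | Path, units: str = "mm") -> None:
    """Write a minimal TRC file (tab separated, Motion Analysis layout)."""
    scale = {"mm": 1.0, "m": 1e-3, "cm": 0.1}[units]
    labels = traj.labels
    n = traj.n_frames
    rate = traj.rate
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(labels)}\t{units}\t{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t".join(f"{lab}\t\t" for lab in labels).rstrip() + "\n")
        comps = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(labels)))
        fh.write(f"\t\t{comps}\n")
        for i in range(n):
            cells = [str(i + 1), f"{i / rate:.9f}"]
            for lab in labels:
                p = traj.positions[lab][i] * scale
                cells.extend(f"{c:.9f}" for c in p)
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# force plate


def _solve_cop(force: np.ndarray, moment: np.ndarray, threshold: float,
               surface_y: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Solve CoP on the plate surface from force and moment about the origin.

    With r = (x, surface_y, z) and M = r x F (lab frame, Y up), the
    horizontal CoP coordinates follow from the X and Z moment components;
    the residual vertical moment is the free moment Tz.
    """
    fy = force[:, 1]
    valid = np.abs(fy) >= threshold
    cop = np.full_like(force, np.nan)
    tz = np.zeros(len(force))
    with np.errstate(divide="ignore", invalid="ignore"):
        # M_x = y*F_z - z*F_y ; M_z = x*F_y - y*F_x
        x = (moment[:, 2] + surface_y * force[:, 0]) / fy
        z = (surface_y * force[:, 2] - moment[:, 0]) / fy
    cop[valid, 0] = x[valid]
    cop[valid, 1] = surface_y
    cop[valid, 2] = z[valid]
    # free vertical moment: M_y - (z*F_x - x*F_z)
    tz[valid] = moment[valid, 1] - (cop[valid, 2] * force[valid, 0]
                                    - cop[valid, 0] * force[valid, 2])
    return cop, tz


def load_force_plate(path: str | Path, config: TrialConfig) -> ForcePlateRecord:
    """Read a force-plate CSV (pre-computed CoP or raw plate channels)."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    if not {"Fx", "Fy", "Fz"}.issubset(cols):
        raise FormatError(f"{path}: force CSV needs Fx, Fy, Fz columns")
    times = df["time"].to_numpy(dtype=float) if "time" in cols else None
    if times is not None and len(times) > 1:
        rate = 1.0 / (times[1] - times[0])
    else:
        rate = 1200.0
    mat = _axis_matrix(config.axis_map)
    force = df[["Fx", "Fy", "Fz"]].to_numpy(dtype=float) @ mat.T
    if {"COPx", "COPy", "COPz"}.issubset(cols):
        cop = df[["COPx", "COPy", "COPz"]].to_numpy(dtype=float) @ mat.T
        tz = df["Tz"].to_numpy(dtype=float) if "Tz" in cols else np.zeros(len(df))
        below = np.abs(force[:, 1]) < config.contact_threshold
        cop = cop.copy()
        cop[below] = np.nan
    elif {"Mx", "My", "Mz"}.issubset(cols):
        moment = df[["Mx", "My", "Mz"]].to_numpy(dtype=float) @ mat.T
        cop, tz = _solve_cop(force, moment, config.contact_threshold)
    else:
        raise FormatError(
            f"{path}: force CSV needs either COPx/COPy/COPz or Mx/My/Mz columns"
        )
    if not (np.abs(force[:, 1]) >= config.contact_threshold).any():
        import warnings

        warnings.warn(f"{path}: no contact above {config.contact_threshold} N "
                      "(all-zero vertical force?)", stacklevel=2)
    if config.grf_cutoff is not None:
        sos = signal.butter(2, config.grf_cutoff, fs=rate, output="sos")
        force = signal.sosfiltfilt(sos, force, axis=0)
    return ForcePlateRecord(force=force, cop=cop, tz=tz, rate=rate)


def write_force_csv(fp: ForcePlateRecord, path: str | Path) -> None:
    n = fp.n_samples
    df = pd.DataFrame(
        {
            "time": np.arange(n) / fp.rate,
            "Fx": fp.force[:, 0],
            "Fy": fp.force[:, 1],
            "Fz": fp.force[:, 2],
            "COPx": fp.cop[:, 0],
            "COPy": fp.cop[:, 1],
            "COPz": fp.cop[:, 2],
            "Tz": fp.tz,
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def resample_force_to_markers(fp: ForcePlateRecord, marker_rate: float,
                              contact_threshold: float = 20.0) -> ForcePlateRecord:
    """Decimate a force-plate record to the marker rate.

    Forces are anti-alias filtered (polyphase FIR) before decimation; the
    CoP, which is undefined outside contact, is linearly re-sampled within
    contact intervals only.
    """
    if marker_rate > fp.rate:
        raise ValueError(
            f"upsampling refused: marker rate {marker_rate} Hz exceeds "
            f"plate rate {fp.rate} Hz"
        )
    if np.isclose(marker_rate, fp.rate):
        return replace(fp)
    ratio = fp.rate / marker_rate
    up, down = (np.round([1, ratio]).astype(int) if np.isclose(ratio, round(ratio))
                else np.round([1000, 1000 * ratio]).astype(int))
    force = signal.resample_poly(fp.force, up, down, axis=0, padtype="line")
    tz = signal.resample_poly(fp.tz, up, down, padtype="line")
    n_out = len(force)
    t_out = np.arange(n_out) / marker_rate
    t_in = np.arange(fp.n_samples) / fp.rate
    cop = np.full((n_out, 3), np.nan)
    valid_in = fp.cop_valid
    if valid_in.any():
        # re-sample each contiguous contact interval independently
        edges = np.flatnonzero(np.diff(valid_in.astype(int)))
        starts = [0] if valid_in[0] else []
        starts += [e + 1 for e in edges if valid_in[e + 1]]
        ends = [e + 1 for e in edges if valid_in[e]]
        if valid_in[-1]:
            ends.append(fp.n_samples)
        for a, b in zip(starts, ends):
            sel = (t_out >= t_in[a]) & (t_out <= t_in[b - 1])
            for k in range(3):
                cop[sel, k] = np.interp(t_out[sel], t_in[a:b], fp.cop[a:b, k])
    out = ForcePlateRecord(force=force, cop=cop, tz=tz, rate=marker_rate)
    # CoP validity must also respect the contact threshold after filtering
    below = np.abs(out.force[:, 1]) < contact_threshold
    out.cop[below] = np.nan
    out.cop_valid = np.isfinite(out.cop).all(axis=1)
    return out
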