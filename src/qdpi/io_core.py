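"""Data model and I/O for multiplexed recordings, keypoint tables and calibrations.

The recording pipeline interleaves reflectance (IR-illuminated body surface)
and fluorescence (NIR-excited marker emission) exposures within each
illumination cycle.  This module owns the in-memory containers shared by the
rest of the package, the channel demultiplexer/blender, and the on-disk
dialects (multi-page TIFF or frame directories, keypoint CSV/HDF5,
calibration JSON, TOML configs).

Coordinate convention used throughout the package: ``x`` is the column and
``y`` the row, 0-based, origin at the top-left pixel center.
"""

from __future__ import annotations

import json
import logging
import re
import tomllib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

REFLECTANCE = "reflectance"
FLUORESCENCE = "fluorescence"

#: keypoint-table column order used by every reader/writer in the package
KEYPOINT_COLUMNS = ["frame", "camera", "node", "x", "y", "score"]


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


# ---------------------------------------------------------------------------
# illumination schedule and recordings
# ---------------------------------------------------------------------------

_PHASE_LABELS = {"reflectance_on", "off", "fluorescence_on"}

#: default illumination sequence (milliseconds): IR on, off, NIR on, off
DEFAULT_PHASES = (
    ("reflectance_on", 10.0),
    ("off", 1.0),
    ("fluorescence_on", 23.0),
    ("off", 1.5),
)

#: shorter sequence for high-frame-rate acquisition
FAST_PHASES = (
    ("reflectance_on", 2.0),
    ("off", 1.0),
    ("fluorescence_on", 8.0),
    ("off", 6.0),
)


@dataclass(frozen=True)
class IlluminationSchedule:
    """Ordered light phases of one acquisition cycle.

    A camera exposure is taken during every ``*_on`` phase, so the number of
    frames per cycle equals the number of ``*_on`` phases.  Exactly one
    reflectance and one fluorescence exposure per cycle are required.
    """

    phases: tuple[tuple[str, float], ...] = DEFAULT_PHASES

    def __post_init__(self) -> None:
        for label, duration_ms in self.phases:
            if label not in _PHASE_LABELS:
                raise ValidationError(f"unknown phase label {label!r}")
            if duration_ms <= 0:
                raise ValidationError(f"phase {label!r} has duration {duration_ms} <= 0")
        slots = self.channel_of_slot
        channels = list(slots.values())
        if channels.count(REFLECTANCE) != 1 or channels.count(FLUORESCENCE) != 1:
            raise ValidationError(
                "schedule must contain exactly one reflectance and one "
                f"fluorescence exposure per cycle, got {channels}"
            )

    @property
    def frames_per_cycle(self) -> int:
        return sum(1 for label, _ in self.phases if label.endswith("_on"))

    @property
    def channel_of_slot(self) -> dict[int, str]:
        """Map within-cycle frame index -> channel name."""
        slots: dict[int, str] = {}
        for label, _ in self.phases:
            if label == "reflectance_on":
                slots[len(slots)] = REFLECTANCE
            elif label == "fluorescence_on":
                slots[len(slots)] = FLUORESCENCE
        return slots

    @property
    def cycle_ms(self) -> float:
        return float(sum(d for _, d in self.phases))

    def to_dict(self) -> dict:
        return {"phases": [{"label": l, "ms": d} for l, d in self.phases]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "IlluminationSchedule":
        return cls(phases=tuple((p["label"], float(p["ms"])) for p in d["phases"]))


@dataclass(frozen=True)
class SessionKey:
    """Identity of one recording session (one mouse, one camera, one day)."""

    mouse_id: str = "m0"
    camera_id: str = "cam0"
    day_post_injection: float = 0.0
    variant_label: str = ""

    def __post_init__(self) -> None:
        if self.day_post_injection < 0:
            raise ValidationError("day_post_injection must be >= 0")


@dataclass
class MultiplexedRecording:
    """Interleaved reflectance/fluorescence frame stack plus its schedule."""

    frames: np.ndarray  # (n_frames, rows, cols) unsigned integers
    schedule: IlluminationSchedule = field(default_factory=IlluminationSchedule)
    session: SessionKey = field(default_factory=SessionKey)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError("frames must be a non-empty (frame, row, col) stack")
        if self.frames.dtype not in (np.uint8, np.uint16):
            raise ValidationError(f"frames must be uint8 or uint16, got {self.frames.dtype}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])  # type: ignore[return-value]


@dataclass
class DemuxResult:
    """Channel-separated stacks with frame-index provenance."""

    reflectance: np.ndarray
    fluorescence: np.ndarray
    reflectance_indices: np.ndarray  # original frame indices
    fluorescence_indices: np.ndarray
    dropped_indices: np.ndarray  # trailing partial-cycle frames


def demultiplex(recording: MultiplexedRecording) -> DemuxResult:
    """Split an interleaved recording into reflectance and fluorescence stacks.

    Frames are assigned by their within-cycle slot from the schedule; a
    trailing partial cycle is dropped with a warning rather than erroring,
    since recordings routinely end mid-cycle.
    """
    fpc = recording.schedule.frames_per_cycle
    n = recording.n_frames
    n_complete = (n // fpc) * fpc
    if n_complete < n:
        warnings.warn(
            f"dropping {n - n_complete} trailing frame(s) of a partial "
            f"illumination cycle ({n} frames, {fpc}-frame cycle)",
            stacklevel=2,
        )
    slots = recording.schedule.channel_of_slot
    idx = np.arange(n_complete)
    slot_of_frame = idx % fpc
    refl_slot = next(s for s, c in slots.items() if c == REFLECTANCE)
    fluo_slot = next(s for s, c in slots.items() if c == FLUORESCENCE)
    refl_idx = idx[slot_of_frame == refl_slot]
    fluo_idx = idx[slot_of_frame == fluo_slot]
    return DemuxResult(
        reflectance=recording.frames[refl_idx],
        fluorescence=recording.frames[fluo_idx],
        reflectance_indices=refl_idx,
        fluorescence_indices=fluo_idx,
        dropped_indices=np.arange(n_complete, n),
    )


def blend_channels(reflectance: np.ndarray, fluorescence: np.ndarray, alpha: float = 0.9) -> np.ndarray:
    """Alpha-blend a fluorescence frame over a reflectance frame.

    ``alpha`` is the fluorescence weight; the default 0.9 reproduces the
    90% fluorescence / 10% reflectance display mix used for hand labeling.
    Output is clipped and cast back to the input bit depth.
    """
    reflectance = np.asarray(reflectance)
    fluorescence = np.asarray(fluorescence)
    if reflectance.shape != fluorescence.shape:
        raise ValidationError(
            f"shape mismatch: reflectance {reflectance.shape} vs fluorescence {fluorescence.shape}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    out = alpha * fluorescence.astype(np.float64) + (1.0 - alpha) * reflectance.astype(np.float64)
    if np.issubdtype(fluorescence.dtype, np.integer):
        info = np.iinfo(fluorescence.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(fluorescence.dtype)
    return out


# ---------------------------------------------------------------------------
# keypoint tables
# ---------------------------------------------------------------------------


@dataclass
class KeypointTable:
    """Per frame/camera/node predictions: (x, y, confidence).

    ``records`` is a DataFrame with columns ``frame, camera, node, x, y,
    score``.  Missing keypoints are encoded as NaN x/y (or absent rows).
    """

    records: pd.DataFrame
    node_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).reset_index(drop=True)
        missing = [c for c in KEYPOINT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"keypoint table missing columns {missing}")
        df = df[KEYPOINT_COLUMNS].copy()
        df["frame"] = df["frame"].astype(np.int64)
        df["camera"] = df["camera"].astype(str)
        df["node"] = df["node"].astype(str)
        for c in ("x", "y", "score"):
            df[c] = pd.to_numeric(df[c], errors="coerce").astype(np.float64)
        bad_score = df.index[(df["score"] < 0) | (df["score"] > 1)].tolist()
        if bad_score:
            raise ValidationError(
                f"confidence outside [0, 1] at row(s) {bad_score[:5]}"
            )
        if df.duplicated(subset=["frame", "camera", "node"]).any():
            dup = df[df.duplicated(subset=["frame", "camera", "node"])].iloc[0]
            raise ValidationError(
                f"duplicate (frame, camera, node) record: "
                f"({dup['frame']}, {dup['camera']}, {dup['node']})"
            )
        inf_rows = df.index[np.isinf(df["x"]) | np.isinf(df["y"])].tolist()
        if inf_rows:
            raise ValidationError(f"non-finite coordinates at row(s) {inf_rows[:5]}")
        self.records = df
        if not self.node_set:
            self.node_set = tuple(pd.unique(df["node"]))
        unknown = set(df["node"]) - set(self.node_set)
        if unknown:
            raise ValidationError(f"records reference unknown node names {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    def equals(self, other: "KeypointTable") -> bool:
        a = self.records.sort_values(["frame", "camera", "node"]).reset_index(drop=True)
        b = other.records.sort_values(["frame", "camera", "node"]).reset_index(drop=True)
        return a.equals(b) and self.node_set == other.node_set


# ---------------------------------------------------------------------------
# camera models
# ---------------------------------------------------------------------------


@dataclass
class CameraModel:
    """Pinhole camera with radial-tangential distortion; world units are mm."""

    camera_id: str
    K: np.ndarray  # (3, 3) intrinsics, px
    dist: np.ndarray  # (5,) [k1, k2, p1, p2, k3]
    R: np.ndarray  # (3, 3) world -> camera rotation
    t: np.ndarray  # (3,) world -> camera translation, mm
    pixel_pitch_um: float = 5.7
    focal_length_mm: float = 8.0

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=np.float64).reshape(3, 3)
        self.dist = np.asarray(self.dist, dtype=np.float64).reshape(-1)
        if self.dist.size != 5:
            raise ValidationError("distortion must have 5 coefficients [k1,k2,p1,p2,k3]")
        self.R = np.asarray(self.R, dtype=np.float64).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3)
        if self.K[0, 0] <= 0 or self.K[1, 1] <= 0 or abs(self.K[1, 0]) > 1e-9 or np.any(np.abs(self.K[2, :2]) > 1e-9):
            raise ValidationError("intrinsic matrix must be upper-triangular with positive focal terms")
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-6) or np.linalg.det(self.R) < 0:
            raise ValidationError("rotation must be orthonormal with det +1")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates (mm)."""
        return -self.R.T @ self.t

    @property
    def optical_axis(self) -> np.ndarray:
        """Unit viewing direction (+z of the camera frame) in world coordinates."""
        return self.R.T @ np.array([0.0, 0.0, 1.0])

    def to_dict(self) -> dict:
        return {
            "K": self.K.ravel().tolist(),
            "dist": self.dist.tolist(),
            "R": self.R.ravel().tolist(),
            "t": self.t.tolist(),
            "pixel_pitch_um": self.pixel_pitch_um,
            "focal_length_mm": self.focal_length_mm,
        }

    @classmethod
    def from_dict(cls, camera_id: str, d: Mapping) -> "CameraModel":
        return cls(
            camera_id=camera_id,
            K=np.asarray(d["K"], dtype=np.float64).reshape(3, 3),
            dist=np.asarray(d["dist"], dtype=np.float64),
            R=np.asarray(d["R"], dtype=np.float64).reshape(3, 3),
            t=np.asarray(d["t"], dtype=np.float64),
            pixel_pitch_um=float(d.get("pixel_pitch_um", 5.7)),
            focal_length_mm=float(d.get("focal_length_mm", 8.0)),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_recording(recording: MultiplexedRecording, path: str | Path) -> None:
    """Write a recording as multi-page TIFF (``.tif``) or a frame directory.

    The directory layout stores zero-padded per-frame TIFFs plus a
    ``schedule.json``; the TIFF layout stores the schedule in a JSON sidecar
    ``<stem>.schedule.json``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, recording.frames, photometric="minisblack")
        _schedule_sidecar(path).write_text(json.dumps(recording.schedule.to_dict()))
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(5, len(str(recording.n_frames - 1)))
        for i, frame in enumerate(recording.frames):
            tifffile.imwrite(path / f"frame_{i:0{width}d}.tif", frame)
        (path / "schedule.json").write_text(json.dumps(recording.schedule.to_dict()))


def _schedule_sidecar(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".schedule.json")


_FRAME_RE = re.compile(r"frame_(\d+)\.(tif|tiff|png)$")


def read_recording(
    path: str | Path,
    schedule: IlluminationSchedule | None = None,
    session: SessionKey | None = None,
) -> MultiplexedRecording:
    """Read a recording from a multi-page TIFF or a frame directory."""
    path = Path(path)
    if path.is_dir():
        entries = sorted(
            (int(m.group(1)), p)
            for p in path.iterdir()
            if (m := _FRAME_RE.match(p.name))
        )
        if not entries:
            raise ValidationError(f"no frame_*.tif/png files in {path}")
        frames = np.stack([tifffile.imread(p) if p.suffix != ".png" else np.asarray(_read_png(p)) for _, p in entries])
        sched_path = path / "schedule.json"
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sched_path = _schedule_sidecar(path)
    if schedule is None:
        if not sched_path.exists():
            raise ValidationError(f"no schedule given and {sched_path} not found")
        schedule = IlluminationSchedule.from_dict(json.loads(sched_path.read_text()))
    return MultiplexedRecording(frames=frames, schedule=schedule, session=session or SessionKey())


def _read_png(p: Path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(p)


def write_keypoints_csv(table: KeypointTable, path: str | Path) -> None:
    """CSV dialect: header ``frame,camera,node,x,y,score``; missing x/y left empty."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = table.records.copy()
    df.to_csv(path, index=False, float_format="%.17g")


def read_keypoints_csv(path: str | Path, node_set: Sequence[str] = ()) -> KeypointTable:
    df = pd.read_csv(path, dtype={"camera": str, "node": str})
    return KeypointTable(records=df, node_set=tuple(node_set))


def write_keypoints_hdf5(table: KeypointTable, path: str | Path) -> None:
    """HDF5 mirror of the CSV dialect: one table per camera under ``/cameras``."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["node_set"] = list(table.node_set)
        grp = f.create_group("cameras")
        for cam, sub in table.records.groupby("camera", sort=True):
            g = grp.create_group(str(cam))
            g.create_dataset("frame", data=sub["frame"].to_numpy())
            g.create_dataset("node", data=sub["node"].to_numpy(dtype="S"))
            for c in ("x", "y", "score"):
                g.create_dataset(c, data=sub[c].to_numpy())


def read_keypoints_hdf5(path: str | Path) -> KeypointTable:
    rows = []
    with h5py.File(path, "r") as f:
        node_set = tuple(str(n) for n in f.attrs["node_set"])
        for cam in f["cameras"]:
            g = f["cameras"][cam]
            rows.append(
                pd.DataFrame(
                    {
                        "frame": g["frame"][:],
                        "camera": cam,
                        "node": [n.decode() for n in g["node"][:]],
                        "x": g["x"][:],
                        "y": g["y"][:],
                        "score": g["score"][:],
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=KEYPOINT_COLUMNS)
    return KeypointTable(records=df, node_set=node_set)


def write_calibration_json(cameras: Iterable[CameraModel], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = {cam.camera_id: cam.to_dict() for cam in cameras}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_calibration_json(path: str | Path) -> list[CameraModel]:
    payload = json.loads(Path(path).read_text())
    return [CameraModel.from_dict(cid, d) for cid, d in payload.items()]


# ---------------------------------------------------------------------------
# TOML configs
# ---------------------------------------------------------------------------


def read_config_toml(path: str | Path) -> dict:
    with open(path, "rb") as f:
        return tomllib.load(f)


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float, np.integer, np.floating)):
        return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(f"unsupported TOML value {v!r}")


def write_config_toml(config: Mapping, path: str | Path) -> None:
    """Minimal TOML emitter for nested dicts of scalars/lists (config subset)."""
    lines: list[str] = []

    def emit(table: Mapping, prefix: str) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, Mapping)}
        subtables = {k: v for k, v in table.items() if isinstance(v, Mapping)}
        if prefix and (scalars or not subtables):
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_scalar(v)}")
        for k, v in subtables.items():
            if lines and lines[-1] != "":
                lines.append("")
            emit(v, f"{prefix}.{k}" if prefix else k)

    emit(config, "")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")
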