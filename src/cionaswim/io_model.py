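"""Data model and I/O for tracked larval skeleton recordings.

A recording is a time series of 49-point midline skeletons produced by an
upstream tracker (Tierpsy-style): per frame, 49 ordered (x, y) coordinates in
pixels (index 0 = head tip, 48 = tail tip), 49 contour widths in pixels, and a
validity flag marking whether segmentation succeeded on that frame.

Coordinates follow the image convention (origin top-left, y increasing
downward) and stay in pixels; conversion to micrometers is always explicit via
:func:`calibrate_scale`.

Invalid frames are kept in place with ``valid=False`` rather than dropped, so
downstream time series retain the acquisition clock; each downstream stage
defines its own gap policy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

N_POINTS = 49
DEFAULT_FPS = 30.0


class SchemaError(ValueError):
    """Input does not match the expected skeleton layout (e.g. not 49 points)."""


class ParseError(ValueError):
    """Malformed input file; message names the first offending record."""


@dataclass(frozen=True)
class StimulusProtocol:
    """A single light-stimulus window: 60 s of colored light starting at 30 s."""

    color: str = "white"
    onset_s: float = 30.0
    duration_s: float = 60.0
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        if self.color not in {"red", "green", "blue", "white"}:
            raise ValueError(f"unknown stimulus color {self.color!r}")
        if self.onset_s < 10.0:
            raise ValueError("stimulus onset must be >= 10 s (room for the before-window)")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class SkeletonFrame:
    """One frame: 49 midline points, 49 contour widths, validity flag."""

    points: np.ndarray  # (49, 2) float, pixels
    widths: np.ndarray  # (49,) float, pixels
    valid: bool
    frame_index: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        w = np.asarray(self.widths, dtype=float)
        if pts.shape != (N_POINTS, 2):
            raise SchemaError(f"frame {self.frame_index}: expected {N_POINTS} points, got shape {pts.shape}")
        if w.shape != (N_POINTS,):
            raise SchemaError(f"frame {self.frame_index}: expected {N_POINTS} widths, got shape {w.shape}")
        if self.valid:
            if np.any(w < 0):
                raise SchemaError(f"frame {self.frame_index}: negative contour width")
            spacing = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if np.any(~np.isfinite(pts)) or np.any(spacing <= 0):
                raise SchemaError(f"frame {self.frame_index}: valid frame with degenerate point spacing")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "widths", w)


@dataclass
class TrackRecording:
    """One animal's skeleton time series with metadata.

    Internally array-backed: ``points`` is (T, 49, 2), ``widths`` is (T, 49),
    ``valid`` is (T,) bool and ``frame_index`` is (T,) int, strictly
    increasing. Invalid frames may hold NaN coordinates.
    """

    points: np.ndarray
    widths: np.ndarray
    valid: np.ndarray
    frame_index: np.ndarray
    fps: float = DEFAULT_FPS
    um_per_pixel: float | None = None
    condition: str = "wild_type"
    animal_id: str = "animal0"
    stimulus: StimulusProtocol | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        T = len(self.frame_index)
        if self.points.shape != (T, N_POINTS, 2) or self.widths.shape != (T, N_POINTS):
            raise SchemaError(
                f"recording {self.animal_id}: inconsistent shapes "
                f"{self.points.shape} / {self.widths.shape} for {T} frames"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if T > 1 and np.any(np.diff(self.frame_index) <= 0):
            raise SchemaError(f"recording {self.animal_id}: frame indices not strictly increasing")

    def __len__(self) -> int:
        return len(self.frame_index)

    def __iter__(self) -> Iterator[SkeletonFrame]:
        for i in range(len(self)):
            yield self.frame(i)

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(
            points=self.points[i],
            widths=self.widths[i],
            valid=bool(self.valid[i]),
            frame_index=int(self.frame_index[i]),
        )

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid)) if len(self) else 0.0

    @classmethod
    def from_frames(cls, frames: Sequence[SkeletonFrame], **meta) -> "TrackRecording":
        return cls(
            points=np.stack([f.points for f in frames]),
            widths=np.stack([f.widths for f in frames]),
            valid=np.array([f.valid for f in frames]),
            frame_index=np.array([f.frame_index for f in frames]),
            **meta,
        )


@dataclass
class Dataset:
    """Recordings grouped by condition with an explicit control pairing.

    ``control_map`` declares, for every non-control condition, which condition
    is its statistical control (e.g. every drug -> wild type, dopamine ->
    ascorbic acid).
    """

    recordings: dict[str, list[TrackRecording]] = field(default_factory=dict)
    control_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, ctrl in self.control_map.items():
            if ctrl not in self.recordings:
                raise ValueError(f"condition {cond!r} declares missing control {ctrl!r}")

    def add(self, rec: TrackRecording) -> None:
        self.recordings.setdefault(rec.condition, []).append(rec)

    def conditions(self) -> list[str]:
        return list(self.recordings)

    def all_recordings(self) -> list[TrackRecording]:
        return [r for recs in self.recordings.values() for r in recs]

    def control_of(self, condition: str) -> str:
        try:
            return self.control_map[condition]
        except KeyError:
            raise KeyError(f"no control declared for condition {condition!r}") from None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_CSV_COLUMNS = (
    ["frame_index", "valid"]
    + [f"x{i}" for i in range(N_POINTS)]
    + [f"y{i}" for i in range(N_POINTS)]
    + [f"w{i}" for i in range(N_POINTS)]
)


def write_recording(rec: TrackRecording, path: str | Path) -> None:
    """Write the CSV interchange format: one row per frame,
    frame_index, valid, x0..x48, y0..y48, w0..w48."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for i in range(len(rec)):
            row = [int(rec.frame_index[i]), int(rec.valid[i])]
            row += [f"{v:.6f}" for v in rec.points[i, :, 0]]
            row += [f"{v:.6f}" for v in rec.points[i, :, 1]]
            row += [f"{v:.6f}" for v in rec.widths[i]]
            writer.writerow(row)


def _read_csv_recording(path: Path) -> TrackRecording:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing[:3]}...")
    xs = df[[f"x{i}" for i in range(N_POINTS)]].to_numpy(float)
    ys = df[[f"y{i}" for i in range(N_POINTS)]].to_numpy(float)
    widths = df[[f"w{i}" for i in range(N_POINTS)]].to_numpy(float)
    points = np.stack([xs, ys], axis=-1)
    valid = df["valid"].to_numpy().astype(bool)
    # frames whose coordinates failed to parse or are NaN are flagged, not dropped
    bad = ~np.isfinite(points).all(axis=(1, 2))
    valid = valid & ~bad
    return TrackRecording(
        points=points,
        widths=widths,
        valid=valid,
        frame_index=df["frame_index"].to_numpy(int),
        animal_id=path.stem,
    )


def _read_tierpsy_hdf5(path: Path) -> TrackRecording:
    import h5py

    with h5py.File(path, "r") as f:
        skel_key = next((k for k in ("skeletons", "coordinates/skeletons", "skeleton") if k in f), None)
        if skel_key is None:
            raise ParseError(f"{path}: no skeleton dataset found (looked for 'skeletons')")
        skel = np.asarray(f[skel_key], dtype=float)
        width_key = next((k for k in ("widths", "coordinates/widths", "width") if k in f), None)
        widths = np.asarray(f[width_key], dtype=float) if width_key else np.full(skel.shape[:2], np.nan)
        fps = float(f.attrs.get("fps", DEFAULT_FPS))
    if skel.ndim != 3 or skel.shape[1] != N_POINTS or skel.shape[2] != 2:
        raise SchemaError(f"{path}: skeleton array has shape {skel.shape}, expected (T, {N_POINTS}, 2)")
    valid = np.isfinite(skel).all(axis=(1, 2))
    widths = np.where(np.isfinite(widths), widths, 0.0)
    return TrackRecording(
        points=skel,
        widths=widths,
        valid=valid,
        frame_index=np.arange(len(skel)),
        fps=fps,
        animal_id=path.stem,
    )


def read_recording(path: str | Path, dialect: str = "csv-interchange") -> TrackRecording:
    """Load a recording. ``dialect`` is 'csv-interchange' or 'tierpsy-hdf5'.

    All frames are loaded in order; frames with missing/non-finite
    coordinates are flagged ``valid=False`` rather than dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv-interchange":
        return _read_csv_recording(path)
    if dialect == "tierpsy-hdf5":
        return _read_tierpsy_hdf5(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_manifest(ds: Dataset, directory: str | Path) -> Path:
    """Write every recording as CSV plus a manifest table
    (path, condition, control, fps, animal_id)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for cond, recs in ds.recordings.items():
        for rec in recs:
            fname = f"{cond}_{rec.animal_id}.csv"
            write_recording(rec, directory / fname)
            rows.append(
                {
                    "path": fname,
                    "condition": cond,
                    "control": ds.control_map.get(cond, ""),
                    "fps": rec.fps,
                    "animal_id": rec.animal_id,
                }
            )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest: str | Path) -> Dataset:
    manifest = Path(manifest)
    df = pd.read_csv(manifest, keep_default_na=False)
    ds = Dataset()
    for _, row in df.iterrows():
        rec = read_recording(manifest.parent / row["path"])
        rec.condition = row["condition"]
        rec.fps = float(row["fps"])
        rec.animal_id = str(row["animal_id"])
        ds.add(rec)
    for _, row in df.iterrows():
        if row["control"]:
            ds.control_map[row["condition"]] = row["control"]
    return ds


# ---------------------------------------------------------------------------
# filtering and calibration
# ---------------------------------------------------------------------------


def filter_recordings(ds: Dataset, min_valid_fraction: float) -> Dataset:
    """Keep recordings whose fraction of successfully segmented frames is at
    least ``min_valid_fraction`` (the study used 0.8 for model fitting).
    Order within conditions is preserved; the operation is idempotent and
    monotone in the threshold."""
    if not 0.0 <= min_valid_fraction <= 1.0:
        raise ValueError("min_valid_fraction must be in [0, 1]")
    kept = {
        cond: [r for r in recs if r.valid_fraction >= min_valid_fraction]
        for cond, recs in ds.recordings.items()
    }
    kept = {cond: recs for cond, recs in kept.items() if recs}
    control_map = {c: k for c, k in ds.control_map.items() if c in kept and k in kept}
    return Dataset(recordings=kept, control_map=control_map)


def calibrate_scale(length_px: float, length_um: float) -> float:
    """Micrometers per pixel from a calibration length measured both ways.

    The study's average larva measured 115.10 px = 1,330.61 um, giving
    ~11.56 um/px.
    """
    if length_px <= 0 or length_um <= 0:
        raise ValueError("calibration lengths must be positive")
    return length_um / length_px
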