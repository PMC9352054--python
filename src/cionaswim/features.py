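"""Per-frame biophysical featurization of 49-point larval skeletons.

The larva is split into 7 body segments (Head, Neck, TailBase, TailPreMid,
TailMid, TailPostMid, TailTip) around an automatically detected neck point —
the skeleton index in [4, 22] where the contour width drops most sharply,
marking the transition from the wide trunk to the narrow tail.

Features computed per frame:

* signed curvature at each of the 49 points (Savitzky-Golay derivatives,
  window 15, order 2, over point index; positive = leftward bend relative to
  head->tail traversal in image coordinates),
* the 7 segment curvatures sampled at segment midpoints (cH..cTT),
* 6 relative tangent angles (segment chord orientation minus head chord
  orientation, wrapped to (-pi, pi]),
* quirkiness, a bounded eccentricity of the body's principal-axis bounding
  box: q = sqrt(1 - (b/a)^2), 1 for a straight body, ->0 for a maximally
  bent one,
* 6 segment speeds (mean per-point displacement between adjacent frames,
  px/frame),
* a head-rigidity diagnostic comparing point deviations from the head chord
  vs the tail chord.

The 25-column feature panel (6 segment curvatures excluding the head, 6
relative tangent angles, 6 segment speeds, EC1..EC6, quirkiness) is the input
to the downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .io_model import N_POINTS, TrackRecording

SEGMENT_NAMES = ("H", "N", "TB", "TprM", "TM", "TpoM", "TT")
TAIL_SEGMENT_NAMES = SEGMENT_NAMES[1:]  # everything but the head

PANEL_COLUMNS = (
    [f"c{s}" for s in TAIL_SEGMENT_NAMES]
    + [f"rta{s}" for s in TAIL_SEGMENT_NAMES]
    + [f"s{s}" for s in TAIL_SEGMENT_NAMES]
    + [f"EC{i}" for i in range(1, 7)]
    + ["quirkiness"]
)

SG_WINDOW = 15
SG_ORDER = 2
NECK_RANGE = (4, 22)


class NeckDetectionError(ValueError):
    """Width profile has no sharp decrease in the allowed neck range."""


@dataclass(frozen=True)
class SegmentPartition:
    """Contiguous, disjoint index ranges covering skeleton points 0..48.

    Head = 0..neck-2, Neck = the 3 points centered on the neck index, and the
    remaining tail points split into 5 as-equal-as-possible contiguous blocks
    (remainder to the most posterior blocks). ``midpoints`` holds the central
    index of each of the 7 segments (lower-middle on even sizes).
    """

    neck_index: int
    ranges: tuple[tuple[int, int], ...]  # 7 half-open (start, stop) index ranges
    midpoints: tuple[int, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return SEGMENT_NAMES


def detect_neck(widths: np.ndarray, lo: int = NECK_RANGE[0], hi: int = NECK_RANGE[1]) -> int:
    """Neck = index in [lo, hi] with the most negative smoothed width gradient.

    The width profile is smoothed with a 5-point moving average before
    differencing; ties break toward the anterior (smaller) index.
    """
    w = np.asarray(widths, dtype=float)
    if w.shape != (N_POINTS,) or not np.all(np.isfinite(w)):
        raise ValueError("expected 49 finite contour widths")
    smooth = np.convolve(w, np.ones(5) / 5.0, mode="same")
    grad = np.diff(smooth)  # grad[i] = smooth[i+1] - smooth[i]
    window = grad[lo : hi + 1]
    if np.min(window) >= 0:
        raise NeckDetectionError("contour width never decreases in the neck search range")
    return lo + int(np.argmin(window))


def partition_segments(neck_index: int) -> SegmentPartition:
    lo, hi = NECK_RANGE
    if not lo <= neck_index <= hi:
        raise ValueError(f"neck index {neck_index} outside [{lo}, {hi}]")
    head = (0, neck_index - 1)  # points 0..neck-2
    neck = (neck_index - 1, neck_index + 2)  # 3 points centered on the neck
    tail_start = neck_index + 2
    n_tail = N_POINTS - tail_start
    base, rem = divmod(n_tail, 5)
    # remainder goes to the most posterior blocks
    sizes = [base + (1 if i >= 5 - rem else 0) for i in range(5)]
    ranges = [head, neck]
    start = tail_start
    for size in sizes:
        ranges.append((start, start + size))
        start += size
    midpoints = tuple((a + b - 1) // 2 for a, b in ranges)
    return SegmentPartition(neck_index=neck_index, ranges=tuple(ranges), midpoints=midpoints)


def partition_recording(rec: TrackRecording) -> SegmentPartition:
    """One partition per recording, from the median width profile over valid
    frames (the neck is anatomical, not frame-varying)."""
    if not rec.valid.any():
        raise ValueError("recording has no valid frames")
    median_widths = np.nanmedian(rec.widths[rec.valid], axis=0)
    return partition_segments(detect_neck(median_widths))


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------


def curvature(points: np.ndarray, window: int = SG_WINDOW, order: int = SG_ORDER) -> np.ndarray:
    """Signed curvature at every skeleton point.

    kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^{3/2}, derivatives taken with
    respect to point index via a Savitzky-Golay filter (window 15, order 2),
    approximating the skeleton by a smooth curve. Accepts (49, 2) or
    (T, 49, 2); vectorized over frames.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 2
    if single:
        pts = pts[None]
    x, y = pts[..., 0], pts[..., 1]
    x1 = savgol_filter(x, window, order, deriv=1, axis=-1)
    y1 = savgol_filter(y, window, order, deriv=1, axis=-1)
    x2 = savgol_filter(x, window, order, deriv=2, axis=-1)
    y2 = savgol_filter(y, window, order, deriv=2, axis=-1)
    denom = (x1**2 + y1**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (x1 * y2 - y1 * x2) / denom
    return kappa[0] if single else kappa


def segment_curvature(kappa: np.ndarray, partition: SegmentPartition) -> np.ndarray:
    """Curvature sampled at the 7 segment midpoints (cH..cTT).

    Accepts (49,) or (T, 49); returns (7,) or (T, 7).
    """
    mids = list(partition.midpoints)
    return np.asarray(kappa, dtype=float)[..., mids]


# ---------------------------------------------------------------------------
# tangent angles, quirkiness, speeds
# ---------------------------------------------------------------------------


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return -np.mod(-np.asarray(a) + np.pi, 2 * np.pi) + np.pi


def relative_tangent_angles(points: np.ndarray, partition: SegmentPartition) -> np.ndarray:
    """6 relative tangent angles (neck..tail tip), radians in (-pi, pi].

    Each segment's tangent angle is the arctan2 orientation of the chord
    joining its two end skeleton points; the head segment's angle is the
    reference. Accepts (49, 2) or (T, 49, 2).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 2
    if single:
        pts = pts[None]
    angles = []
    for start, stop in partition.ranges:
        chord = pts[:, stop - 1] - pts[:, start]
        if np.any(np.all(chord == 0, axis=-1)):
            raise ValueError("coincident segment endpoints: tangent angle undefined")
        angles.append(np.arctan2(chord[:, 1], chord[:, 0]))
    theta = np.stack(angles, axis=1)  # (T, 7)
    rta = _wrap_angle(theta[:, 1:] - theta[:, :1])
    return rta[0] if single else rta


def quirkiness(points: np.ndarray) -> float | np.ndarray:
    """Eccentricity of the skeleton's principal-axis bounding box.

    q = sqrt(1 - (b/a)^2) with a >= b the point cloud's extents along its two
    principal axes. 1 = perfectly straight body; near 0 = bounding box nearly
    square (highly curled). Rotation invariant by construction.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 2
    if single:
        pts = pts[None]
    centered = pts - pts.mean(axis=1, keepdims=True)
    out = np.empty(len(pts))
    for i, c in enumerate(centered):
        # principal axes from the 2x2 scatter matrix
        cov = c.T @ c
        _, vecs = np.linalg.eigh(cov)
        proj = c @ vecs
        extents = proj.max(axis=0) - proj.min(axis=0)
        a, b = max(extents), min(extents)
        if a == 0:
            raise ValueError("all skeleton points coincide; quirkiness undefined")
        out[i] = np.sqrt(1.0 - (b / a) ** 2)
    return float(out[0]) if single else out


def segment_speeds(rec: TrackRecording, partition: SegmentPartition | None = None) -> np.ndarray:
    """(T, 6) segment speeds in px/frame for segments neck..tail tip.

    Per-point speed is the Euclidean displacement between consecutive frames;
    a segment's speed is the mean over its points. The first frame and any
    frame adjacent to an invalid frame are NaN (masked, not interpolated).
    Convert to um/s by multiplying with ``um_per_pixel * fps``.
    """
    if partition is None:
        partition = partition_recording(rec)
    T = len(rec)
    disp = np.full((T, N_POINTS), np.nan)
    if T >= 2:
        step = np.linalg.norm(np.diff(rec.points, axis=0), axis=-1)  # (T-1, 49)
        ok = rec.valid[1:] & rec.valid[:-1]
        step[~ok] = np.nan
        disp[1:] = step
    speeds = np.stack([disp[:, a:b].mean(axis=1) for a, b in partition.ranges[1:]], axis=1)
    return speeds


def head_rigidity_profile(rec: TrackRecording, partition: SegmentPartition | None = None) -> pd.DataFrame:
    """Per-point chord-deviation distributions used to demonstrate head rigidity.

    For head-region points: perpendicular distance to the chord joining the
    head tip and the neck point. For tail-region points: distance to the
    chord joining the neck point and the tail tip. Returns a tidy frame with
    columns (point, region, deviation), one row per valid frame and point.
    """
    if partition is None:
        partition = partition_recording(rec)
    neck = partition.neck_index
    pts = rec.points[rec.valid]
    rows = []

    def _dists(p0: np.ndarray, p1: np.ndarray, pts_sub: np.ndarray) -> np.ndarray:
        chord = p1 - p0  # (F, 2)
        norm = np.linalg.norm(chord, axis=-1, keepdims=True)
        norm[norm == 0] = np.nan  # degenerate chord -> masked
        d = pts_sub - p0[:, None]
        cross = np.abs(chord[:, None, 0] * d[..., 1] - chord[:, None, 1] * d[..., 0])
        return cross / norm

    head_dev = _dists(pts[:, 0], pts[:, neck], pts[:, 1:neck])
    tail_dev = _dists(pts[:, neck], pts[:, -1], pts[:, neck + 1 : -1])
    for j in range(head_dev.shape[1]):
        for v in head_dev[:, j]:
            rows.append((j + 1, "head", v))
    for j in range(tail_dev.shape[1]):
        for v in tail_dev[:, j]:
            rows.append((neck + 1 + j, "tail", v))
    return pd.DataFrame(rows, columns=["point", "region", "deviation"])


# ---------------------------------------------------------------------------
# feature panel assembly
# ---------------------------------------------------------------------------


def feature_panel(
    rec: TrackRecording,
    eigencoefficients: np.ndarray,
    partition: SegmentPartition | None = None,
) -> pd.DataFrame:
    """The 25-feature per-frame panel: 6 segment curvatures (neck..tail tip),
    6 relative tangent angles, 6 segment speeds, EC1..EC6, quirkiness.

    ``eigencoefficients`` is (T, 6) (see :mod:`cionaswim.eigenposture`).
    Rows for invalid frames are NaN.
    """
    if partition is None:
        partition = partition_recording(rec)
    T = len(rec)
    ec = np.asarray(eigencoefficients, dtype=float)
    if ec.shape != (T, 6):
        raise ValueError(f"eigencoefficients must be (T, 6); got {ec.shape}")
    data = np.full((T, 25), np.nan)
    vmask = rec.valid
    kappa = curvature(rec.points[vmask])
    data[vmask, 0:6] = segment_curvature(kappa, partition)[:, 1:]
    data[vmask, 6:12] = relative_tangent_angles(rec.points[vmask], partition)
    data[:, 12:18] = segment_speeds(rec, partition)
    data[vmask, 18:24] = ec[vmask]
    data[vmask, 24] = quirkiness(rec.points[vmask])
    df = pd.DataFrame(data, columns=PANEL_COLUMNS)
    df.insert(0, "frame_index", rec.frame_index)
    df.insert(0, "animal_id", rec.animal_id)
    return df
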