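"""Behavioral motif discovery via the multidimensional matrix profile.

The input is the 7-channel time series of segment curvatures (cH..cTT) of one
animal, smoothed by a 10-frame rolling mean. For a window length m (30 frames
= 1 s or 150 frames = 5 s at 30 fps), the all-dimensions matrix profile
assigns to every subsequence start the mean over channels of the z-normalized
Euclidean distance to its best jointly matching other subsequence (trivial
matches within ceil(m/2) of self excluded). Profile dips below a threshold of
8 mark onsets of recurring motifs; the extracted 7xm motifs are clustered
k-means-style into 15 groups and their per-condition usage compared against
control.

The profile here is computed by exact vectorized all-pairs distances — the
same quantity an mSTAMP-style algorithm produces with all 7 dimensions
included — and is verified against a brute-force oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

N_CHANNELS = 7


@dataclass(frozen=True)
class MotifConfig:
    """Mining parameters: window length (30 or 150 frames), profile threshold
    8, 10-frame rolling-mean smoothing, 15 clusters."""

    m: int = 30
    profile_threshold: float = 8.0
    smoothing: int = 10
    n_clusters: int = 15

    def __post_init__(self) -> None:
        if self.m < 4:
            raise ValueError("window must be at least 4 frames")
        if self.profile_threshold <= 0:
            raise ValueError("profile threshold must be positive")


def window_frames(seconds: float, fps: float = 30.0) -> int:
    """Window length in frames for a duration in seconds (5 s -> 150 at 30 fps)."""
    return int(round(seconds * fps))


@dataclass
class Motif:
    recording_id: str
    start_frame: int
    m: int
    data: np.ndarray  # (7, m) segment curvatures
    profile_value: float
    cluster_label: int | None = None  # 1..15 once clustered


@dataclass
class MotifClusterModel:
    centers: np.ndarray  # (k, 7, m)
    labels: np.ndarray  # (n_motifs,), values 1..k
    inertia: float
    k: int
    seed: int


# ---------------------------------------------------------------------------
# smoothing and profile
# ---------------------------------------------------------------------------


def smooth_channels(series: np.ndarray, width: int = 10) -> np.ndarray:
    """Centered rolling mean per channel, window ``width``; edges are means of
    the truncated window. Input (C, T), output same shape."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] < width:
        raise ValueError(f"series length {series.shape[1]} shorter than smoothing window {width}")
    df = pd.DataFrame(series.T)
    out = df.rolling(window=width, center=True, min_periods=1).mean()
    return out.to_numpy().T


def _znorm_windows(channel: np.ndarray, m: int, var_floor: float = 1e-8) -> np.ndarray:
    """(n_sub, m) matrix of z-normalized sliding windows of one channel.

    Near-constant windows (std < floor) z-normalize to zeros, so two constant
    windows are at distance 0 of each other.
    """
    n = len(channel) - m + 1
    idx = np.arange(m)[None, :] + np.arange(n)[:, None]
    W = channel[idx]
    mu = W.mean(axis=1, keepdims=True)
    sd = W.std(axis=1, keepdims=True)
    Wc = W - mu
    Wz = np.where(sd < var_floor, 0.0, Wc / np.maximum(sd, var_floor))
    return Wz


def matrix_profile_md(series: np.ndarray, m: int, exclusion: int | None = None) -> np.ndarray:
    """All-dimensions multidimensional matrix profile of a (7, T) series.

    profile[i] = min over j (|i-j| >= ceil(m/2)) of the mean over the 7
    channels of the z-normalized Euclidean distance between windows i and j.
    Exact O(T^2) computation, vectorized one channel at a time.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be (channels, T)")
    C, T = series.shape
    if T < 2 * m:
        raise ValueError(f"series length {T} must be at least 2*m = {2 * m}")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values; split at gaps first")
    n = T - m + 1
    excl = int(np.ceil(m / 2)) if exclusion is None else exclusion
    dist_sum = np.zeros((n, n))
    for c in range(C):
        Wz = _znorm_windows(series[c], m)
        # z-normed distance^2 = 2m - 2 <zi, zj>  (for full-variance windows
        # |z|^2 = m; near-constant windows are zero vectors, handled exactly)
        G = Wz @ Wz.T
        sq = np.einsum("ij,ij->i", Wz, Wz)
        d2 = sq[:, None] + sq[None, :] - 2.0 * G
        np.maximum(d2, 0.0, out=d2)
        dist_sum += np.sqrt(d2)
    dist_sum /= C
    i = np.arange(n)
    mask = np.abs(i[:, None] - i[None, :]) < excl
    dist_sum[mask] = np.inf
    return dist_sum.min(axis=1)


def extract_motifs(profile: np.ndarray, m: int, threshold: float = 8.0) -> list[int]:
    """Motif onsets: local minima of the profile below ``threshold``, accepted
    greedily in ascending profile order with an exclusion zone of m frames
    between accepted starts. Lowering the threshold never adds motifs."""
    p = np.asarray(profile, dtype=float)
    n = len(p)
    if n == 0:
        return []
    # local minima (plateau-tolerant: <= both neighbors, < at least one side
    # or boundary)
    left = np.r_[np.inf, p[:-1]]
    right = np.r_[p[1:], np.inf]
    is_min = (p <= left) & (p <= right) & ((p < left) | (p < right) | ((left == np.inf) & (right == np.inf)))
    candidates = np.where(is_min & (p < threshold))[0]
    order = candidates[np.argsort(p[candidates], kind="stable")]
    accepted: list[int] = []
    for idx in order:
        if all(abs(idx - a) >= m for a in accepted):
            accepted.append(int(idx))
    return sorted(accepted)


def mine_recording(
    series: np.ndarray,
    recording_id: str,
    config: MotifConfig = MotifConfig(),
    valid: np.ndarray | None = None,
) -> list[Motif]:
    """Smooth, profile and extract motifs from one animal's (7, T) segment
    curvature series. Windows overlapping invalid frames are discarded."""
    smoothed = smooth_channels(series, config.smoothing)
    profile = matrix_profile_md(smoothed, config.m)
    starts = extract_motifs(profile, config.m, config.profile_threshold)
    motifs = []
    for s in starts:
        if valid is not None and not np.all(valid[s : s + config.m]):
            continue
        motifs.append(
            Motif(
                recording_id=recording_id,
                start_frame=s,
                m=config.m,
                data=smoothed[:, s : s + config.m].copy(),
                profile_value=float(profile[s]),
            )
        )
    return motifs


# ---------------------------------------------------------------------------
# clustering and usage
# ---------------------------------------------------------------------------


def cluster_motifs(motifs: list[Motif], k: int = 15, seed: int = 0) -> MotifClusterModel:
    """k-means on the flattened 7xm motif matrices (Euclidean metric, no
    per-motif normalization — cluster amplitude is informative). Labels are
    written back onto the motifs as 1..k."""
    if len(motifs) < k:
        raise ValueError(f"need at least k={k} motifs; got {len(motifs)}")
    X = np.stack([mo.data.ravel() for mo in motifs])
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X) + 1
    for mo, lab in zip(motifs, labels):
        mo.cluster_label = int(lab)
    shape = motifs[0].data.shape
    centers = km.cluster_centers_.reshape(k, *shape)
    return MotifClusterModel(centers=centers, labels=labels, inertia=float(km.inertia_), k=k, seed=seed)


def inertia_curve(motifs: list[Motif], ks: list[int], seed: int = 0) -> pd.DataFrame:
    """k-means inertia over candidate cluster counts, for elbow selection."""
    X = np.stack([mo.data.ravel() for mo in motifs])
    rows = []
    for k in ks:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
        rows.append({"k": k, "inertia": float(km.inertia_)})
    return pd.DataFrame(rows)


def elbow_select(ks: np.ndarray, inertia: np.ndarray) -> int:
    """Elbow = k at the maximum discrete second difference of the inertia
    curve (the point where the decrease levels out); ties break toward the
    smallest k."""
    ks = np.asarray(ks)
    inertia = np.asarray(inertia, dtype=float)
    if len(ks) < 4:
        raise ValueError("need at least 4 candidate cluster counts")
    second = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]
    return int(ks[1:-1][int(np.argmax(second))])


def motif_usage(
    motifs_by_condition: dict[str, list[Motif]],
    control_map: dict[str, str],
    k: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition cluster shares (%) and percentage fold change vs control.

    Shares sum to 100 per condition; fold change for condition c, cluster j is
    100 * (share_c[j] - share_ctrl[j]) / share_ctrl[j].
    """
    shares = {}
    for cond, motifs in motifs_by_condition.items():
        labels = np.array([mo.cluster_label for mo in motifs])
        if any(l is None for l in labels):
            raise ValueError(f"unclustered motifs in condition {cond!r}")
        counts = np.bincount(labels, minlength=k + 1)[1:]
        shares[cond] = 100.0 * counts / counts.sum()
    usage = pd.DataFrame(shares, index=[f"cluster_{j}" for j in range(1, k + 1)]).T
    fold_rows = {}
    for cond, ctrl in control_map.items():
        if ctrl not in shares:
            raise ValueError(f"control {ctrl!r} for {cond!r} has no motifs")
        with np.errstate(divide="ignore", invalid="ignore"):
            fold_rows[cond] = 100.0 * (shares[cond] - shares[ctrl]) / shares[ctrl]
    fold = pd.DataFrame(fold_rows, index=usage.columns).T
    return usage, fold
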