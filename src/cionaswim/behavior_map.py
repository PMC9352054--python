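"""Spatiotemporal behavioral-space mapping.

Each frame's posture dynamics are summarized by the moduli of continuous
Morlet wavelet transforms of the six eigencoefficient channels at 30
uniformly spaced frequencies in [1, 30] Hz — a 180-dimensional spectrotemporal
feature vector. A training sample of frames, drawn with probability
proportional to a speed-weighted sum (neck 50%, each tail segment 10%), is
embedded three times with t-SNE (cosine metric, PCA initialization, differing
perplexity/exaggeration); the composite 4-D space [e1.x, e1.y, e2.x, e3.y] is
density-clustered (DBSCAN) into behavioral regions, and a 200-nearest-neighbor
distance-weighted classifier assigns any further frames to those regions.

Numerical conventions: Morlet center parameter omega0 = 5, modulus (not real
part), reflective edge padding, per-scale 1/sqrt(scale) amplitude
normalization. The kNN assigner votes in the 180-dim wavelet feature space
(well defined for unseen frames without re-embedding); DBSCAN eps /
min_samples are configuration, with a sweep utility targeting a desired
cluster count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.neighbors import KNeighborsClassifier

N_EC = 6
N_SCALES = 30
N_WAVELET = N_EC * N_SCALES  # 180
OMEGA0 = 5.0

# (perplexity, exaggeration) of the three planar embeddings; the composite
# space keeps e1.x, e1.y, e2.x, e3.y
EMBEDDING_PARAMS = ((500.0, 12.0), (250.0, 3.0), (750.0, 2.0))
REFERENCE_N = 200_000  # sample size the perplexities above were chosen for


def wavelet_frequencies(fmin: float = 1.0, fmax: float = 30.0, n: int = N_SCALES) -> np.ndarray:
    return np.linspace(fmin, fmax, n)


def wavelet_features(ec_series: np.ndarray, fps: float = 30.0, omega0: float = OMEGA0) -> np.ndarray:
    """(180, T) Morlet power features of a gap-free (6, T) EC series.

    Continuous complex-Morlet transform per channel at 30 frequencies in
    [1, 30] Hz; reflective padding absorbs edge effects; moduli are scaled by
    1/sqrt(scale) so amplitude is comparable across frequencies.
    """
    ec = np.atleast_2d(np.asarray(ec_series, dtype=float))
    if ec.shape[0] != N_EC:
        raise ValueError(f"expected {N_EC} EC channels; got {ec.shape[0]}")
    T = ec.shape[1]
    if T < 64:
        raise ValueError(f"series too short for wavelet support ({T} < 64 frames)")
    if not np.all(np.isfinite(ec)):
        raise ValueError("EC series contains gaps; split at invalid frames first")
    freqs = wavelet_frequencies()
    wavelet = pywt.ContinuousWavelet(f"cmor1.0-{omega0 / (2 * np.pi):.8f}")
    scales = pywt.frequency2scale(wavelet, freqs / fps)
    pad = min(T, int(np.ceil(scales.max() * 2)))
    out = np.empty((N_WAVELET, T))
    for c in range(N_EC):
        padded = np.pad(ec[c], pad, mode="reflect")
        coeffs, _ = pywt.cwt(padded, scales, wavelet)
        mod = np.abs(coeffs[:, pad : pad + T]) / np.sqrt(scales)[:, None]
        out[c * N_SCALES : (c + 1) * N_SCALES] = mod
    return out


def speed_weighted_sample(
    speeds: np.ndarray,
    n: int = REFERENCE_N,
    seed: int = 0,
) -> tuple[np.ndarray, bool]:
    """Draw frame indices with probability proportional to
    w = 0.5*sN + 0.1*(sTB + sTprM + sTM + sTpoM + sTT).

    ``speeds`` is (T, 6) in the order neck..tail tip; NaN rows get weight 0.
    Draws are without replacement when n <= available frames, otherwise with
    replacement (flagged by the second return value). All-zero weights fall
    back to uniform with a warning.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.ndim != 2 or speeds.shape[1] != 6:
        raise ValueError("speeds must be (T, 6): neck + 5 tail segments")
    coeff = np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
    w = np.where(np.isfinite(speeds).all(axis=1), speeds @ coeff, 0.0)
    w = np.clip(w, 0.0, None)
    if w.sum() == 0:
        warnings.warn("all sampling weights zero; falling back to uniform")
        w = np.ones(len(w))
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    available = int(np.sum(p > 0))
    replace = n > available
    if replace:
        warnings.warn(f"requested {n} > {available} weighted frames; sampling with replacement")
    idx = rng.choice(len(p), size=min(n, len(p)) if not replace else n, replace=replace, p=p)
    return idx, replace


@dataclass
class EmbeddingModel:
    """Composite 4-D behavioral-space embedding of a training frame sample."""

    features: np.ndarray  # (n, 180) training wavelet features
    composite: np.ndarray  # (n, 4) = [e1.x, e1.y, e2.x, e3.y]
    embeddings: list[np.ndarray]  # the three full planar embeddings
    perplexities: tuple[float, float, float]
    seed: int


def _scaled_perplexity(p: float, n: int) -> float:
    """Perplexities were chosen for a 200,000-frame sample; for smaller
    samples they scale proportionally, floored at 30 (the conventional
    t-SNE neighborhood size — smaller values shatter coherent clusters)
    and capped at (n - 1) / 3."""
    scaled = max(30.0, p * n / REFERENCE_N)
    return min(scaled, max(5.0, (n - 1) / 3.0))


def fit_embedding(features: np.ndarray, seed: int = 0) -> EmbeddingModel:
    """Three 2-D t-SNE embeddings (cosine metric, PCA init) of (n, 180)
    wavelet features, combined into the composite 4-D space.

    e1 runs perplexity 500 with early exaggeration 12 then 1; e2 perplexity
    250, exaggeration 3; e3 perplexity 750, exaggeration 2 (exaggerations
    applied as the early phase; the final phase is unexaggerated).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_WAVELET:
        raise ValueError(f"features must be (n, {N_WAVELET})")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite wavelet features")
    n = len(X)
    embeddings = []
    perps = []
    for i, (perp, exag) in enumerate(EMBEDDING_PARAMS):
        p = _scaled_perplexity(perp, n)
        perps.append(p)
        ts = TSNE(
            n_components=2,
            perplexity=p,
            early_exaggeration=exag,
            init="pca",
            metric="cosine",
            random_state=seed + i,
        )
        embeddings.append(ts.fit_transform(X))
    composite = np.column_stack(
        [embeddings[0][:, 0], embeddings[0][:, 1], embeddings[1][:, 0], embeddings[2][:, 1]]
    )
    return EmbeddingModel(
        features=X,
        composite=composite,
        embeddings=embeddings,
        perplexities=tuple(perps),
        seed=seed,
    )


@dataclass
class BehaviorClusterModel:
    """Density clusters of the composite space plus the kNN assigner."""

    embedding: EmbeddingModel
    labels: np.ndarray  # per training frame; 1..k clusters, 0 = outlier
    n_clusters: int
    outlier_fraction: float
    eps: float
    min_samples: int
    classifier: KNeighborsClassifier = field(repr=False, default=None)


class ClusterTuningError(RuntimeError):
    """DBSCAN parameters produced no clusters; carries a diagnostic sweep."""

    def __init__(self, message: str, sweep: "np.ndarray | None" = None):
        super().__init__(message)
        self.sweep = sweep


def cluster_map(model: EmbeddingModel, eps: float, min_samples: int = 20, n_neighbors: int = 200) -> BehaviorClusterModel:
    """DBSCAN on the composite 4-D coordinates. Cluster labels are 1..k in
    decreasing size order; 0 marks outliers. A distance-weighted kNN
    classifier over the 180-dim training features is fitted on the non-outlier
    frames for out-of-sample assignment."""
    db = DBSCAN(eps=eps, min_samples=min_samples).fit(model.composite)
    raw = db.labels_
    uniq = [u for u in np.unique(raw) if u >= 0]
    if not uniq:
        raise ClusterTuningError(
            f"eps={eps}, min_samples={min_samples} produced 0 clusters; run sweep_eps() for diagnostics"
        )
    sizes = {u: int(np.sum(raw == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: -sizes[u])
    labels = np.zeros(len(raw), dtype=int)
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    outlier_fraction = float(np.mean(raw < 0))
    clf = None
    inliers = labels > 0
    if inliers.any():
        k = min(n_neighbors, int(inliers.sum()))
        clf = KNeighborsClassifier(n_neighbors=k, weights="distance")
        clf.fit(model.features[inliers], labels[inliers])
    return BehaviorClusterModel(
        embedding=model,
        labels=labels,
        n_clusters=len(uniq),
        outlier_fraction=outlier_fraction,
        eps=eps,
        min_samples=min_samples,
        classifier=clf,
    )


def sweep_eps(
    model: EmbeddingModel,
    eps_grid: np.ndarray,
    min_samples: int = 20,
    target_clusters: int = 6,
) -> "pd.DataFrame":
    """Diagnostic sweep: cluster count and outlier fraction over an eps grid,
    for choosing parameters that yield the desired number of behavioral
    regions."""
    import pandas as pd

    rows = []
    for eps in np.asarray(eps_grid, dtype=float):
        raw = DBSCAN(eps=eps, min_samples=min_samples).fit(model.composite).labels_
        rows.append(
            {
                "eps": eps,
                "n_clusters": int(len(set(raw[raw >= 0]))),
                "outlier_fraction": float(np.mean(raw < 0)),
                "hits_target": int(len(set(raw[raw >= 0]))) == target_clusters,
            }
        )
    return pd.DataFrame(rows)


def assign(features: np.ndarray, model: BehaviorClusterModel) -> np.ndarray:
    """Label new 180-dim wavelet frames by the distance-weighted vote of
    their (up to) 200 nearest training frames. Deterministic for a fixed
    model; an exact training frame reproduces its own label."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_WAVELET:
        raise ValueError(f"features must be (n, {N_WAVELET})")
    if model.classifier is None:
        raise RuntimeError("cluster model has no fitted classifier")
    return model.classifier.predict(X)


def occupancy_density(
    coords: np.ndarray,
    bins: int = 100,
    sigma: float = 2.0,
    saturation: float = 0.008,
    extent: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """2-D occupancy density of planar (e1) coordinates: histogram, Gaussian
    smoothing, intensity clipped at ``saturation`` x the smoothed maximum.

    The default saturation (0.8% of max) follows the published density plots;
    override for less aggressive clipping.
    """
    coords = np.asarray(coords, dtype=float)
    rng = (
        [(extent[0], extent[1]), (extent[2], extent[3])] if extent is not None else None
    )
    H, xe, ye = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins, range=rng, density=True)
    smooth = gaussian_filter(H, sigma=sigma)
    cap = saturation * smooth.max() if smooth.max() > 0 else 0.0
    return np.clip(smooth, None, cap), (xe, ye)


def cluster_transitions(
    label_sequences: list[tuple[np.ndarray, np.ndarray]],
    n_clusters: int,
    show_threshold: float = 0.001,
):
    """Row-stochastic transition matrix over behavioral clusters plus a
    filtered edge list.

    ``label_sequences`` holds (frame_index, labels) per recording, labels in
    1..k with 0 = outlier. Outlier frames are skipped without bridging the
    gap (a transition is only counted between consecutive frames that are
    both clustered); counts never cross recordings.
    """
    from .hmm_states import export_transition_graph

    counts = np.zeros((n_clusters, n_clusters))
    for frame_index, labels in label_sequences:
        frame_index = np.asarray(frame_index)
        labels = np.asarray(labels, dtype=int)
        step = np.diff(frame_index) == 1
        ok = step & (labels[:-1] > 0) & (labels[1:] > 0)
        np.add.at(counts, (labels[:-1][ok] - 1, labels[1:][ok] - 1), 1)
    row_sums = counts.sum(axis=1)
    matrix = np.where(
        (row_sums == 0)[:, None], 1.0 / n_clusters, counts / np.where(row_sums == 0, 1, row_sums)[:, None]
    )
    edges = export_transition_graph(
        matrix, show_threshold=show_threshold, state_names=[str(i) for i in range(1, n_clusters + 1)]
    )
    return matrix, edges
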