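"""Eigenposture decomposition of the 49-point curvature field.

Larval postures are summarized by PCA of the per-frame curvature vectors: the
49x49 sample covariance of curvature over frames is eigendecomposed, and the
leading eigenvectors ("eigencionas") form a basis of elementary postural
shapes. Six modes capture ~97% of the curvature variance in wild-type
recordings, so each posture reduces to six eigencoefficients EC1..EC6 — the
projections of the (mean-centered) curvature onto the basis.

Conventions fixed for reproducibility: eigenpairs in descending eigenvalue
order; each eigenvector's largest-magnitude entry made positive; projections
subtract the training mean (a ``center=False`` path exists for sensitivity
checks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import N_POINTS


@dataclass
class EigenBasis:
    """Curvature eigenmodes: mean profile, orthonormal eigenvector rows
    (descending eigenvalue order) and per-mode variance fractions."""

    mean_curvature: np.ndarray  # (49,)
    eigenvectors: np.ndarray  # (k, 49), rows orthonormal
    eigenvalues: np.ndarray  # (k,)
    variance_fraction: np.ndarray  # (k,), lambda_i / trace(C)
    k: int = 6
    center: bool = True

    @property
    def total_variance_fraction(self) -> float:
        return float(np.sum(self.variance_fraction))


def curvature_covariance(kappa: np.ndarray) -> np.ndarray:
    """49x49 sample covariance (denominator n-1) of per-frame curvature
    vectors; symmetrized to kill round-off asymmetry."""
    kappa = np.asarray(kappa, dtype=float)
    kappa = kappa[np.isfinite(kappa).all(axis=1)]
    if kappa.ndim != 2 or kappa.shape[1] != N_POINTS:
        raise ValueError(f"expected (n, {N_POINTS}) curvature frames; got {kappa.shape}")
    if len(kappa) < 2:
        raise ValueError("need at least 2 valid frames for a covariance")
    C = np.cov(kappa, rowvar=False, ddof=1)
    return (C + C.T) / 2.0


def eigendecompose(C: np.ndarray, k: int = 6, center: bool = True, mean_curvature: np.ndarray | None = None) -> EigenBasis:
    """Top-k eigenmodes of a symmetric 49x49 curvature covariance.

    Variance fractions are eigenvalues over the full trace, so the all-49
    fractions sum to 1. Deterministic: symmetric solver plus the fixed sign
    convention make the basis reproducible bit-for-bit for a fixed input.
    """
    C = np.asarray(C, dtype=float)
    if C.shape != (N_POINTS, N_POINTS) or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("covariance must be a symmetric 49x49 matrix")
    evals, evecs = np.linalg.eigh((C + C.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are eigenvectors
    # sign convention: largest-|entry| of each eigenvector positive
    flip = np.sign(evecs[np.arange(len(evecs)), np.argmax(np.abs(evecs), axis=1)])
    evecs = evecs * flip[:, None]
    total = float(np.sum(evals))
    frac = evals / total if total > 0 else np.zeros_like(evals)
    if mean_curvature is None:
        mean_curvature = np.zeros(N_POINTS)
    return EigenBasis(
        mean_curvature=np.asarray(mean_curvature, dtype=float),
        eigenvectors=evecs[:k],
        eigenvalues=evals[:k],
        variance_fraction=frac[:k],
        k=k,
        center=center,
    )


def fit_eigenbasis(kappa: np.ndarray, k: int = 6, center: bool = True) -> EigenBasis:
    """Covariance + eigendecomposition + training mean, in one step.

    ``kappa`` is (n_frames, 49); non-finite rows (masked frames) are ignored.
    """
    kappa = np.asarray(kappa, dtype=float)
    kappa = kappa[np.isfinite(kappa).all(axis=1)]
    C = curvature_covariance(kappa)
    return eigendecompose(C, k=k, center=center, mean_curvature=kappa.mean(axis=0))


def project(kappa: np.ndarray, basis: EigenBasis) -> np.ndarray:
    """Eigencoefficients EC = V (kappa - mean). Accepts (49,) or (T, 49);
    returns (k,) or (T, k). Non-finite frames project to NaN."""
    kappa = np.asarray(kappa, dtype=float)
    single = kappa.ndim == 1
    if kappa.shape[-1] != N_POINTS:
        raise ValueError(f"curvature frames must have {N_POINTS} points")
    centered = kappa - basis.mean_curvature if basis.center else kappa
    ec = centered @ basis.eigenvectors.T
    return ec[0] if single and ec.ndim == 2 else ec


def reconstruct(ec: np.ndarray, basis: EigenBasis) -> np.ndarray:
    """Inverse of :func:`project`: kappa_hat = mean + V^T EC."""
    ec = np.asarray(ec, dtype=float)
    rec = ec @ basis.eigenvectors
    if basis.center:
        rec = rec + basis.mean_curvature
    return rec


# ---------------------------------------------------------------------------
# serialization: CSV matrix + JSON sidecar
# ---------------------------------------------------------------------------


def save_eigenbasis(basis: EigenBasis, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    csv_path = Path(csv_path)
    rows = np.vstack([basis.mean_curvature, basis.eigenvectors])
    np.savetxt(csv_path, rows, delimiter=",")
    meta = {
        "k": basis.k,
        "center": basis.center,
        "eigenvalues": basis.eigenvalues.tolist(),
        "variance_fraction": basis.variance_fraction.tolist(),
    }
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=1))


def load_eigenbasis(csv_path: str | Path, json_path: str | Path | None = None) -> EigenBasis:
    csv_path = Path(csv_path)
    rows = np.loadtxt(csv_path, delimiter=",")
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    meta = json.loads(json_path.read_text())
    return EigenBasis(
        mean_curvature=rows[0],
        eigenvectors=rows[1:],
        eigenvalues=np.asarray(meta["eigenvalues"]),
        variance_fraction=np.asarray(meta["variance_fraction"]),
        k=int(meta["k"]),
        center=bool(meta["center"]),
    )
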