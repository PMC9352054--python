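"""Gaussian hidden-Markov segmentation of larval behavior.

A 10-state HMM with full covariance is fitted by EM (Baum-Welch) to the
7-dimensional per-frame feature series [EC1..EC6, quirkiness], pooled over
recordings (each recording is its own observation sequence; transitions never
cross recording boundaries). Viterbi decoding yields per-frame behavioral
state labels; per-condition state usage and empirical transition matrices
summarize the ethogram. hmmlearn provides the EM and Viterbi machinery.

Recordings are split at invalid-frame gaps into contiguous valid segments
before fitting/decoding (an HMM needs uninterrupted observations). Features
are used on their raw scales by default (state means/variances are then
directly interpretable); optional z-scoring is available.

Model selection follows the over-segmentation diagnostic used in the study:
fits with 6, 8, 10, 12 and 15 states are compared on log-likelihood and on
the number of states used by fewer than 1% of frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import linear_sum_assignment

STATE_LETTERS = "αβγδεζηθικλμνξο"  # display labels for states 0..14


@dataclass
class GHMMModel:
    """Fitted Gaussian HMM: probabilities, per-state Gaussians, fit log."""

    n_states: int
    startprob: np.ndarray  # (K,)
    transmat: np.ndarray  # (K, K), rows sum to 1
    means: np.ndarray  # (K, 7)
    covars: np.ndarray  # (K, 7, 7) for full; (K, 7) for diagonal
    covariance_type: str
    loglik_trace: list[float]
    seed: int

    def __post_init__(self) -> None:
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")

    def state_letter(self, s: int) -> str:
        return STATE_LETTERS[s] if s < len(STATE_LETTERS) else str(s)

    def to_hmmlearn(self) -> GaussianHMM:
        h = GaussianHMM(n_components=self.n_states, covariance_type=self.covariance_type)
        h.startprob_ = self.startprob
        h.transmat_ = self.transmat
        h.means_ = self.means
        h.covars_ = self.covars
        h.n_features = self.means.shape[1]
        return h


@dataclass
class StateSequence:
    recording_id: str
    frame_index: np.ndarray  # frames the labels refer to (valid frames only)
    states: np.ndarray  # per-frame state labels


def split_at_gaps(features: np.ndarray, valid: np.ndarray | None = None, min_length: int = 2) -> list[np.ndarray]:
    """Split a (T, d) feature series into contiguous finite/valid segments."""
    features = np.asarray(features, dtype=float)
    ok = np.isfinite(features).all(axis=1)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    segments = []
    edges = np.flatnonzero(np.diff(np.r_[0, ok.astype(int), 0]))
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a >= min_length:
            segments.append(features[a:b])
    return segments


def fit_ghmm(
    sequences: list[np.ndarray],
    n_states: int = 10,
    covariance_type: str = "full",
    seed: int = 0,
    n_iter: int = 200,
    tol: float = 1e-3,
) -> GHMMModel:
    """Baum-Welch fit over a pooled set of (T_i, d) observation sequences.

    Initialization is k-means on the pooled frames with the given seed
    (hmmlearn's default means initializer); convergence at log-likelihood
    gain < 1e-3 or 200 iterations. A small diagonal floor keeps covariances
    positive-definite. Deterministic for a fixed seed and input order.
    """
    if not sequences:
        raise ValueError("no observation sequences")
    sequences = [np.asarray(s, dtype=float) for s in sequences]
    for s in sequences:
        if not np.all(np.isfinite(s)):
            raise ValueError("sequence contains NaN; split at gaps first (split_at_gaps)")
    X = np.concatenate(sequences)
    lengths = [len(s) for s in sequences]
    cov_type = {"diagonal": "diag"}.get(covariance_type, covariance_type)
    h = GaussianHMM(
        n_components=n_states,
        covariance_type=cov_type,
        n_iter=n_iter,
        tol=tol,
        random_state=seed,
        min_covar=1e-6,
        init_params="",  # explicit k-means initialization below
    )
    # k-means on pooled frames seeds the means; per-cluster covariances and
    # label-bigram transition counts seed the rest (initializing every state
    # at the global covariance lets EM collapse all means to the grand mean)
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_states, random_state=seed, n_init=10).fit(X)
    labels = km.labels_
    d = X.shape[1]
    h.startprob_ = np.bincount(labels, minlength=n_states) / len(labels)
    trans = np.ones((n_states, n_states))  # +1 smoothing
    offset = 0
    for L in lengths:
        seg = labels[offset : offset + L]
        np.add.at(trans, (seg[:-1], seg[1:]), 1)
        offset += L
    h.transmat_ = trans / trans.sum(axis=1, keepdims=True)
    h.means_ = km.cluster_centers_
    covs = []
    for k in range(n_states):
        pts = X[labels == k]
        c = np.cov(pts.T, ddof=1) if len(pts) > d else np.eye(d)
        covs.append(np.atleast_2d(c) + 1e-6 * np.eye(d))
    covs = np.stack(covs)
    h.covars_ = covs if cov_type == "full" else np.stack([np.diag(c) for c in covs])
    h.fit(X, lengths)
    covars = np.asarray(h.covars_)  # hmmlearn exposes (K, d, d) for all types
    if cov_type == "diag":
        covars = np.stack([np.diag(c) for c in covars])
        covars = np.maximum(covars, 1e-6)
    else:
        # symmetrize and floor eigenvalues so degenerate states (e.g. a
        # near-constant feature) stay positive-definite
        covars = (covars + covars.transpose(0, 2, 1)) / 2.0
        floored = []
        for c in covars:
            w, V = np.linalg.eigh(c)
            floored.append((V * np.maximum(w, 1e-6)) @ V.T)
        covars = np.stack(floored)
    return GHMMModel(
        n_states=n_states,
        startprob=h.startprob_.copy(),
        transmat=h.transmat_.copy(),
        means=h.means_.copy(),
        covars=covars,
        covariance_type=cov_type,
        loglik_trace=list(h.monitor_.history),
        seed=seed,
    )


def loglikelihood(model: GHMMModel, sequences: list[np.ndarray]) -> float:
    h = model.to_hmmlearn()
    return float(sum(h.score(np.asarray(s, dtype=float)) for s in sequences))


def decode(sequence: np.ndarray, model: GHMMModel, recording_id: str = "", frame_index: np.ndarray | None = None) -> StateSequence:
    """Exact Viterbi path for one contiguous (T, d) sequence."""
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim != 2 or sequence.shape[1] != model.means.shape[1]:
        raise ValueError(f"sequence must be (T, {model.means.shape[1]})")
    h = model.to_hmmlearn()
    states = h.predict(sequence)
    if frame_index is None:
        frame_index = np.arange(len(sequence))
    return StateSequence(recording_id=recording_id, frame_index=np.asarray(frame_index), states=states)


def path_log_probability(model: GHMMModel, sequence: np.ndarray, states: np.ndarray) -> float:
    """Joint log p(states, sequence) under the model (for Viterbi optimality
    checks)."""
    from scipy.stats import multivariate_normal

    sequence = np.asarray(sequence, dtype=float)
    states = np.asarray(states, dtype=int)
    logp = np.log(model.startprob[states[0]] + 1e-300)
    logp += np.sum(np.log(model.transmat[states[:-1], states[1:]] + 1e-300))
    for k in np.unique(states):
        idx = states == k
        cov = model.covars[k] if model.covariance_type == "full" else np.diag(model.covars[k])
        logp += multivariate_normal.logpdf(sequence[idx], model.means[k], cov).sum()
    return float(logp)


# ---------------------------------------------------------------------------
# usage and transitions
# ---------------------------------------------------------------------------


def state_usage(
    decoded_by_condition: dict[str, list[StateSequence]],
    n_states: int,
    control_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-condition share of frames per state (%, rows sum to 100) and,
    if a control map is given, percentage fold change vs control."""
    shares = {}
    for cond, seqs in decoded_by_condition.items():
        counts = np.zeros(n_states)
        for s in seqs:
            counts += np.bincount(s.states, minlength=n_states)
        shares[cond] = 100.0 * counts / counts.sum()
    usage = pd.DataFrame(shares, index=[f"state_{i}" for i in range(n_states)]).T
    fold = None
    if control_map:
        rows = {}
        for cond, ctrl in control_map.items():
            with np.errstate(divide="ignore", invalid="ignore"):
                rows[cond] = 100.0 * (shares[cond] - shares[ctrl]) / shares[ctrl]
        fold = pd.DataFrame(rows, index=usage.columns).T
    return usage, fold


def empirical_transitions(decoded: list[StateSequence], n_states: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic transition matrix from decoded sequences pooled within a
    condition. Counts never cross recording boundaries or frame-index gaps.
    Returns (matrix, uniform_row_flags); rows with zero counts are set
    uniform and flagged."""
    counts = np.zeros((n_states, n_states))
    for seq in decoded:
        s = seq.states
        if len(s) < 2:
            continue
        contiguous = np.diff(seq.frame_index) == 1
        np.add.at(counts, (s[:-1][contiguous], s[1:][contiguous]), 1)
    row_sums = counts.sum(axis=1)
    uniform = row_sums == 0
    matrix = np.where(uniform[:, None], 1.0 / n_states, counts / np.where(row_sums == 0, 1, row_sums)[:, None])
    return matrix, uniform


def export_transition_graph(
    matrix: np.ndarray,
    show_threshold: float = 0.001,
    label_threshold: float = 0.01,
    state_names: list[str] | None = None,
) -> pd.DataFrame:
    """Edge list for transition-graph rendering: edges with probability >
    ``show_threshold`` are kept; those above ``label_threshold`` get printed
    probability labels."""
    matrix = np.asarray(matrix, dtype=float)
    K = matrix.shape[0]
    if state_names is None:
        state_names = [STATE_LETTERS[i] if i < len(STATE_LETTERS) else str(i) for i in range(K)]
    rows = []
    for i in range(K):
        for j in range(K):
            p = matrix[i, j]
            if p > show_threshold:
                rows.append(
                    {
                        "from": state_names[i],
                        "to": state_names[j],
                        "probability": p,
                        "labeled": p > label_threshold,
                    }
                )
    return pd.DataFrame(rows, columns=["from", "to", "probability", "labeled"])


# ---------------------------------------------------------------------------
# model selection and stability
# ---------------------------------------------------------------------------


def selection_report(
    sequences: list[np.ndarray],
    n_states_grid: tuple[int, ...] = (6, 8, 10, 12, 15),
    covariance_types: tuple[str, ...] = ("full", "diagonal"),
    seed: int = 0,
    rare_share: float = 1.0,
) -> pd.DataFrame:
    """Fit each candidate model and report log-likelihood, per-state frame
    shares, and the count of states used by fewer than ``rare_share`` percent
    of frames (the over-segmentation diagnostic)."""
    rows = []
    for cov in covariance_types:
        for K in n_states_grid:
            model = fit_ghmm(sequences, n_states=K, covariance_type=cov, seed=seed)
            decoded = [decode(s, model).states for s in sequences]
            counts = np.zeros(K)
            for d in decoded:
                counts += np.bincount(d, minlength=K)
            shares = 100.0 * counts / counts.sum()
            rows.append(
                {
                    "n_states": K,
                    "covariance_type": cov,
                    "loglik": model.loglik_trace[-1],
                    "n_rare_states": int(np.sum(shares < rare_share)),
                    "state_shares": shares.tolist(),
                }
            )
    return pd.DataFrame(rows)


def align_states(reference: GHMMModel, other: GHMMModel) -> np.ndarray:
    """Optimal state matching between two fits: Hungarian assignment on the
    Euclidean distances between state means. Returns perm with
    other-state perm[i] matched to reference state i."""
    d = np.linalg.norm(reference.means[:, None, :] - other.means[None, :, :], axis=-1)
    _, col = linear_sum_assignment(d)
    return col


def stability_protocol(
    sequences: list[np.ndarray],
    condition_labels: list[str],
    n_states: int = 10,
    covariance_type: str = "full",
    seeds: tuple[int, int, int] = (0, 1, 2),
) -> pd.DataFrame:
    """Replicate-fit protocol: (a) full data under 3 seeds, (b) 3 mutually
    exclusive random splits, (c) 3 mutually exclusive condition-balanced
    splits. Reports, per replicate, the correlation of state means with the
    full-data seed-0 reference after Hungarian alignment."""
    if len(sequences) < 6:
        raise ValueError("dataset too small to split into 3 exclusive subsets")
    condition_labels = list(condition_labels)
    reference = fit_ghmm(sequences, n_states, covariance_type, seed=seeds[0])

    def _mean_corr(model: GHMMModel) -> float:
        perm = align_states(reference, model)
        a = reference.means.ravel()
        b = model.means[perm].ravel()
        return float(np.corrcoef(a, b)[0, 1])

    rows = []
    for s in seeds:
        model = fit_ghmm(sequences, n_states, covariance_type, seed=s)
        rows.append({"protocol": "full_data", "replicate": s, "mean_correlation": _mean_corr(model)})

    rng = np.random.default_rng(seeds[0])
    order = rng.permutation(len(sequences))
    for r, part in enumerate(np.array_split(order, 3)):
        model = fit_ghmm([sequences[i] for i in part], n_states, covariance_type, seed=seeds[0])
        rows.append({"protocol": "random_split", "replicate": r, "mean_correlation": _mean_corr(model)})

    # condition-balanced: deal recordings round-robin, continuing the deal
    # across conditions so all three parts stay populated
    parts: list[list[int]] = [[], [], []]
    deal = 0
    for cond in sorted(set(condition_labels)):
        idx = [i for i, c in enumerate(condition_labels) if c == cond]
        rng.shuffle(idx)
        for i in idx:
            parts[deal % 3].append(i)
            deal += 1
    for r, part in enumerate(parts):
        model = fit_ghmm([sequences[i] for i in part], n_states, covariance_type, seed=seeds[0])
        rows.append({"protocol": "balanced_split", "replicate": r, "mean_correlation": _mean_corr(model)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: GHMMModel, path: str | Path) -> None:
    payload = {
        "n_states": model.n_states,
        "startprob": model.startprob.tolist(),
        "transmat": model.transmat.tolist(),
        "means": model.means.tolist(),
        "covars": model.covars.tolist(),
        "covariance_type": model.covariance_type,
        "loglik_trace": model.loglik_trace,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> GHMMModel:
    payload = json.loads(Path(path).read_text())
    return GHMMModel(
        n_states=payload["n_states"],
        startprob=np.asarray(payload["startprob"]),
        transmat=np.asarray(payload["transmat"]),
        means=np.asarray(payload["means"]),
        covars=np.asarray(payload["covars"]),
        covariance_type=payload["covariance_type"],
        loglik_trace=payload["loglik_trace"],
        seed=payload["seed"],
    )
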