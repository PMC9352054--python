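"""Surrogate larval-swim generator with full ground truth.

The generator emulates the gross structure of tracked ascidian-larva
recordings so that every pipeline stage can be exercised against known truth:

* a rigid head and undulating tail: the curvature field is a traveling wave
  over six fixed smooth orthonormal basis shapes that vanish on the head
  region, so the eigenposture stage has an exact generating basis;
* a contour-width profile with a head bulb, a sharp neck constriction at a
  configurable index, and a tapering tail, so neck detection has a planted
  answer;
* intermittent locomotion — dwell, beat, glide, clockwise/counter-clockwise
  turns and startle bouts — driven by a first-order Markov chain over
  regimes, so state segmentation has a generating path;
* asymmetric tail bending for the turning regimes, additive Gaussian
  observation noise, and random frame dropouts (``valid=False``).

Propulsion is kinematic (speed proportional to beat amplitude, exponential
decay while gliding), not hydrodynamic; it is sufficient for speed features
and speed-weighted sampling, not a physical swimming model.

Skeletons are reconstructed from the curvature field by integrating the
tangent angle along arc length at fixed point spacing, so consecutive-point
spacing is constant by construction and the feature stage's curvature
estimates recover the planted field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_model import N_POINTS, Dataset, StimulusProtocol, TrackRecording

REGIMES = ("dwell", "beat", "glide", "turn_cw", "turn_ccw", "startle")

BODY_LENGTH_PX = 115.0  # matches the calibration larva (115.10 px)
DS = BODY_LENGTH_PX / (N_POINTS - 1)  # arc-length spacing, px


@dataclass(frozen=True)
class RegimeParams:
    """Kinematic parameters of one locomotor regime."""

    amplitudes: tuple[float, ...]  # curvature-mode amplitudes a1..a6, 1/px
    freq_hz: float  # fundamental tail-beat frequency
    asym: float = 0.0  # constant tail-curvature offset (turn bias), 1/px
    gain: float = 0.0  # propulsion: px/frame of centroid speed at full beat
    glide: bool = False  # speed decays instead of following the gain


def default_regimes(curvature_scale: float = 0.03) -> dict[str, RegimeParams]:
    """Regime set qualitatively in wild-type feature ranges: curvature up to
    a few times 0.01 1/px for a ~115 px larva, beats at 3-8 Hz (< Nyquist)."""
    A = curvature_scale
    return {
        "dwell": RegimeParams(amplitudes=(0, 0, 0, 0, 0, 0), freq_hz=0.0, gain=0.0),
        "beat": RegimeParams(
            amplitudes=(1.0 * A, 0.6 * A, 0.4 * A, 0.25 * A, 0.15 * A, 0.1 * A), freq_hz=5.0, gain=3.0
        ),
        "glide": RegimeParams(
            amplitudes=(0.15 * A, 0.1 * A, 0.05 * A, 0.03 * A, 0.02 * A, 0.01 * A),
            freq_hz=2.0,
            gain=0.0,
            glide=True,
        ),
        "turn_cw": RegimeParams(
            amplitudes=(0.8 * A, 0.5 * A, 0.3 * A, 0.2 * A, 0.1 * A, 0.08 * A),
            freq_hz=5.0,
            asym=0.35 * A,
            gain=2.0,
        ),
        "turn_ccw": RegimeParams(
            amplitudes=(0.8 * A, 0.5 * A, 0.3 * A, 0.2 * A, 0.1 * A, 0.08 * A),
            freq_hz=5.0,
            asym=-0.35 * A,
            gain=2.0,
        ),
        "startle": RegimeParams(
            amplitudes=(2.5 * A, 1.8 * A, 1.2 * A, 0.8 * A, 0.5 * A, 0.3 * A), freq_hz=8.0, gain=6.0
        ),
    }


def default_transition_matrix(regimes: tuple[str, ...] = REGIMES) -> np.ndarray:
    """Sticky Markov chain: long dwells and bouts, brief startles."""
    n = len(regimes)
    self_p = {r: 0.97 for r in regimes}
    self_p["startle"] = 0.85
    self_p["glide"] = 0.95
    P = np.zeros((n, n))
    for i, r in enumerate(regimes):
        P[i, i] = self_p.get(r, 0.97)
        off = (1.0 - P[i, i]) / (n - 1)
        for j in range(n):
            if j != i:
                P[i, j] = off
    return P


@dataclass
class SwimSimConfig:
    fps: float = 30.0
    duration_s: float = 60.0
    seed: int = 0
    regimes: dict[str, RegimeParams] = field(default_factory=default_regimes)
    regime_order: tuple[str, ...] = REGIMES
    transition_matrix: np.ndarray | None = None  # defaults to the sticky chain
    noise_sd: float = 0.05  # observation noise, fraction of the max mode amplitude
    neck_index: int = 12  # planted width-constriction index
    dropout_rate: float = 0.0
    glide_tau_s: float = 0.5  # speed decay time constant while gliding
    turn_rate: float = 60.0  # heading change per unit asym curvature, rad/(1/px)/frame
    condition: str = "wild_type"

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.regime_order)
        P = np.asarray(self.transition_matrix, dtype=float)
        if not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        nyquist = self.fps / 2.0
        for name, rp in self.regimes.items():
            if rp.freq_hz >= nyquist:
                raise ValueError(f"regime {name!r} beats at {rp.freq_hz} Hz >= Nyquist {nyquist} Hz")


@dataclass
class GroundTruth:
    """Frame-aligned generating state of a simulated recording."""

    regimes: np.ndarray  # (T,) regime name per frame
    kappa: np.ndarray  # (T, 49) generating curvature field, 1/px
    heading: np.ndarray  # (T,) head tangent angle, rad
    speed: np.ndarray  # (T,) centroid speed, px/frame
    basis: np.ndarray  # (6, 49) generating orthonormal curvature modes
    kappa_observed: np.ndarray | None = None  # field incl. observation noise
    planted_motifs: list[dict] = field(default_factory=list)
    planted_events: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# basis, widths, skeleton reconstruction
# ---------------------------------------------------------------------------


def curvature_mode_basis(neck_index: int = 12, n_modes: int = 6) -> np.ndarray:
    """Six orthonormal smooth curvature shapes over the 49-point grid.

    Legendre polynomials of degree 1..6 over the tail coordinate, tapered to
    zero over the head region (rigid head), then QR-orthonormalized. Rows are
    unit-norm and mutually orthogonal; the first entries (head points) are
    ~zero.
    """
    s = np.linspace(-1.0, 1.0, N_POINTS)
    taper_end = neck_index + 2
    taper = np.ones(N_POINTS)
    taper[: taper_end + 1] = 0.5 * (1 - np.cos(np.pi * np.arange(taper_end + 1) / taper_end)) ** 2
    taper[: max(neck_index - 2, 0)] = 0.0
    cols = []
    for deg in range(1, n_modes + 1):
        leg = np.polynomial.legendre.Legendre.basis(deg)(s)
        cols.append(leg * taper)
    M = np.stack(cols, axis=1)  # (49, 6)
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))[None, :]
    return Q.T  # (6, 49)


def width_template(neck_index: int = 12) -> np.ndarray:
    """Head bulb, sharp neck constriction, tapering tail (pixels)."""
    w = np.empty(N_POINTS)
    w[: neck_index - 1] = 10.0
    # sharp drop across the 3-point neck segment
    w[neck_index - 1] = 8.0
    w[neck_index] = 4.5
    w[neck_index + 1] = 3.5
    tail = np.linspace(3.5, 1.0, N_POINTS - neck_index - 1)
    w[neck_index + 1 :] = tail
    return w


def skeleton_from_curvature(kappa: np.ndarray, heading: float, head_pos: np.ndarray) -> np.ndarray:
    """Integrate the tangent angle along arc length at spacing DS.

    kappa is (49,) in 1/px; returns (49, 2) points with the head tip at
    ``head_pos`` and initial tangent ``heading``.
    """
    theta = heading + np.concatenate([[0.0], np.cumsum(0.5 * (kappa[1:] + kappa[:-1]) * DS)])
    steps = DS * np.stack([np.cos(theta[:-1] + 0.5 * np.diff(theta)), np.sin(theta[:-1] + 0.5 * np.diff(theta))], axis=1)
    pts = np.empty((N_POINTS, 2))
    pts[0] = head_pos
    pts[1:] = head_pos + np.cumsum(steps, axis=0)
    return pts


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_recording(config: SwimSimConfig, animal_id: str = "sim0") -> tuple[TrackRecording, GroundTruth]:
    """One simulated animal; bit-identical for a fixed config and seed."""
    rng = np.random.default_rng(config.seed)
    T = int(round(config.duration_s * config.fps))
    names = config.regime_order
    P = np.asarray(config.transition_matrix, dtype=float)
    basis = curvature_mode_basis(config.neck_index)
    widths = width_template(config.neck_index)
    max_amp = max(max(rp.amplitudes) for rp in config.regimes.values())
    # amplitudes are peak curvatures, so noise_sd is a fraction of the
    # largest mode's peak curvature
    noise_scale = config.noise_sd * max_amp

    # regime path
    state = int(rng.integers(len(names)))
    states = np.empty(T, dtype=int)
    for t in range(T):
        states[t] = state
        state = int(rng.choice(len(names), p=P[state]))

    # per-mode frequency multipliers give the curvature field full rank over
    # a bout (pure sinusoids at one frequency would only span 2 dimensions)
    freq_mult = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
    phases = rng.uniform(0, 2 * np.pi, size=6)

    kappa = np.zeros((T, N_POINTS))
    heading = np.zeros(T)
    speed = np.zeros(T)
    head_pos = np.zeros((T, 2))
    pos = np.array([500.0, 500.0])
    hdg = rng.uniform(0, 2 * np.pi)
    v = 0.0
    glide_decay = np.exp(-1.0 / (config.glide_tau_s * config.fps))
    tail_mask = np.zeros(N_POINTS)
    tail_mask[config.neck_index + 2 :] = 1.0

    for t in range(T):
        name = names[states[t]]
        rp = config.regimes[name]
        if t > 0 and states[t] != states[t - 1]:
            phases = rng.uniform(0, 2 * np.pi, size=6)  # fresh bout phase
        tt = t / config.fps
        coeff = np.array(
            [rp.amplitudes[i] * np.sin(2 * np.pi * rp.freq_hz * freq_mult[i] * tt + phases[i]) for i in range(6)]
        )
        # amplitudes are in curvature units at the basis peak
        k = (coeff / np.abs(basis).max(axis=1)) @ basis + rp.asym * tail_mask
        kappa[t] = k
        envelope = np.abs(coeff[0]) / rp.amplitudes[0] if rp.amplitudes[0] > 0 else 0.0
        if rp.glide:
            v *= glide_decay
        else:
            v = rp.gain * envelope
        hdg += config.turn_rate * rp.asym / config.fps
        pos = pos + v * np.array([np.cos(hdg), np.sin(hdg)])
        heading[t] = hdg
        speed[t] = v
        head_pos[t] = pos

    kappa_noisy = kappa + rng.normal(0.0, noise_scale, size=kappa.shape)
    points = np.stack(
        [skeleton_from_curvature(kappa_noisy[t], heading[t], head_pos[t]) for t in range(T)]
    )
    valid = rng.random(T) >= config.dropout_rate
    points[~valid] = np.nan
    rec = TrackRecording(
        points=points,
        widths=np.tile(widths, (T, 1)),
        valid=valid,
        frame_index=np.arange(T),
        fps=config.fps,
        condition=config.condition,
        animal_id=animal_id,
    )
    gt = GroundTruth(
        regimes=np.array([names[s] for s in states]),
        kappa=kappa,
        heading=heading,
        speed=speed,
        basis=basis,
        kappa_observed=kappa_noisy,
    )
    return rec, gt


def simulate_dataset(
    n_per_condition: dict[str, int],
    duration_s: float = 60.0,
    seed: int = 0,
    control_map: dict[str, str] | None = None,
    config_overrides: dict[str, dict] | None = None,
) -> tuple[Dataset, dict[str, GroundTruth]]:
    """A multi-condition dataset of independent simulated animals.

    ``config_overrides`` maps condition -> SwimSimConfig field overrides
    (e.g. a drug condition with a different transition matrix).
    """
    ds = Dataset()
    truths: dict[str, GroundTruth] = {}
    counter = 0
    for cond, n in n_per_condition.items():
        overrides = (config_overrides or {}).get(cond, {})
        for i in range(n):
            cfg = SwimSimConfig(duration_s=duration_s, seed=seed + counter, condition=cond, **overrides)
            rec, gt = simulate_recording(cfg, animal_id=f"{cond}_{i}")
            ds.add(rec)
            truths[rec.animal_id] = gt
            counter += 1
    if control_map:
        ds.control_map.update(control_map)
    return ds, truths


# ---------------------------------------------------------------------------
# planting: exact motif repeats and stimulus responses
# ---------------------------------------------------------------------------


def plant_motif(
    rec: TrackRecording,
    gt: GroundTruth,
    template: np.ndarray,
    starts: list[int],
    neck_index: int = 12,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TrackRecording, GroundTruth]:
    """Overwrite windows of the recording with exact repeats of a 7-channel
    segment-curvature template.

    The (7, m) template holds curvatures at the 7 segment midpoints; it is
    interpolated to the full 49-point field (zero over the rigid head),
    written into the generating curvature at each start, and the skeletons
    rebuilt. Optional Gaussian noise (sd as a fraction of the template's peak
    amplitude) is added per plant. Overlapping starts are an error.
    """
    from scipy.interpolate import PchipInterpolator

    from .features import partition_segments

    template = np.asarray(template, dtype=float)
    C, m = template.shape
    if C != 7:
        raise ValueError("template must have 7 channels")
    starts = sorted(int(s) for s in starts)
    for a, b in zip(starts, starts[1:]):
        if b - a < m:
            raise ValueError(f"plant starts {a} and {b} overlap (window {m})")
    if starts and (starts[0] < 0 or starts[-1] + m > len(rec)):
        raise ValueError("plant window outside recording")

    part = partition_segments(neck_index)
    mids = np.array(part.midpoints)
    rng = np.random.default_rng(seed)
    peak = np.abs(template).max()
    kappa = gt.kappa.copy()
    kappa_obs = gt.kappa_observed.copy() if gt.kappa_observed is not None else kappa.copy()
    points = rec.points.copy()
    for s in starts:
        block = template + (rng.normal(0.0, noise_sd * peak, size=template.shape) if noise_sd > 0 else 0.0)
        for t in range(m):
            x = np.concatenate([[0], mids, [N_POINTS - 1]])
            y = np.concatenate([[0.0], block[:, t], [block[-1, t]]])
            interp = PchipInterpolator(x, y)
            k = interp(np.arange(N_POINTS))
            k[: max(neck_index - 2, 0)] = 0.0
            kappa[s + t] = k
            kappa_obs[s + t] = k
            points[s + t] = skeleton_from_curvature(k, gt.heading[s + t], rec.points[s + t, 0])
        gt.planted_motifs.append({"start": s, "length": m})
    new_rec = TrackRecording(
        points=points,
        widths=rec.widths.copy(),
        valid=rec.valid.copy(),
        frame_index=rec.frame_index.copy(),
        fps=rec.fps,
        um_per_pixel=rec.um_per_pixel,
        condition=rec.condition,
        animal_id=rec.animal_id,
        stimulus=rec.stimulus,
    )
    new_gt = replace(gt, kappa=kappa, kappa_observed=kappa_obs)
    return new_rec, new_gt


def plant_stimulus_response(
    rec: TrackRecording,
    gt: GroundTruth,
    protocol: StimulusProtocol,
    speed_factor: float = 1.0,
    amplitude_factor: float = 1.0,
) -> tuple[TrackRecording, GroundTruth]:
    """Shift kinematics during the stimulus window: centroid displacements
    are scaled by ``speed_factor`` and the tail-curvature field by
    ``amplitude_factor`` between light ON and OFF. Ground-truth alignment is
    preserved; the recording is tagged with the protocol."""
    T = len(rec)
    on = int(round(protocol.onset_s * rec.fps))
    off = int(round(protocol.offset_s * rec.fps))
    if off > T:
        raise ValueError("stimulus window does not fit the recording")
    window = np.zeros(T, dtype=bool)
    window[on:off] = True

    # rescale displacements inside the window, keep the path elsewhere
    head = rec.points[:, 0].copy()
    disp = np.diff(head, axis=0)
    disp[window[1:]] *= speed_factor
    new_head = np.vstack([head[:1], head[:1] + np.cumsum(disp, axis=0)])

    kappa = gt.kappa.copy()
    kappa[window] *= amplitude_factor
    kappa_obs = gt.kappa_observed.copy() if gt.kappa_observed is not None else kappa.copy()
    kappa_obs[window] *= amplitude_factor
    points = np.stack(
        [skeleton_from_curvature(kappa_obs[t], gt.heading[t], new_head[t]) for t in range(T)]
    )
    points[~rec.valid] = np.nan
    speed = gt.speed.copy()
    speed[window] *= speed_factor
    gt_new = replace(gt, kappa=kappa, kappa_observed=kappa_obs, speed=speed)
    gt_new.planted_events.append(
        {"onset_frame": on, "offset_frame": off, "speed_factor": speed_factor, "amplitude_factor": amplitude_factor}
    )
    rec_new = TrackRecording(
        points=points,
        widths=rec.widths.copy(),
        valid=rec.valid.copy(),
        frame_index=rec.frame_index.copy(),
        fps=rec.fps,
        um_per_pixel=rec.um_per_pixel,
        condition=rec.condition,
        animal_id=rec.animal_id,
        stimulus=protocol,
    )
    return rec_new, gt_new
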