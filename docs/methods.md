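# Methods

This note documents the models, conventions and numerical choices behind
`cionaswim`, and what the synthetic-data tests do and do not establish about
real tracker data.

## Data model and units

A recording is a fixed-rate (30 fps) time series of 49-point midline
skeletons with contour widths, in pixels, image convention (origin top-left,
y down). Frames where upstream segmentation failed are kept in place with
`valid=False` so every stage sees the true acquisition clock; each stage has
an explicit gap policy (speeds are masked on both sides of a gap, HMM and
wavelet stages split recordings into contiguous valid segments, motif windows
containing invalid frames are discarded). Unit conversion is explicit:
`calibrate_scale(length_px, length_um)` returns µm/px (11.56 for the
reference larva of 115.10 px = 1,330.61 µm), and speeds convert as
px/frame × µm/px × fps.

## Posture features

**Neck detection.** The neck is the skeleton index in [4, 22] where the
contour width drops most sharply: the argmin of the first difference of the
5-point moving-average-smoothed width profile, ties broken anteriorly. The
smoothing width and tie rule are our choices; a degenerate profile with no
decrease raises an error rather than guessing.

**Segments.** Head = points 0..neck−2; Neck = the 3 points centered on the
neck; the remaining tail points split into 5 contiguous blocks of
as-equal-as-possible size, remainder assigned posteriorly; segment midpoints
take the lower-middle index on even sizes. These conventions are fixed and
arbitrary where the anatomy does not dictate them.

**Curvature.** κ_i = (x′y″ − y′x″)/(x′²+y′²)^{3/2} with derivatives over
point index from a Savitzky–Golay filter, window 15, order 2. Sign: positive
is a leftward bend relative to head→tail traversal in image coordinates.
Window 15 at 49 points means shapes with spatial periods below roughly a
third of the body are attenuated — see "Limitations".

**Quirkiness.** q = √(1 − (b/a)²) where a ≥ b are the skeleton's extents
along its two principal axes. This eccentricity form is the only one
consistent with q = 1 for a straight body and q ≈ 0 for a square bounding
box; using principal axes (not image axes) makes it rotation invariant. q is
numerically sensitive near 0 (equal extents), which only occurs for
unrealistically curled shapes.

**Speeds.** Per-point displacement between adjacent frames, averaged over
each segment's points (the midpoint-only variant would be noisier; the mean
is our documented choice).

## Eigenposture decomposition

The 49×49 sample covariance (denominator n−1) of per-frame curvature is
eigendecomposed; eigenpairs are sorted by descending eigenvalue, each
eigenvector's largest-magnitude entry is made positive (reproducibility),
and variance fractions are eigenvalues over the full trace. Projections
subtract the training mean by default (`center=False` available for
sensitivity checks, since deposited coefficients could have been computed
either way). On the training sample the mean squared reconstruction residual
equals the discarded eigenvalue mass — asserted as a test invariant.

## Motif mining

Input: the 7-channel segment-curvature series, smoothed by a centered
10-frame rolling mean (truncated at edges). The all-dimensions
multidimensional matrix profile assigns to each window start the mean over
channels of the z-normalized Euclidean distance to the best jointly matching
other window, with a trivial-match exclusion zone of ⌈m/2⌉. It is computed
exactly (vectorized all-pairs Gram products per channel, O(T²m) work) and is
verified against an independent brute-force oracle to 1e-6; windows with
standard deviation below 1e-8 z-normalize to zero vectors, so two constant
windows are at distance 0. Memory is O(n²) per series, which bounds practical
series length at a few thousand frames per call — recordings are mined
individually.

Motif onsets are local profile minima below the threshold 8, accepted
greedily in ascending profile order with an exclusion zone of m frames. The
10-frame pre-smoothing plus self-similar context (long dwells) spreads each
dip over about ±m/2 frames, so a planted repeat counts as recovered when an
extracted window overlaps it (start within m frames); under that criterion
recovery exceeds 90 % at noise up to 20 % of template amplitude. Because the
dip-detection and overlap rules are our documented choices, absolute motif
counts on any given dataset are not expected to reproduce another
implementation's counts exactly.

Motif clustering is k-means (fixed seed, 10 restarts) on the flattened,
un-normalized 7×m matrices — amplitude is behaviorally meaningful, so no
per-motif normalization. Cluster count selection uses the maximum discrete
second difference of the inertia-vs-k curve (ties to the smallest k).

## Behavioral states (Gaussian HMM)

States are fitted on [EC1..EC6, quirkiness] per frame, raw scales (state
means/variances stay interpretable; optional z-scoring flag). Recordings are
split at invalid frames into contiguous segments; transitions never cross
segment or recording boundaries.

EM (Baum–Welch, hmmlearn) runs to log-likelihood gain < 1e-3 or 200
iterations. Initialization is k-means on the pooled frames with the given
seed: means from cluster centers, covariances per cluster (diagonal floor
1e-6), transition matrix from label bigrams with +1 smoothing. We initialize
explicitly because seeding every state with the global covariance lets the
first M-step collapse all means to the grand mean when states are well
separated. Fitted covariances are symmetrized and eigenvalue-floored at 1e-6
so degenerate states (e.g. near-constant quirkiness while dwelling) remain
positive-definite.

State labels are arbitrary; all cross-model comparisons first align states
by Hungarian assignment on state-mean distances. Model selection reports
log-likelihood and the count of states used by < 1 % of frames (the
over-segmentation diagnostic); the stability protocol refits on the full
data under 3 seeds and on 3 mutually exclusive random and
condition-balanced splits, reporting aligned state-mean correlations.
Empirical per-condition transition matrices row-normalize counts; rows with
no observations are set uniform and flagged. Transition-graph export filters
edges at probability 0.001 and labels them above 0.01.

## Behavioral space

Wavelet features: continuous complex Morlet transform (ω₀ = 5, modulus) of
each EC channel at 30 frequencies uniformly spaced in 1–30 Hz, reflective
padding, per-scale 1/√scale amplitude normalization — 180 dimensions per
frame. Frames are sampled for embedding with probability ∝ 0.5·sN +
0.1·(sTB+sTprM+sTM+sTpoM+sTT) (weights sum to 1), without replacement when
possible, uniform fallback when all weights vanish.

The composite space takes [e1.x, e1.y, e2.x, e3.y] from three planar t-SNE
embeddings (cosine metric, PCA init) with (perplexity, exaggeration) =
(500, 12), (250, 3), (750, 2); the e2.y and e3.x coordinates are computed and
discarded. Our t-SNE backend applies each stated exaggeration as the early
phase followed by an unexaggerated final phase. The reference perplexities
assume a 200,000-frame sample; smaller samples scale them proportionally with
a floor of 30 (values below ~10 shatter coherent clusters into
micro-clusters) and a cap of (n−1)/3.

Density clustering is DBSCAN on the 4-D composite coordinates; eps and
min_samples are configuration, with `sweep_eps` reporting cluster counts and
outlier fractions over a grid so the user can target a desired region count
(six, for the wild-type repertoire). The kNN assigner (200 neighbors,
distance-weighted) votes in the 180-dim wavelet feature space, which is well
defined for unseen frames without re-embedding; training frames reproduce
their own labels exactly. Occupancy maps are 2-D histograms of the e1 plane,
Gaussian-smoothed, clipped at 0.8 % of the smoothed maximum by default (a
configurable saturation, implemented as printed in the source protocol).

## Statistics

SMD = (median₁ − median₂)/s_pool with s_pool = √((s₁²+s₂²)/2) and
s = 1.4826·MAD per group — a robust scale consistent with the median
numerator on heavy-tailed features; `robust=False` switches to sample SDs.
If both scales vanish the SMD is 0 for equal medians and NaN (undefined
scale) otherwise.

Shapiro–Wilk (α 0.05) justifies the nonparametric battery; samples above
4,999 observations are deterministically subsampled. Segment-wise paired
comparisons use Wilcoxon signed-rank (two-sided and both one-sided p values;
all-zero differences are flagged degenerate). Treatment-vs-control feature
comparisons use Mann–Whitney U at Bonferroni-corrected α = 0.05/25 = 0.002
with effect size U/(n₁n₂). Usage comparisons (per-video percentage of frames
in a state/cluster) use Mann–Whitney U at α 0.05. Exactness at small n is
verified against full enumeration of the null in the tests, and the
usage-comparison type-I error is checked against 0.05 over 1,000 null
replicates.

Light-stimulus analysis: a 60 s stimulus window starting at 30 s; responses
are per-feature SMDs (after − before) between a 10 s pre-event window and a
2.5 s post-event window starting 0.5 s after the event, computed separately
at ON and OFF. The 0.5 s skip applies to both events (the design is
symmetric). At 30 fps and onset 30 s the ON windows are frames [600, 900)
and [915, 990).

## Synthetic-data generator

The generator is the ground-truth engine for every stage. Curvature is a
traveling wave over six orthonormal modes: Legendre polynomials of degree
1..6 over arc length, tapered to zero over the head region (rigid head) and
QR-orthonormalized on the 49-point grid. Per regime, mode i oscillates at
the regime frequency times a per-mode multiplier (1, 1, 2, 2, 3, 3) with
bout-resampled phases — pure single-frequency driving would span only two
dimensions, not six. Turning regimes add a constant tail-curvature offset
(asymmetric bending); this offset lies outside the six-mode span, so strict
six-mode subspace recovery is assessed on turn-free configurations.
Amplitudes are calibrated so that the stated values are peak curvatures
(1/px); observation noise is Gaussian per point with sd expressed as a
fraction of the largest mode's peak amplitude (default 5 %).

Skeletons are rebuilt by integrating the tangent angle along arc length at
fixed 2.396 px spacing (115 px body, matching the calibration larva), so
point spacing is constant by construction. Regimes follow a sticky Markov
chain (defaults: self-transition 0.97; startle 0.85). Propulsion is
kinematic — centroid speed proportional to beat amplitude, exponential decay
(τ = 0.5 s) while gliding — sufficient for speed features and speed-weighted
sampling, not a hydrodynamic model. Frame dropouts are Bernoulli.
Default regime parameters (curvature scale 0.03 1/px, beats at 2–8 Hz)
put feature distributions in qualitatively realistic wild-type ranges;
no quantitative claim is attached to them.

`plant_motif` writes exact repeats of a 7-channel segment-curvature template
(PCHIP-interpolated to 49 points, zero over the head) into the generating
field and rebuilds the skeletons; `plant_stimulus_response` rescales centroid
displacements and/or tail curvature inside the stimulus window. Both
preserve frame alignment with the ground truth.

**What the simulator does not emulate:** hydrodynamics and body–fluid
interaction, tracker segmentation artifacts other than uniform dropouts
(e.g. head–tail flips, partial occlusions), arena-boundary interactions,
inter-animal variability in size and width profile, and drug-specific
kinematic signatures. Passing tests therefore establish correctness of the
algorithms under the stated generative model, not biological conclusions
about real larvae.

## Problem sizes and runtimes

Test and acceptance computations use scaled-down twins of the full-data
analyses, sized to run on a single CPU in minutes: the eigenposture variance
twin uses 50,000 simulated frames (10 recordings × 5,000); HMM parameter
recovery uses 10⁵ frames from a known 4-state model; matrix-profile oracle
checks run at T ≤ 500; the behavioral-space twin embeds 1,800 frames from 6
planted oscillatory regimes with perplexities scaled as described above; the
type-I-error check uses 1,000 null replicates of 25 videos per arm. These
sizes are package choices recorded here for reproducibility.

## Known limitations

* Savitzky–Golay re-extraction of curvature from reconstructed skeletons
  attenuates the highest-order shape modes: the leading three generating
  modes are recovered to within 10° of principal angle, the fifth and sixth
  only approximately. The retained variance statement (≥ 97 % in six modes)
  is unaffected.
* The matrix-profile implementation is exact but O(T²) in memory per
  recording; deposit-scale corpora would need a streaming (STOMP-style)
  profile.
* Absolute motif counts, HMM state identities and embedding geometry are
  implementation- and seed-dependent; the package's contracts are the
  recovery, stability and exactness properties asserted in the test suite.
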