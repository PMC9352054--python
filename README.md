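# cionaswim

Quantitative analysis of *Ciona intestinalis* larval swimming from tracked
midline skeletons.

Ascidian larvae are a minimal chordate model for the neural control of
locomotion: a ~1.3 mm tadpole with a rigid trunk and an undulating tail,
swimming intermittently in bouts. Given Tierpsy-style tracker output — per
video frame, 49 equally spaced midline points and 49 contour widths in pixels
at 30 fps — this package reconstructs the behavioral repertoire end to end:

1. **Posture featurization** (`features`): automatic neck detection from the
   contour-width constriction, partition into 7 body segments (Head, Neck,
   TailBase, TailPreMid, TailMid, TailPostMid, TailTip), signed curvature
   κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2} via Savitzky–Golay derivatives
   (window 15, order 2), relative tangent angles, segment speeds, and
   quirkiness q = √(1 − (b/a)²) of the principal-axis bounding box.
2. **Eigenposture decomposition** (`eigenposture`): PCA of the 49-point
   curvature covariance. Six "eigencionas" explain ≥ 97 % of postural
   variance; per-frame projections EC1..EC6 are the posture coordinates.
3. **Motif mining** (`motifs`): multidimensional matrix profile of the
   7-channel segment-curvature series (windows of 1 s / 5 s, i.e. 30 / 150
   frames), motif onsets at profile dips below 8, k-means clustering of the
   extracted motifs into 15 groups, per-condition usage and fold change.
4. **Behavioral states** (`hmm_states`): a 10-state full-covariance Gaussian
   HMM over [EC1..EC6, quirkiness], Baum–Welch fitting, Viterbi decoding,
   per-condition state usage and empirical transition matrices, model
   selection and stability protocols.
5. **Behavioral space** (`behavior_map`): 180-dim Morlet wavelet features
   (6 EC channels × 30 frequencies in 1–30 Hz), speed-weighted frame
   sampling, a composite 4-D t-SNE embedding, DBSCAN density clusters, and a
   200-NN distance-weighted assigner.
6. **Statistics** (`stats_stimulus`): standardized median difference (SMD)
   barcodes, Shapiro–Wilk, Wilcoxon signed-rank, Mann–Whitney U with
   Bonferroni correction (α = 0.05/25 = 0.002 for the 25-feature panel),
   U/(n₁n₂) effect sizes, and light-stimulus event-window analysis
   (10 s before vs 2.5 s after each ON/OFF event, skipping 0.5 s).
7. **Ground-truth simulator** (`synthetic_data`): a traveling-wave curvature
   model over six orthonormal shape modes with a Markov regime process
   (dwell / beat / glide / CW–CCW turn / startle), planted motifs and planted
   stimulus responses, so every stage is testable without data downloads.

A config-driven orchestrator (`pipeline`, console script `cionaswim`) chains
the stages and writes CSV/JSON tables with a provenance record.

## Worked example

```python
import numpy as np
from cionaswim import (SwimSimConfig, simulate_recording, curvature,
                       fit_eigenbasis, detect_neck, quirkiness,
                       calibrate_scale, features, motifs)

cfg = SwimSimConfig(duration_s=60.0, seed=0)
rec, truth = simulate_recording(cfg)
print(f"frames: {len(rec)}, valid: {rec.valid_fraction:.2f}")
print(f"um/px: {calibrate_scale(115.10, 1330.61):.4f}")

neck = detect_neck(rec.widths[0])
kappa = curvature(rec.points)
basis = fit_eigenbasis(kappa, k=6)
print(f"neck index: {neck}")
print("variance fractions:", np.round(basis.variance_fraction, 3))
print(f"top-6 variance: {100 * basis.total_variance_fraction:.1f}%")

part = features.partition_segments(neck)
seg = features.segment_curvature(kappa, part).T
profile = motifs.matrix_profile_md(motifs.smooth_channels(seg), m=30)
starts = motifs.extract_motifs(profile, m=30, threshold=8.0)
print(f"motif onsets found: {len(starts)}")
print(f"median quirkiness: {np.median(quirkiness(rec.points[rec.valid])):.3f}")
```

Output:

```
frames: 1800, valid: 1.00
um/px: 11.5605
neck index: 12
variance fractions: [0.696 0.228 0.053 0.015 0.004 0.002]
top-6 variance: 99.9%
motif onsets found: 42
median quirkiness: 0.997
```

The calibration converts the tracker's pixel units (a 115.10 px larva is
1,330.61 µm long, so 11.56 µm/px). The neck is found at the planted
constriction (index 12). The fitted eigenbasis concentrates virtually all
curvature variance in six modes, as expected for data generated from a
six-mode traveling wave; on the 1-second timescale the matrix profile finds
42 recurring motif onsets; and a median quirkiness near 1 reflects the mostly
straight body of an intermittently swimming larva.

To run the full pipeline on a simulated dataset from the shell:

```sh
cionaswim simulate --out simdata --seed 0 --n 4 --duration 60
printf 'manifest: simdata/manifest.csv\n' > run.yaml
cionaswim run --config run.yaml --out results_run --seed 1
```

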