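# Methods

This note documents the models, conventions and numerical choices behind
`gaitkit`, and what the synthetic-data generator does and does not emulate.

## Calibration

Each camera films the tunnel wall through a lens that introduces
perspective/lens distortion. We model the image-to-wall map as a single
planar homography `H` (3×3, 8 degrees of freedom) estimated from exactly
four point correspondences whose targets are given in millimetres on the
rectified wall plane. Because the targets are metric, calibration and
pixel→mm conversion are one step; no separate scale factor exists.

Four points in general position determine `H` exactly, so we solve the
homogeneous 8×9 direct-linear-transform system by taking the right
singular vector of its smallest singular value — an exact solve, not a
least-squares fit. We do not pre-normalize the points (Hartley
conditioning): with four well-spread calibration marks the system is well
conditioned, and the acceptance suite verifies recovery of random
projective maps to < 1e-8 reprojection error. Degeneracy is declared when
any three source or target points are collinear, tested as a triangle
area below 1e-9 of the bounding-box area. Points whose homogeneous `w`
falls below 1e-12 of the coordinate scale raise an error rather than
silently mapping to infinity.

## Step kinematics

A step is delimited by manually annotated start/end instants, so duration
is the *frame span* over fps (`(last − first)/fps`), not the frame count.
Stride length is the net horizontal displacement of the metatarsus marker,
`|x_last − x_first|`, not the path length; speed is their ratio. These
conventions make `speed · duration = stride_length` an identity.

Left/right step pairs are classified by a fixed decision order:

1. both stride lengths below `(1 − length_tol) ×` a baseline length → **B**
   (both strides shortened);
2. otherwise, lengths within `length_tol` and durations within `time_tol`
   of each other (relative to the larger of the pair) → **A**;
3. otherwise **C** if the left stride is longer, **D** if the right is.
   If the lengths are *exactly* equal (possible only on constructed data),
   the tie breaks on duration so that relabelling the limbs always swaps
   C and D.

The baseline for rule 1 is the median control-group stride length,
computed per run; the reference for "shorter steps" is not specified by
the protocol, and a within-cohort control norm is the least arbitrary
choice. Both tolerances default to 0.15 and are config-exposed, since the
protocol gives only qualitative class definitions. Pairing matches each
left step to the unmatched right step with maximal frame-range overlap;
unpaired steps are kept for speed analysis but not classified.

## Displacement curves and the distance statistic D

Each marker's `x(t)` and `y(t)` over one step are resampled to 100
percent-of-cycle points with a cubic interpolating spline on normalized
time `u ∈ [0, 1]`. End conditions are not-a-knot (the scipy default), so
all polynomials up to degree 3 are reproduced exactly at the cycle
points; a natural spline would bias curve ends whenever the marker has
nonzero end acceleration. The first and last output samples are pinned to
the raw endpoint values to make the endpoint contract exact in floating
point. At 61 raw frames the resampling error for a full sine cycle is
~3e-7 mm (fourth-order convergence), far below annotation noise.

Two normalized curves of the same marker and side are compared with

    D = (1/200) · [ Σᵢ (x₁ᵢ − x₂ᵢ)² + Σᵢ (y₁ᵢ − y₂ᵢ)² ]   (mm²),

the mean of all 200 squared pointwise differences. The published form is
typographically ambiguous about whether the 1/200 scopes both axis sums;
we take the mean over both (the natural "mean squared error" reading) and
keep the alternative (1/200 on the x sum only) behind a config flag for
sensitivity checks. D is symmetric, non-negative, zero iff the curves
coincide at every sample, and invariant to translating both curves by a
common vector.

Before comparison each step is re-zeroed: the metatarsus x position on
the step's first frame is subtracted from every marker's x. Without this,
D mostly measures *where in the tunnel* a step happened rather than its
shape. The raw-coordinate comparison remains available (`rezero: false`).

For each subject mouse, every step curve is compared against every step
curve of every control mouse; the minimum and maximum distances found are
the subject's `D_min` and `D_max`. Control mice are summarized within
their own group with same-mouse comparisons excluded. Ties for the
extremes break toward the lexicographically smallest
`((mouse, step), (mouse, step))` pair, making summaries deterministic.
Left and right hindlimbs are kept separate throughout, and the analysis
runs both over all steps and restricted to Type-A pairs.

## Open field

The arena is a 45 × 32 cm rectangle partitioned into a 4 × 4 grid of
11.25 × 8 cm quadrants; the 12 wall-adjacent quadrants form the periphery
and the inner 2 × 2 block the center. Quadrant cells are half-open, so a
point exactly on the center-block boundary counts as periphery
(deterministic, wall-adjacent bias). Time accounting is by frame counts
(`duration = n_frames / fps`), which makes
`periphery_time + center_time = duration` exact.

Total distance is the sum of Euclidean inter-frame displacements.
Stillness — which the protocol excludes from the speed denominator
without stating a criterion — defaults to instantaneous speed below
0.5 cm/s sustained for at least 0.5 s; both knobs are config-exposed.
Frame speeds are backward differences (frame *i* carries the displacement
from frame *i−1*; frame 0 copies frame 1), so a track that freezes at its
midpoint yields a moving time of exactly half the duration. A
consequence of frame-count time accounting is a fencepost factor: a
constant-velocity track sampled at *n* frames holds *n−1* path segments,
so the recovered speed is `v·(n−1)/n` (0.006% at 10 min × 30 fps). Still
time is excluded from the speed denominator only; the negligible distance
accrued during still frames stays in the total.

## Group statistics

Rank-based tests (Kruskal–Wallis omnibus, Wilcoxon rank-sum/signed-rank
pairwise) are wired to behavioral measures; kinematic measures (per-step
speeds, D summaries) use multiple Welch t-tests with Bonferroni
correction `p_adj = min(1, m·p)` over each comparison family (all
pairwise group contrasts of one analysis). Welch is the default because
group variances are not assumed equal; the pooled form is a config
switch. Rank tests use exact enumeration below 25 combined observations
(without ties) and the tie-corrected large-sample approximation above.
When every observation is identical the Kruskal–Wallis tie correction
degenerates; by convention H = 0 and p = 1. Per-step speeds are pooled
within group as the unit of analysis (matching how speed distributions
are plotted); per-mouse means are available as a robustness option since
steps within a mouse are not independent.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, not a biomechanical simulation. What it emulates:

- **Group speed distributions.** Per-step target speeds are Gaussian with
  the study's printed all-steps means (control 27.72, cortex-injured
  24.38, hippocampus-injured 20.66, EV-treated 30.53 mm/s) and SD 7 mm/s.
  Step durations are quantized to the 240 fps frame grid first and the
  stride set to `speed × quantized duration`, so a noise-free trace
  yields the sampled speed exactly — the recovery tests then measure only
  estimator and sampling error.
- **Stance/swing shape.** Metatarsus x follows a slow linear progression
  (10% of the stride) during stance (duty factor 0.6) and a cubic
  smoothstep advance during swing, with a 5 mm half-sine vertical lift.
  Knee and ankle are offset copies (−4, +8) and (−8, +18) mm with 0.6×
  and 0.3× lift. These template values are not from the protocol; they
  are plausible mouse hindlimb geometry and are config-pluggable.
- **Step-type mixture.** Types emerge from the kinematics: a per-pair
  "short step" event scales both strides by 0.6 (probability 0.05 /
  0.45 / 0.35 / 0.10 per group, chosen to reproduce the reported
  qualitative pattern — control and EV-treated mostly Type A,
  cortex-injured dominated by B, hippocampus-injured mixed), and per-limb
  log-normal jitter (SD 0.05–0.12) produces C/D asymmetries. Nothing is
  labelled post hoc.
- **Curve-shape variability.** Smooth perturbations (first three sine
  harmonics, vanishing at the step boundaries so endpoint kinematics are
  untouched) with base SD 0.8 mm, scaled per group; the
  hippocampus-injured preset uses 0.6× to mirror the reported *reduced*
  within-group variability after hippocampal damage.
- **Open field.** A correlated random walk (heading turn SD 0.25
  rad/frame) with specular wall reflection. A wall-attraction parameter
  in [−1, 1] biases the heading toward a ring 4 cm inside the walls
  (positive; thigmotaxis) or toward the center block (negative), with
  strength proportional to the distance error so the walker cruises along
  the preferred region instead of pressing into the boundary. At 0 the
  long-run periphery occupancy approaches the 0.75 area fraction; the
  group presets (+0.05, +0.04, −0.05, +0.03) were calibrated once so the
  expected periphery times match the printed group values (≈528, 513,
  320, 493 s of 600). Still bouts are scheduled with known onsets and
  freeze the position exactly, totalling the per-group still time implied
  by the printed distance and moving-speed values.
- **Reproducibility.** Every mouse draws from its own stream
  (`SeedSequence([master_seed, crc32(mouse_id)])`), so adding mice never
  perturbs existing ones, and identical configs give byte-identical files.

What it does **not** emulate: video, pose-estimation or annotation error
structure (noise is i.i.d. Gaussian, 0.1 mm); inter-step correlations
beyond shared pair-level draws; fatigue or learning trends across steps;
grooming/rearing in the open field. Passing recovery tests therefore
demonstrates that the *analysis* is correct and well-powered under the
assumed structure, not that the assumed structure captures real mice.

## Problem sizes

Replicated studies in the test suite and acceptance script use 5 mice per
group × 6 steps per hindlimb (the study's own scale), 200 replicates for
speed-recovery/power/size and 100 seed-matched pairs for the
variance-monotonicity check; these sizes give Monte-Carlo standard errors
comfortably below the margins being asserted.

## Known limitations

- Step segmentation is taken as given (manual annotation); no automatic
  stride detection.
- D compares curves point-by-point at matched percent-cycle; no dynamic
  time warping, so residual phase differences inside the cycle contribute
  to D by design.
- The homography treats each camera plane independently; no 3D
  reconstruction or radial-distortion model.
- Bonferroni is the only correction offered, matching the source
  protocol; with many markers/sides/filters it is conservative.
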