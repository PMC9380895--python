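# Methods

This note documents the models, conventions and numerical choices behind
`gaitfive`, and what the synthetic cohorts do and do not establish.

## Input model and preprocessing

A subject is a sequence of BODY_25 skeleton frames: 25 keypoints with
pixel coordinates and optional detection confidences. Analysis assumes a
front-view walker and a fixed 75-frame window, so that every subject
contributes the same temporal support to the features.

*Window selection.* Sequences longer than 75 frames are cropped to the
contiguous 75-frame window with the highest mean keypoint confidence
(earliest window on ties); shorter sequences are rejected rather than
resampled, because resampling would change the temporal frequencies the
wavelet features measure. When several people are detected in a frame,
the one with the highest summed confidence is kept — the intended use is
one walker per video.

*Missing detections.* A keypoint sample is invalid when its confidence is
below a threshold (default 0.1) or when it is the pose-estimator null
output (0, 0) with zero confidence. Interior gaps are filled by linear
interpolation over frame index per coordinate; runs at either end copy
the nearest valid value. A keypoint with no valid frame at all is an
error, not a guess.

*Coordinate translation.* Every frame is re-expressed relative to MidHip:
x′ᵢ = xᵢ − x₈, y′ᵢ = yᵢ − y₈. This removes global position and body
placement in the image and makes all downstream features invariant to
camera translation. MidHip itself becomes the origin and is removed,
leaving 24 keypoints (48 coordinate series).

*Smoothing.* Each of the 48 series is convolved with [1, 4, 6, 4, 1]/16
(a binomial approximation to a narrow Gaussian). The boundary policy is
symmetric (reflect) extension: it preserves constants, keeps the output
length at 75, and does not fabricate trends at the ends. Smoothing is
applied after translation; since the kernel is linear and
translation is a per-frame shift, the order only matters for the boundary
treatment of the MidHip series itself, which is discarded anyway.

*Odd/even split.* Frame numbering is 1-based. The odd half is frames
1, 3, …, 73 and the even half 2, 4, …, 74 — 37 frames each from the first
74; frame 75 belongs to neither half. The halves are the instrument for
split-half reliability: two interleaved sub-videos of the same walk.

## Feature construction

The feature data pool holds 132 named time series: 48 coordinates, their
48 forward interframe differences (Δf_j = f_{j+1} − f_j), 26 axis-wise
joint distances over 13 joint pairs, and 10 joint angles.

*Distances* are absolute axis-wise separations |x′_a − x′_b|,
|y′_a − y′_b|: the quantities they encode (hand swing, stride width, head
sway) are magnitudes. A signed variant is available
(`joint_distance_series(..., signed=True)`) for analyses that care about
crossing, e.g. hands passing each other.

*Angles* are measured at the middle joint between the two rays, via the
arccos of the normalized dot product, in degrees in [0, 180]. The cosine
is clipped to [−1, 1] to absorb rounding; a zero-length ray (coincident
joints) yields angle 0 with a logged warning rather than NaN.

*Wavelets.* Each coordinate series is decomposed with a 5-level haar
transform (symmetric signal extension) into detail bands D1…D5 and the
approximation A5. The additive identity X = D1 + … + D5 + A5 holds at
machine precision when each coefficient array is inverted with the others
zeroed; the test suite verifies this on random series of lengths 37 and
75. Five levels require length ≥ 32, which both the full window and the
halves satisfy. Coefficient-array lengths differ between 75- and 37-frame
inputs, but only summary statistics of the arrays enter the feature
vector, so the vector's dimension and names are stream-invariant — the
property the odd/even reliability design needs.

*Summaries.* Ten time-domain functions are applied to each of the 132
series: maximum, minimum, mean, median, variance, root mean square,
skewness, kurtosis, absolute energy (Σx²), and variation coefficient
(σ/μ). Four frequency-domain statistics are applied to each of the
48 × 6 wavelet coefficient arrays: absolute maximum, mean, variance,
absolute energy. Totals: 132 × 10 = 1320 time-domain and
48 × 6 × 4 = 1152 frequency-domain features, 2472 overall, asserted on
every extraction.

Conventions chosen where more than one is defensible, applied uniformly
and tested: population (biased) variance and population moment estimators
for skewness; kurtosis is excess (Fisher), so a Gaussian series scores 0;
skewness and kurtosis of a constant series are defined as 0; the
variation coefficient of a zero-mean series is defined as 0 (logged).

## Modeling

With 2472 features and cohort-scale n, regularization by construction is
essential. Each trait model is a stack fitted end-to-end on training
subjects only:

1. **Standardize** per feature (zero-variance features get unit scale, so
   they standardize to zeros and are inert).
2. **PCA** to min(n − 1, p) components — the full decorrelated space; no
   variance cutoff is imposed, selection is left to the next stage.
3. **Sequential forward selection** of k = 40 components: at each stage
   every remaining component is scored by the mean 5-fold inner-CV
   negative RMSE of the chosen algorithm refit on the candidate subset,
   and the best one is added (ties break to the lowest index, making the
   path deterministic given the seed).
4. **Regressor**: one of GPR (RBF + white-noise kernel, 3 optimizer
   restarts, target normalization), LR, RFR (100 trees), or SVR with
   linear/poly/rbf/sigmoid kernels, refit on the 40 selected components.

For LR, the SFS scoring is computed in closed form: per inner fold the
centred Gram matrix is cached and each candidate's OLS fit is obtained by
orthogonalizing the candidate column against the selected block, which is
algebraically exact OLS and vectorizes over candidates. The test suite
confirms path-identity with brute-force greedy enumeration using
scikit-learn fits on instances small enough to enumerate.

*Evaluation protocol.* 10 repetitions of 10-fold cross-validation. Within
each training fold the entire stack is refit from scratch; the held-out
subjects' all-frames, odd and even feature vectors then pass through that
one fitted stack. This is deliberately stricter than fitting the stack
once globally (which would leak held-out subjects into the standardizer,
the PCA basis and the selection); the global variant remains available
(`refit_stack_per_fold=False`, `--global-stack`) for comparison. Each
subject receives one out-of-fold prediction per stream per repetition;
the reported prediction is the mean over repetitions. Targets are raw
subscale sums, so RMSE is in score points.

## Psychometric evaluation

* **Criterion validity r₁**: Pearson correlation between aggregated
  all-frames predictions and scale scores, per trait, with t-distribution
  (n − 2 df) p-values. A per-repetition r₁ distribution is also available.
* **Split-half reliability r₂**: correlation between aggregated odd-half
  and even-half predictions.
* **MTMM matrix**: the 10 × 10 Pearson matrix over (model, scale) × five
  traits. Convergent validity = the five mono-trait hetero-method
  entries; discriminant structure = the ten hetero-trait entries within
  each method block. No trait is sign-reflected; negative correlations
  (e.g. neuroticism with the rest) are reported as-is.
* **Convergent-vs-discriminant test**: each convergent entry is compared
  with the hetero-trait hetero-method entries in its row and column (on
  magnitudes). Significance comes from a permutation test that shuffles
  the subject correspondence between the two method blocks and
  recomputes the mean paired difference; this is the package's choice of
  test for "convergent exceeds discriminant", as no canonical test
  exists for that contrast. Off-diagonal entries with p ≥ 0.001 are
  flagged in the summary.

## Keypoint mapping

Selection operates on principal components, but interpretation wants
keypoints. Each of the 40 selected components spreads one unit of mass
over the 2472 raw features in proportion to its absolute PCA loadings
(squared loadings are available as an alternative rule); feature mass
then flows to keypoints by the construction rules — coordinate,
difference and wavelet features charge their keypoint fully, distance
features charge each endpoint ½, angle features charge each joint ⅓.
Total mass is conserved (= number of selected components, to 1e−9) and
MidHip can never be charged. Models are compared by the intersection of
their top-⌈24/2⌉ = 12 keypoints (ties rank the lower index first).

## Synthetic cohorts

The generator exists so the full pipeline can be exercised against known
ground truth. Per subject, a latent Big Five vector is drawn from a
correlated standard Gaussian (default: +0.3 among extraversion,
agreeableness, conscientiousness, openness; −0.4 of each with
neuroticism — the canonical inter-scale pattern, so MTMM discriminant
structure is non-trivial). Subscale sums are center + slope·latent +
Gaussian noise (default SD 2 points), rounded and clipped to the legal
ranges (E 8–40, A 9–45, C 9–45, N 8–40, O 10–50); slopes (4.5–5.5 points
per latent SD) put ±3 SD comfortably inside each range.

Five kinematic parameters are linear in the latents with a diagonal
default effect matrix: extraversion → arm-swing amplitude (8 px/SD on a
25 px base), agreeableness → torso sway (3 on 6), conscientiousness →
stride (10 on 40), neuroticism → gait period (+4 frames/SD on 25,
i.e. slower cadence), openness → head bob (2.5 on 5). Amplitudes clip at
0 and the period at [12, 40] frames. The walker is a fixed standing pose
(~400 px tall) with sinusoidal limb oscillation: left/right antiphase,
arms counter-phased to their same-side leg, elbows/knees at half
amplitude, foot points riding their ankle, upper body swaying laterally,
head points bobbing at twice the stride frequency. Gaussian pixel noise
(default SD 1 px) models pose-estimator jitter. Scale is irrelevant after
MidHip translation; pixel units are cosmetic.

What this emulates: periodic, individually parameterized, trait-coupled
limb kinematics observed through a noisy keypoint channel, with
questionnaire scores that are imperfect readouts of the same latent
traits. What it does not emulate: ground-contact biomechanics, turning
and off-axis view, occlusion-structured (non-Gaussian, temporally
correlated) pose errors, within-subject gait variability across walks,
and any nonlinear trait-kinematics coupling. Passing the recovery tests
therefore demonstrates that the pipeline is statistically sound and
leak-free end-to-end — not that real gait video carries this much trait
signal; with real data the attainable r₁ is an empirical question.

Default problem sizes were chosen to make the recovery experiments sharp
but cheap: cohorts of 150 subjects for recovery runs (strong effects and
a zero-effect null control), 10×10 cross-validation with per-fold stack
refits, and scores-only cohorts of ~500 for correlation-structure checks.

## Known limitations

* Sequential selection is greedy; it makes no optimality claim beyond
  stage-wise optimality, and with heavily correlated components the
  chosen subset is one of many near-equivalent ones.
* GPR and RFR inside SFS use generic refits and are markedly slower than
  the closed-form LR path; for large component counts LR is the
  practical inner estimator.
* The keypoint mapping's |loading| propagation is a modeling choice; the
  mapping is conserved mass, not causal attribution.
* Front/back-view classification and gait-cycle segmentation are out of
  scope: callers supply front-view windows of sufficient length.
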