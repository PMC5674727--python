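# Methods

This note records the model, the parameter choices that matter, the design
decisions taken where the method description left the design open, and what
the synthetic phantoms do and do not establish about real data.

## Detection model

The detector searches for saddle-shaped intensity structure — two darker and
two brighter sectors alternating around a point — in band-pass filtered
images. Vessels in fundus photographs are smooth dark valleys on a brighter
background; their crossings, bends, branch points and disc transitions
produce saddle profiles in the absolute DoG, while straight uniform ridges do
not (their along-ridge arcs are a single pixel wide at ring radius 3, which
the 2–8 arc-length rule excludes by design — the rule is what separates
saddles from simple edges).

Pipeline per octave of the 4-octave DoG pyramid:

1. **DoG**: `G(kσ₀)∗I − G(σ₀)∗I` with σ₀ = 1.0 and k = 1.6 (a good discrete
   approximation of the Laplacian of Gaussian). Gaussian kernels are truncated
   at radius ⌈4σ⌉ and renormalized; convolution uses reflect padding so the
   frame boundary does not manufacture spurious band-pass edges on top of the
   illumination artifact the detector must already tolerate.
2. **Absolute normalization**: |DoG| min–max scaled to [0, 1] per octave.
   This makes the labeling offset ε comparable across images and octaves; a
   constant octave normalizes to all zeros. ε operates on this normalized
   surface, not on raw intensities.
3. **Candidate lattice**: all pixels at least 3 from the border (0-based
   `[3, dim−4]`), i.e. exactly those whose radius-3 ring fits. Octaves
   narrower than 7 px yield no candidates and are logged, not raised.
4. **Inner test**: of the 8-neighborhood, axial pair {top, bottom} vs
   {left, right} ("+") and the two diagonal pairs ("×"); a shape passes when
   the minimum of one pair strictly exceeds the maximum of the orthogonal
   pair, in either polarity. β is the median of the passing shape's 4 pixels,
   of all 8 when both shapes pass.
5. **Outer test**: the 16-pixel radius-3 digital (Bresenham) circle, ordered
   clockwise from 12 o'clock, labeled d/s/l against β ± ε with the boundaries
   inclusive into s. Validity: every neutral s-run ≤ 2; after deleting
   s-runs the d/l arcs strictly alternate cyclically; every arc 2–8 long; at
   least two arcs per polarity (a saddle has two dark and two bright
   sectors; fewer arcs would accept edges).
6. **Response**: mean d-deficit plus mean l-excess about β. The method's
   source leaves the response unspecified; this form is monotone in local
   contrast, which is the only property non-maxima suppression uses.
7. **NMS** (octave 0 only; higher octaves are already coarse): survive iff
   the response is ≥ every passing 3×3 neighbor's, ties kept by smallest
   (y, x) for determinism.
8. **Subpixel refinement**: least-squares quadratic on the 3×3 |DoG| patch;
   the stationary-point offset is clamped to ±0.5 px. A singular Hessian
   (ridge-shaped surface) falls back to independent 1D parabola vertices per
   axis; a fully flat patch keeps the integer position.
9. **Lifting**: octave coordinates × 2^octave. Evaluation at a different
   native resolution rescales further by (native/working); that factor lives
   in the evaluation stage (`LandmarkSet.scaled`), not the detector.

Defaults: σ₀ = 1.0, k = 1.6, 4 octaves, ε = 0.0010, working resolution 583.
Downsampling is bilinear to ⌈dim/2⌉ (ceil keeps the last row/column of
odd-sized images; 583 is odd). Each octave blurs its own downsampled image
afresh — no inter-octave σ compounding.

Color input is reduced to the green channel, which carries the highest
vessel contrast in fundus photography.

## Descriptor and matching

HOG on the grayscale working image (not the DoG): 32×32 window centered on
the rounded point, 8×8 cells, 2×2-cell blocks at one-cell stride, 9 unsigned
orientation bins, L2 block normalization → 324 values. The window size is
chosen so the descriptor covers roughly ±2 vessel widths at working
resolution; orientation bins are the standard unsigned HOG default. Border
windows are reflect-padded and logged. Matching is one-directional exact
nearest neighbor (Euclidean) with the ratio test at 0.9, boundary inclusive;
approximate search would be an optimization, not a semantic change, at the
few thousand descriptors a fundus image yields. Match symmetry is
deliberately not enforced.

## Robust estimation

MSAC hypotheses are similarity transforms from 2-point minimal samples (the
cheapest geometric hypothesis; the final model is refit afterwards), scored
by Σ min(r², d²) at truncation distance d. An adaptive early exit at 99%
confidence caps the trial count (default ceiling 8000) without affecting
determinism for a fixed seed. The winning hypothesis' inliers (r ≤ d) select
the final model by count — ≤ 8 similarity, 9–30 affine, > 30 second-order
polynomial; the boundary counts 8 and 30 go to the simpler model. The round
(MSAC + fit) repeats `repeats_per_distance` times for each d ∈ {1, 20, 60,
80} px with child seeds derived deterministically from one top-level seed.
With landmarks the best round is the one with smallest TRE (the evaluation
protocol); without ground truth — the only option in real use — the round
with most inliers, ties broken by smallest mean inlier residual, is kept,
and this deviation is intentional and documented.

Warping is inverse-mapped bilinear resampling; the second-order polynomial
has no closed-form inverse, so the inverse map is itself fit as a
second-order polynomial on a 24×24 grid of forward-mapped samples (exact for
the near-affine warps that arise here up to the quadratic term's own
self-composition, which is negligible at the ≤ 2 px quadratic amplitudes the
phantoms use). Out-of-domain pixels are zero-filled and masked.

## Evaluation

TRE is the mean Euclidean landmark distance after mapping moving landmarks
through the estimated transform. (The method's printed error formula
contains a sign/root typo; the implementation follows the prose definition —
an average distance in pixels.) Success thresholds are strict: < 1 px for
super-resolution, < 5 px for mosaicking and longitudinal study. UN, the
peak-deviation nonuniformity, is implemented as (max+min)/(max−min) over the
ROI — larger for more uniform images, matching the metric's reported
direction and magnitude range; the original reference formula is not
reproduced in the source, so this is an interpretation and is flagged as
such. A perfectly uniform ROI returns a documented sentinel (1e6) with a
warning. The ROI defaults to an Otsu-thresholded, hole-filled FOV mask;
explicit masks are accepted.

## Phantom generator

What it emulates: circular FOV on a dark frame; a branching vessel tree
grown by correlated random walks from the optic disc rim (widths 2–12 px
biased wide for trunks, contrasts 0.05–0.5, children thinner and fainter);
Gaussian-valley vessel cross-sections (σ = width/2), which reproduce the
saddle structure the detector targets; a bright optic disc; band-limited
choroidal/pigmentation mottle (std 0.02, 4 px correlation length) — real
fundus background is textured, not flat; multiplicative radial illumination
falloff plus a random lateral gradient; dark-spot occlusions; and sensor
noise referred to native resolution (std 0.02) passed through the
anti-aliased 5:1 downsample the 2912→583 working-resolution chain implies,
which attenuates it ~7× and correlates it over ~0.4 px.

Pairs are cut from one extended scene so anatomy exists beyond the fixed
FOV; the moving frame samples the scene through the true moving→fixed map
(translation solved from the two-circle intersection area to hit a requested
FOV overlap; rotation/scale per category; affine adds a small shear;
polynomial pairs add a quadratic bend of ≤ 2 px at the FOV edge). The two
frames are degraded independently (fresh illumination phase, fresh spots,
fresh noise). Category S: overlap 86–100%, rotation ≤ 5°; P: 17–89%, ≤ 7°;
A: 95–100%, ≤ 4° plus anatomy perturbation of the moving frame (smooth
tortuosity jitter on half the vessels, 1–3 small dark lesions). Landmarks
are 10 spread-out vessel-centerline points visible in both FOVs, with the
moving coordinates obtained by exact inversion (Newton iteration for the
polynomial), consistent with the truth to < 1e-6 px. All randomness in a
pair flows from one seed through named substreams.

What it does **not** emulate: photorealistic color/texture statistics,
pathology beyond generic blobs and jitter, motion blur or defocus, lens
distortion, vessel central reflex, and the fine-grain spatial statistics of
real sensor/compression noise. Consequently, passing phantom batteries shows
that the pipeline recovers known geometry under fundus-like degradations; it
does not certify performance on clinical images. One measurable gap is
known: the inner-ring test rejects ≈ 62% of candidates on these phantoms
versus ≈ 80% reported on real retinal data — the phantom's vessel-free
background keeps a noise-dominated DoG where the strict inequality passes
about half the time, whereas real fundus background is structure-dominated
at pixel scale.

## Problem sizes and numerical choices

Unit tests run on 96–192 px phantoms; the parameter-recovery and
overlap batteries use 256 px phantoms with MSAC at 50 repeats per distance
and a 500-trial ceiling, sizes at which the geometry estimates are already
stable (battery medians 0.07–0.28 px). The acceptance script uses the full
583 px working resolution with ten phantoms. Degenerate inputs are
contracts, not crashes: constant images detect nothing with a warning,
too-small images build fewer octaves, failed registration returns a status
with a reason, degenerate least-squares geometry raises a `ValueError`
naming the degeneracy, and MSAC with fewer than two matches reports failure.

## Known limitations

- The detector is not rotation-invariant beyond 90° multiples (ring order is
  covariant only under lattice symmetries); the descriptor is unoriented, so
  large rotations between frames degrade matching — acceptable for fundus
  pairs, whose rotations stay below ~7°.
- Model selection by raw inlier count can pick the polynomial model on pairs
  a similarity would explain; with many inliers this is harmless (the fit is
  over-determined) but it costs interpretability of the recovered pose.
- The best-round rule without landmarks (max inliers, then min residual) is
  a heuristic; with landmarks the evaluation-mode rule (min TRE) is an
  oracle and should not be quoted as blind performance.
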