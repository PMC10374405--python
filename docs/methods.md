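# Methods

## Scope and data model

The package reproduces an automated myocardium-segmentation pipeline for
cardiac T1/T2 parametric maps on synthetic data. The in-memory objects
mirror the clinical workflow: a `MapImage` (one 2D map or weighted image
with pixel spacing, slice position and kind), a `ContourPointSet` (ordered
real-valued (x, y) pixel coordinates, counter-clockwise, the native
annotation format), a 3-class `SegmentationMask` (0 background, 1 LV
cavity, 2 myocardium), and a `PhantomCase` (three slices with all derived
images and truth contours).

## Signal models and map fitting

T1-weighted images follow the inversion-recovery model
`S(t) = A − B·exp(−t/T1)` sampled at 8 inversion times; the signal is kept
signed — no magnitude operation or polarity restoration is applied, so the
fit is a plain 3-parameter least-squares problem. T2-weighted images follow
`S(TE) = S0·exp(−TE/T2)` at TE = 0/25/55 ms.

The T1 fitter is a vectorized damped Gauss–Newton over all pixels at once,
initialized by log-linearizing `(A0 − S)/B0` with `A0 = S(t_last)`,
`B0 = A0 − S(t_first)`; a trust region caps each T1 step at 50 % and the
Levenberg damping grows tenfold on any cost increase. Pixels are flagged
failed (NaN) when the signal has no spread, the normal equations are
singular, T1 leaves (0.01, 1e5) ms, or the relative residual exceeds 0.5.
The T2 fitter is the closed-form log-linear regression, exact for
noiseless data and adequate at the noise levels simulated; pixels with
non-positive signal or non-decaying slope are flagged. Noiseless round
trips recover the generating maps to machine precision (tested at ≤0.1 %).

## Phantom generator

Each synthetic subject has three short-axis slices. Geometry is drawn per
case: basal epicardial radius uniform in 13–17 px, wall thickness 3.5–5.5
px, axis ratio 0.85–1.0, random rotation and center jitter (±4 px on a
64×64 grid at 1.5×1.5 mm pixels). Midventricular and apical slices are
scaled copies (0.75–0.9 and 0.5–0.7 of basal), so apical myocardium is the
smallest — the property that makes apical slices measurably harder for the
segmenter, as in real cohorts. With probability 0.05 an apical cavity gets
a wedge-shaped cut (gap angle 0.6–1.2 rad), emulating the thin-wall cases
whose predicted cavities come out C-shaped.

Tissue parameters default to mapping-scale magnitudes: myocardium T1/T2 =
1000/50 ms, blood 1600/250 ms, background 300/30 ms, with amplitudes
800/1000/150; validation requires ≥10 % separation between classes so the
segmentation task is well posed. Truth contours are dense analytic
samplings (180 points) of the ellipses (or ellipse-with-wedge); the truth
mask is *rasterized from those contours*, so contour/mask consistency holds
by construction and is re-checked in tests. Gaussian noise (default σ =
2 % of the maximum amplitude) is added to the weighted stacks after
synthesis, and the parametric maps are fitted from the noisy stacks —
exactly the path scanner software takes. The eight inversion times default
to a MOLLI-like spread (100…3500 ms); protocol counts (8 inversions,
3 echoes at 0/25/55 ms) are fixed by validation, the values configurable.

What the phantoms do **not** emulate: motion and off-resonance artifacts,
partial-volume mixtures, Rician noise statistics (the additive-Gaussian
hook is isolated in one place if that matters), papillary muscles, the
right ventricle, and anatomical texture inside each tissue class. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
self-consistent at clinical geometry scales — not that the network
generalizes to real CMR contrast.

## Rasterization convention

One convention is used everywhere: 0-based (x = column, y = row)
coordinates, pixel centers at integers, point-in-polygon by pixel center
(even-odd rule), centers exactly on an edge counting as inside. A pixel is
cavity if its center is inside the endocardial polygon, else myocardium if
inside the epicardial polygon, else background. The endocardial region must
rasterize strictly inside the epicardial region (zero-tolerance check) and
an all-myocardium-free pair is rejected as degenerate.

## Network and training

The segmenter is an encoder–decoder with skip connections implemented
directly on NumPy with hand-written backward passes (im2col convolutions,
batch norm, max-pooling, bilinear and transposed-convolution upsampling,
residual blocks, Adam). The flagship preset pairs a 50-convolution
residual encoder (bottleneck stages 3/4/6/3, widths 256–2048) with a
lightweight decoder of exactly 8 convolutions distributed [2,2,2,1,1] over
five bilinear upsampling stages plus a 1×1 classification head (32.5 M
parameters); the classic symmetric U-Net preset (31.0 M) and a small
residual preset (~112 k, downsampling factor 8) complete the set. Where
the reference architecture leaves the decoder layout open we chose
interpolation upsampling with convs after each concatenation; the
transposed-conv variant exists in the classic preset. Grayscale inputs use
a 1-channel stem by default; an encoder checkpoint can be transplanted
(`load_pretrained_encoder`), which replaces encoder tensors only and
rejects shape mismatches naming the offending tensors.

Training uses the soft-Jaccard loss `1 − mean_c (|P∩T|+ε)/(|P∪T|+ε)` over
the two foreground classes only (ε = 1e-6); background is excluded so it
cannot dominate the average. The learning rate follows cosine annealing
with warm restarts; restart periods default to [70, 80] over 150 epochs
with lr 1e-3 → 1e-6, and the curriculum switch must coincide with a restart
boundary (validated). Phase 1 trains on parametric maps *and* the weighted
images used to construct them; phase 2 restricts to maps. Augmentation
applies one shared spatial transform (random crop 0.85–1.0 of the frame,
resize to the network input, nearest-neighbor for masks) and photometric
jitter to the image only; inference uses a fixed full-frame resize.
Images are normalized by fixed per-kind scales (T1 maps /1500, T2 maps
/250, weighted /2000) rather than per-image statistics — per-image
standardization would cancel photometric augmentation exactly.

Desk-scale choices: the experiments in the tests and the acceptance script
train the small preset on 64×64 phantoms (34 cases ≈ 100 slices ≈ 200 map
images plus their weighted stacks) for 20 epochs with restart periods
[9, 11] and the curriculum switch at 9 — the same 150:70:80 proportions at
a size a single CPU core handles in a few minutes. This run reaches ~0.94
held-out Dice with apical slices lowest. Case-level splitting
(largest-remainder rounding of 65/20/15) guarantees no subject contributes
to more than one partition.

## Mask-to-contour pipeline

1. **Boundary tracing.** Connected components (8-connectivity) of the
   target region — cavity for endocardial, the filled epicardial disk
   (classes 1+2) for epicardial, so the ring's outer boundary is isolated —
   are traced with Moore-neighbor tracing and Jacob's stopping criterion,
   yielding ordered closed pixel loops.
2. **Dominant points (Teh–Chin).** Each point's region of support grows
   while the chord keeps lengthening and the signed
   perpendicular-distance/chord ratio shrinks in magnitude; curvature is
   the k-cosine over the support arms; non-maxima within half the support
   are suppressed, near-straight points (cosine within 0.05 of −1) dropped,
   and adjacent survivor runs collapsed to their curvature maximum. On a
   rasterized square exactly the 4 corners survive; on smooth shapes every
   staircase bend survives, keeping the polygon dense enough for accurate
   splining.
3. **Candidate filtering** (only when several components exist): discard
   candidates with axis-aligned bounding-box aspect ratio above 3, keep the
   largest area; if everything is discarded, fall back to the largest area
   with a warning. With filtering disabled (ablation mode) all candidate
   contours are merged, representing the uncurated prediction.
4. **Convex-hull correction** (only when triggered): if the hull area
   exceeds the polygon's shoelace area by more than 5 % of the hull area,
   the contour is replaced by its hull. The threshold is a declared choice:
   large enough that rasterization concavities never trigger it (0/200
   random ellipses in tests), small enough that every constructed C shape
   (wedge ≥ 0.6 rad, hull excess ≳ 9 %) does.
5. **B-spline resampling.** A periodic interpolating cubic (`splprep`,
   s=0) through the points, resampled at 200 parameter-uniform positions;
   the degree drops automatically below 4 points. Distance metrics are
   computed on these dense curves; tiny speck contours (<8 points, only
   reachable in unfiltered ablation mode) stay polygonal because an
   interpolating spline merely overshoots them.

Degenerate inputs: an empty cavity or epicardial region raises a structured
error naming the missing structure; a collinear loop collapses to a minimal
3-point contour with a warning.

## Metrics

Overlap metrics are computed on mask regions — endocardial on the cavity
(disk-like), epicardial on the myocardium (ring-like). The ring topology
makes the epicardial Dice strictly more sensitive to the same boundary
error, which the tests verify with a 1 px shift. Dice and IoU satisfy
`dice = 2·iou/(1+iou)` (fuzz-checked). Distance metrics are point-set
distances between spline-resampled contours, scaled per axis to mm; the
Hausdorff distance is the max-of-directed-max-min (not a percentile
variant — an explicit choice), MSD the symmetric mean. Empty-region
comparisons return NaN with a warning, never a silent 0 or 1.
`best_achievable_hd` measures the rasterize→fit→HD round trip of exact
truth contours: the floor any model evaluated through masks can reach
(≤ one pixel diagonal, 2.13 mm at 1.5 mm spacing, on ≥95 % of phantom
slices). Mapping-value statistics are the median and IQR of map values
over the myocardium mask, excluding failed-fit pixels. ICC uses the
two-way random-effects, average-measures form (ICC(2,k)) with its F-based
95 % CI, via `pingouin`. Inferential group comparisons (ANOVA variants,
post-hoc tests) are out of scope; the report emits per-group tables any
statistics package can consume.

## Known limitations

* The NumPy network engine is single-threaded BLAS-bound; the flagship
  presets are buildable and runnable but meant for parameter-count and
  architecture checks, not full-resolution training.
* The phantom's difficulty ordering (apical hardest) comes solely from
  size; real apical difficulty also involves resolution and planning
  effects the generator does not model.
* The hull-trigger threshold and Teh–Chin collinearity tolerance are
  declared defaults, not fitted to any external data; both are config
  fields.
* Determinism holds within one BLAS/numpy build (the test suite re-runs
  training twice in-process to check it); bit-identity across different
  library builds is not guaranteed.
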