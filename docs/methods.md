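# Methods

This note documents the models, algorithms and design choices behind
`woundmap`, in the spirit of a methods supplement: what each stage computes,
the parameters that matter and their defaults, what the synthetic benchmark
does and does not emulate, and the known limitations.

## Intensity model and I/O

Movies are held as `(T, H, W)` float stacks in [0, 1], normalized by a
single min-max over the *whole movie* rather than per frame. LBP codes are
grayscale-invariant, but the segmentation threshold is not; a per-movie
normalization keeps one variance threshold meaningful across all frames.
Normalization is monotone, so pixel ordering (and hence every texture code)
is unaffected. Physical calibration (µm/pixel, minutes/frame) is always an
explicit user input: bright-field TIFF exports rarely carry reliable
metadata, and every downstream unit (µm/hr speeds, µm distances) depends on
it. Multi-channel images are rejected — the method is defined on a single
bright-field channel.

## Segmentation

Cellular vs background is decided by local intensity variance: monolayer
texture is high-variance, the denuded wound is nearly flat. The variance
image is computed over a sliding window (default: half a patch, ≥3 px) and
thresholded. The automatic threshold is Otsu applied to **log** variance:
within-monolayer texture variance spans an order of magnitude, and in linear
units Otsu splits the cellular class itself rather than separating it from
the near-zero wound mode. The threshold is selected once per movie, on frame
0 (where a wound is guaranteed present), and reused: a per-frame Otsu would
hallucinate a background class in fully healed frames.

The thresholded mask is cleaned by binary closing, then eroded by the same
radius: the sliding window spreads cellular texture ~window/2 into the
background, biasing the boundary outward, and the erosion restores it (both
operations are computed on edge-padded arrays so the image border is not
eaten). Components and holes smaller than one patch area are removed. On
default synthetic movies this yields Jaccard ≥ 0.98 against the true
cellular mask and per-frame wound areas within 10% of truth down to about a
quarter of the initial area; below that the remaining sliver is thinner than
the variance window and cannot be resolved. Consequences: detected closure
lags/leads truth by ≤ 2 frames, and first contact is declared up to ~3
frames early (closing bridges a sub-window gap).

The wound is the background component overlapping the initial scratch: at
frame 0 the largest background component; later, any component overlapping
the previous wound. This keeps the wound's identity as it fragments near
closure and excludes intra-monolayer holes.

## Motion estimation

Block matching with normalized cross-correlation (NCC). Patches tile the
frame without overlap; the default patch is 18.5 µm a side with a hard floor
of 8 px (at 4 µm/px this floor makes the effective patch 32 µm). For each
patch the NCC against the next frame is evaluated over integer shifts within
the search radius (default 5 px, or `search_radius_um` if set); ties in the
arg-max resolve toward the smallest displacement (a bias to stillness), and
the peak is refined by independent 1-D parabolic fits along each axis,
clamped to ±0.5 px. A correlation of exactly 1 (identical content) skips
refinement — the parabola could only move the peak off an already exact
match. Displacements convert to µm/hr via `px · pixel_size · 60 /
frame_interval_min`.

Validity flags: patch center non-cellular; patch variance below 10% of the
movie's median patch variance (textureless); best NCC below 0.5; or search
window leaving the frame (border patches). NCC makes the estimate exactly
invariant to affine intensity changes of either frame with positive scale.
On band-limited synthetic texture, integer translations are recovered to
better than 0.25 px.

The toward-wound component is obtained from the distance map: the unit
down-gradient of distance points at the wound, `v_toward = −v·∇D/|∇D|`,
positive when approaching; the parallel component is the orthogonal
remainder, so the squared speed is preserved. Patches on distance plateaus
(the ridge equidistant between two fronts) have no defined direction and are
flagged.

## Velocity magnitude map, phases, average cells

Distances come from an exact Euclidean distance transform of the wound
region, in µm, evaluated at patch centers. Distance is measured to the
nearest wound *pixel* (so a pixel adjacent to the wound reads one pixel
spacing, not zero — the convention that makes the straight-edge closed form
`d(c) = c_edge − c` hold). With two opposing fronts each pixel reads its
nearer front, so both sides contribute symmetrically. After full closure no
wound exists; the last defined map (distance from the healed seam) is
carried forward, flagged, so post-closure speeds remain attributable to a
location.

`M[t, d]` averages the speed magnitude `√(v_row² + v_col²)` of every valid
patch whose center falls in strip `d` (strip width defaults to one patch
width). Empty bins are missing (NaN), never zero. Velocities exist per
patch, not per pixel, so the strip average is taken at patch resolution.

Phases: first contact is the first frame in which the cellular region
8-connects the two image borders flanking the scratch (the wound, treated
4-connected, no longer separates the fronts); full closure is the first
frame whose wound area falls below `closure_area_fraction` (default 1%) of
the frame-0 area. A movie that starts closed gets both boundaries at 0; a
wound that never heals leaves them undefined, and downstream descriptors
then require operator-supplied phase frames.

Average-cell displacement `R(t)` accumulates the per-frame strip-mean
toward-wound velocity times the frame interval, up to closure. By default
the anchor *advects*: its strip is re-selected each frame from the remaining
distance `d₀ − R(τ)` (floored at zero), i.e. the average cell travels
through the strips; a `fixed` mode keeps the initial strip. The advecting
interpretation matches the idea of tracking a cell rather than monitoring a
location; the switch exists because either reading is defensible. Per-anchor
velocity profiles are fixed-strip by construction and smoothed with a
centered 5-frame moving average.

## Texture representation

Rotation-invariant uniform LBP with 8 neighbors at radius 1. A "ten possible
codes" texture descriptor with 8 ring neighbors uniquely identifies this
variant (P + 2 = 10 bins), so it is adopted: neighbor ≥ center sets a bit
(ties count as brighter, making constant regions code 8); patterns with ≤ 2
circular transitions — 58 of the 256 — are coded by their number of ones
(0–8), all others collapse to code 9. Diagonal neighbors are sampled at
exact radius 1 by bilinear interpolation; border pixels are excluded. The
10-bin histogram over cellular pixels is L1-normalized; an empty mask yields
an undefined (NaN) histogram, not zeros. The per-frame series is summarized
for classification by the mean histogram over the contact-to-closure phase,
where the synthetic morphology programs (and the biology they emulate) put
most morphological change. The implementation is cross-checked in the tests
against scikit-image's `local_binary_pattern(method="uniform")`.

## Single-cell morpho-kinetics

Trajectories are integrated through the patch fields by forward Euler with
bilinear interpolation between the four surrounding patch centers; invalid
patches drop out of the interpolation (weights renormalize), and if no valid
patch lies within one patch radius the track terminates with a status flag
rather than inventing motion. On default synthetic movies the mean distance
between estimated and ground-truth tracks stays below one patch width.

Area and eccentricity come from the equal-second-moments ellipse of a
labeled cell mask (`skimage.regionprops`): eccentricity `√(1 − (b/a)²)`, 0
for a circle, → 1 for a line. Cell density is estimated from mean cell area
as `packing_fraction / area` (reported per 1000 µm²); the packing fraction
(default 0.9, a confluent monolayer) scales absolute density only and
cancels in correlations. Density–speed association uses Spearman's rank
correlation with average ranks; for n ≤ 8 the two-sided p-value is exact by
enumeration of all n! rank permutations, beyond that the usual
t-approximation.

## Descriptors, classification, statistics

The distance axis of `M` is split into 6 equal intervals over
[0, `max_distance_um`] (default 350 µm); each descriptor entry is the mean
of all defined map bins in one interval over one phase's frames, ordered
phase-major. Three phases give a length-18 vector; cohorts in which some
experiments never complete closure use Phases 1–2 only (length 12). A
wholly missing interval × phase cell is an error naming the cell, not a
silent zero. Norm-1 (Euclidean) normalization removes overall motility
scale, leaving the spatio-temporal pattern.

Classification is leave-one-out: each experiment is predicted by a linear
SVM (C = 1) trained on the others, with per-fold feature standardization.
Kernel, C and standardization are the minimal-assumption baseline for a
cohort of ~11 samples; all three are config-exposed. Group separation of
the per-fold decision scores is tested with an exact two-sided Wilcoxon
rank-sum: the statistic is the tie-averaged rank sum of one group, the null
enumerates every `C(nA+nB, nA)` assignment, and the two-sided p doubles the
smaller tail (capped at 1). At complete separation this gives 2/462 ≈
0.0043 for 6 vs 5 and 2/924 ≈ 0.0022 for 6 vs 6. Beyond 25 pooled
observations a tie-corrected normal approximation is used. PCA projections
use a deterministic sign convention (largest-magnitude loading positive).

## Synthetic movies: what they emulate, and what not

The generator reproduces the *study conditions*: a ~300 µm vertical scratch
in a confluent monolayer, imaged every 14.5 min, with ~350 µm of monolayer
behind each front. Defaults render 60 frames of 128×256 px at 4 µm/px
(~14 h — long enough for the untreated and treated regimes to traverse all
three phases at desk scale).

The monolayer is modelled per image row as a 1-D chain of material points
(one per pixel column) advected toward the wound by a prescribed speed law
`v(d, t)` of the distance `d` to the row's current front:

* **untreated** — `v = v_front·exp(−d/λ)` with `v_front = 20 µm/hr`,
  `λ = 100 µm`: front layers lead, constant in time until closure.
* **treated** — a logistic activation wave of width 40 µm travelling
  backward at 90 µm/hr lifts cells from that base profile onto an activated
  plateau `35·(1 + 0.25·d/(d+λ))` µm/hr that rises mildly with distance, so
  that once the wave has passed, distant cells move at least as fast as the
  front — the Phase-2 reversal.
* **inhibited** — the untreated form with `v_front = 15 µm/hr`, `λ = 45 µm`:
  weakest motility and the steepest front-to-distant ratio.

These functional forms (exponential decay, logistic wave) are the simplest
fields with the right qualitative structure; the magnitudes are realistic
for epithelial sheet migration (tens of µm/hr; activation waves of tens of
µm/hr propagating back from the edge). Once a row's fronts meet, its cells
decelerate exponentially with a time constant growing with distance
(`1 h · (1 + d/λ)`), so front cells halt first. The scratch width is
modulated sinusoidally across rows (±40 µm) so the narrowest rows touch
several frames before the widest rows close — first contact and full
closure are distinct, and the middle phase is never degenerate.

Frames are rendered by sampling a static pseudo-cell texture (anisotropic
Gaussian blobs at the regime's cell scale — 20/28/17 µm for
untreated/treated/inhibited — plus finer organelle-scale detail) at the
advected material coordinates, with per-frame additive sensor noise
(σ = 0.01). Rendered motion is therefore *exactly* the integrated
kinematics, and the ground truth exposes: the velocity law, the realized
per-bin speed map, per-frame wound masks, contact/closure frames, material
tracks and noise-free per-patch velocity fields. Cell-level morphology
(area/eccentricity programs per regime, distance and phase) is provided as
labeled ellipse masks rendered on demand — a synthetic stand-in for marked
single cells, used by the morphometrics tests.

Not emulated: proliferation and division, leader-cell fingers, vertical
motion, intercellular force transmission, photobleaching or illumination
drift, and cell-scale texture turnover (the texture is a material property,
so sustained velocity gradients stretch it more than real cells deform —
visible as slightly degraded recovery near fast, steep-gradient fronts).
Passing the end-to-end suites therefore demonstrates correct measurement of
prescribed advective motion under realistic texture and noise, not
robustness to every artifact of real microscopy.

## Numerical choices and degenerate inputs

* Kinematics integrate with 4 Euler substeps per frame; chains are kept
  monotone with a 0.01 µm spacing floor, and rows are clamped at their
  meeting point after contact.
* Block-matching scores are computed against NaN-padded frames; any shift
  touching the padding is unusable for that patch.
* Constant frames segment to all-background with a warning (not an error);
  zero-motion scenarios leave phases undefined and descriptors unavailable,
  with the reason recorded in the run manifest.
* `write_matrix` refuses non-finite entries, naming the offending indices;
  maps with legitimately missing bins are exported via the pipeline's CSV
  writer, which renders NaN as empty cells.
* All randomness (texture, noise, edge phases, track seeding) derives from
  a single scenario seed through spawned child generators; identical seeds
  give bit-identical movies, and the run manifest records SHA-256 checksums
  of inputs and key outputs so a run can be verified as reproduced.

## Benchmark problem sizes

The standard benchmark movie is 128×256 px × 60 frames; a full pipeline run
takes a few seconds, and the 11-movie classification cohort (6 untreated +
5 treated, distinct seeds) runs end to end in under a minute. On these
conditions the measured velocity map recovers the realized ground-truth map
with mean absolute error ≤ 15% of the regime's peak speed (typically 4–6%
for untreated/treated, ~13% for the steep-gradient inhibited regime), and
leave-one-out classification of the cohort is 100% correct on both raw and
norm-1 descriptors.

## Known limitations

* Wound-boundary localization is limited to ~1 px per row after bias
  compensation; area estimates degrade below ~25% of the initial wound area
  and closure detection is ±2 frames at 4 µm/px.
* First contact relies on mask connectivity and can fire up to ~3 frames
  early when the remaining gap is thinner than the closing radius.
* Block matching assumes locally rigid translation per patch; strong shear
  or rotation within a patch biases the estimate (mitigated by sub-cellular
  patch sizes).
* The exact rank-sum enumeration is practical to ~25 pooled observations;
  larger cohorts fall back to the normal approximation (flagged by the
  docstring contract, cohort sizes here are far below the limit).
* The CLI reads multi-page TIFF and per-frame image directories only;
  proprietary microscope formats must be converted upstream.
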