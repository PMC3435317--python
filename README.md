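# woundmap

Fully automated quantification of long-term bright-field (DIC) wound-healing
time-lapse movies.

In a scratch assay, a strip of cells is removed from a confluent monolayer
and the collective migration that refills the gap is imaged for many hours.
Classical read-outs (wound area over time, a handful of manually tracked
cells) discard almost all of the spatiotemporal structure of that process.
`woundmap` extracts it without any cell tracking or fluorescent labels, using
only the texture of the bright-field images:

1. **Segmentation** — each frame is partitioned into cellular and background
   (wound) regions by thresholding a local-variance image; the wound is
   tracked across frames by overlap.
2. **Motion estimation** — the frame is tiled into sub-cellular patches
   (~18.5 µm at the reference magnification) and each patch's displacement to
   the next frame is found by normalized-cross-correlation block matching
   with sub-pixel parabolic refinement, giving a velocity field in µm/hour.
3. **Velocity magnitude map** — the central representation: a matrix
   `M[t, d]` holding the mean speed of all cellular material at distance-bin
   `d` from the wound edge at time `t`. The healing process is partitioned
   into three phases (scratch → first contact of the opposing fronts →
   full closure → post closure), detected automatically from the wound masks.
4. **Average-cell analysis** — per-strip toward-wound velocities are
   accumulated into displacement curves `R(t)` for "average cells" anchored
   at chosen distances, and single-cell trajectories are integrated directly
   through the velocity fields.
5. **Texture descriptors** — a 10-code rotation-invariant uniform local
   binary pattern (LBP, 8 neighbors at radius 1) histogram over cellular
   pixels per frame, a grayscale-invariant implicit measure of multi-cellular
   morphology.
6. **Classification** — a whole experiment is compressed to a descriptor
   vector (mean speed per distance interval × healing phase: 6 intervals ×
   3 phases = length 18, or × 2 phases = length 12; optionally normalized to
   unit Euclidean norm to isolate the *pattern* from overall motility), and
   cohorts are classified by leave-one-out linear SVM with exact Wilcoxon
   rank-sum significance and 2-component PCA.

A synthetic movie generator (`woundmap.synthetic`) renders scratch-assay
movies with full ground truth in three motility regimes — untreated
(exponential decay of speed with distance from the edge), treated (a
growth-factor-like activation wave travelling backward from the edge) and
inhibited (weaker, steeper-decaying motility) — and is used to benchmark
every stage end to end.

## Worked example

Generate a treated-regime synthetic movie (128×256 px at 4 µm/px, one frame
every 14.5 min, ~300 µm scratch) and run the full pipeline. At this pixel
scale the analysis uses 32 µm patches (8 px — the matcher's minimum):

```python
import numpy as np
import woundmap as wm

scenario = wm.SyntheticScenario(regime="treated", rng_seed=2)
movie, truth = wm.generate_movie(scenario)
config = wm.RunConfig(patch_size_um=32.0)
result = wm.run_experiment(movie, config)

ph = result.phases
print(f"phases: contact at frame {ph.t_contact}, closure at frame {ph.t_closure}")
M = result.velocity_map.M
p1 = np.nanmean(M[: ph.t_contact], axis=0)
p2 = np.nanmean(M[ph.t_contact : ph.t_closure], axis=0)
print("mean speed (um/hr) vs distance, Phase 1:", np.round(p1[:8], 1))
print("mean speed (um/hr) vs distance, Phase 2:", np.round(p2[:8], 1))
print("descriptor (length 18):", np.round(result.velocity_vector.values, 1))
```

prints

```
phases: contact at frame 14, closure at frame 19
mean speed (um/hr) vs distance, Phase 1: [34.1 33.1 29.9 25.7 21.3 16.8 12.5  9. ]
mean speed (um/hr) vs distance, Phase 2: [36.6 38.9 37.7 37.  38.  38.6 38.5 37.4]
descriptor (length 18): [33.6 27.8 21.3 14.7  7.5  3.2 37.7 37.4 38.  38.6 36.  26.6  7.1  8.9
 10.4 11.7 17.1 20.2]
```

Reading the output: during Phase 1 speed falls off with distance from the
wound edge (front cells lead), but by Phase 2 the activation wave has passed
and distant strips move as fast as — or faster than — the front, the
signature reversal of the treated regime. The length-18 descriptor is the
phase-major flattening (6 distance intervals × 3 phases) of that map;
Phase 3 (last 6 entries) shows the post-closure deceleration.

The same pipeline is available from the shell:

```bash
woundmap simulate --regime treated --seed 2 --out run/movie.tif
woundmap run-all run/movie.tif --pixel-size 4 --interval 14.5 --out run/analysis
```

which writes the velocity map (CSV + heatmap PNG with phase lines), LBP
histogram series, wound-area curve, descriptor vector and a manifest that
suffices to re-run the analysis bit-identically. `woundmap classify` runs a
labeled cohort through leave-one-out SVM classification.

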