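# Methods

## Problem and approach

`headdir` codes the per-frame head direction of a single freely moving
animal filmed from above against a static scene. It is *semi*-automatic
by design: a deliberately simple image-processing chain does the bulk of
the work, and a replayable manual-override schedule stands in for the
interactive corrections a human coder would make, so the cost of the
residual errors is a bounded amount of human effort rather than a wrong
dataset.

The per-frame chain is:

1. **Background differencing.** `I = |F − BG|` per channel against a
   stored image of the empty scene, collapsed to greyscale with BT.601
   luma weights (0.299 R + 0.587 G + 0.114 B). The luma conversion is
   computed in exact integer arithmetic ((299R + 587G + 114B)/1000, ties
   rounding up) so outputs are bit-reproducible across BLAS/platform
   variations.
2. **Greyscale morphological opening**, `mExOIter` iterations of the 3×3
   8-neighbourhood minimum followed by the same number of maxima.
   Removes noise and bright features narrower than ≈ `2·mExOIter + 1`
   px. Border neighbourhoods are clipped to the image; no padding value
   is invented (edge replication, which is what the min/max filters use
   internally, is equivalent).
3. **Binarization** at `thParam`, strictly greater-than.
4. **Contours.** Canny edges (σ = 1) on the mask; contours are the
   8-connected components of the edge map. Each contour's *half girth*
   is the width + height of its own bounding box; contours below
   `contourTh` are dropped, and the minimum bounding rectangle (MBR) is
   taken over all surviving contour points.
5. **Motion gate.** `m = sqrt(Σ|g₁ − g₂| / 255)` between the current
   frame and the last frame in which motion was detected (initialised to
   the session's first frame). The species algorithm runs only when
   `θ_l ≤ m < θ_u`; the upper bound rejects global changes such as
   lighting shifts. Otherwise the previous frame's state is carried.

Head geometry is then species-specific. All headings use
`atan2(−(h_y − b_y), h_x − b_x)` in degrees — counterclockwise from
image-east with the downward image y-axis negated — range (−180, 180].

**Cluster algorithm** (elongated species; alligator/gerbil archetype).
Foreground pixels are clustered with k-means (k-means++ initialisation,
fixed seed, 100-iteration cap; empty clusters are handled by the
library's internal reassignment). A head point is projected from the
previous base point along the previous heading by the longer MBR side;
the cluster with the nearest centroid is the head cluster, `hPos` is its
foreground point nearest the projection, and `bPos` is the centroid of
the neighbouring cluster closest to the head cluster. A variant replaces
`bPos` with the intensity centroid of a red colour tag, detected by an
inclusive HSV in-range test over H ∈ [175, 180] (half-degree hue scale),
S ∈ [100, 255], V ∈ [90, 255].

**Ear-tuft algorithm** (tufted primates; marmoset archetype). Heavy
opening (`mExOIter = 8`) leaves only the two bright ear tufts; the two
largest contours are the ears, `bPos` is the midpoint of their centres,
and rotating the ear line by 90° about `bPos` yields two candidate
`hPos` points at half the ear separation. The candidate whose heading is
circularly closer to the previous heading wins; an exact tie goes to the
+90° (counterclockwise) rotation, with the ear pair ordered by (x, y) so
the tie-break is deterministic. `hdLineLen` is only the overlay drawing
length, not the candidate offset.

**degTh gate.** A candidate whose circular distance from the previous
heading exceeds `degTh` is rejected and the previous state held (not
clamped): stale frames stay visibly stale and attract manual review.
Algorithm failures (too few foreground points, fewer than two contours,
no tag pixel) likewise fall back to the previous state and are counted,
so human effort can be estimated from the run summary.

**First frame.** A batch replay has no mouse, so the first frame's state
must come from `initial_state` in the configuration or an override row at
that frame.

## Manual override replay

The interactive mouse input of a GUI coder is recast as data: a CSV
schedule of `(frame, hPos, bPos, continuous, continuous_off)` rows.
An explicit row sets the frame's state with `mHPos = mHD = True`.
`continuous` freezes that manual state over subsequent frames
(`mHD = True`, `mHPos = False`) until a `continuous_off` row releases it;
a fresh manual input during the mode refreshes the frozen state. A
backward-navigating coder has no batch equivalent; overrides must be
pre-listed.

## Synchronization and extraction

The session log's clock starts when an LED in a fixed region of the
scene switches on. `white_mass` counts low-saturation, high-value pixels
(defaults S ≤ 40, V ≥ 200 on the 0–255 scale; hue unconstrained) inside
the LED ROI — the binary mask's zeroth moment divided by 255. The first
frame whose mass differs from the first frame's baseline by more than a
user-supplied threshold (two-sided, so an LED switching *off* also
counts) is the session-start frame `i`, and `ΔT = (i − 1)·1000/fps` ms.
The threshold is a required configuration value; it depends on LED size
and scene and has no universal default. An LED already on at frame 1
presents no change and is reported as "onset not found" — the baseline
is assumed dark.

For a stimulus logged `t` ms after session start, the onset video time
is `t + ΔT` and the onset frame `⌊(t + ΔT)·fps/1000⌋ + 1` (floor rather
than round: the residual is under one frame period either way, and floor
keeps the mapping monotone and exact on frame boundaries). The extracted
window spans `pre_s` before to `post_s` after (defaults 5 s + 5 s), so
the onset frame sits at 1-based position `pre_s·fps` of
`(pre_s + post_s)·fps` frames — position 500 of 1000 at 100 FPS. Frames
are cropped, renumbered from 1 and filed under
`<group>_<subject>_t<n>_<stimulus>`. Per-trial LED re-synchronization is
deliberately not performed (each trial is placed arithmetically from the
single session-start ΔT); a jittering acquisition clock therefore shows
up as a small onset-position offset, which is the quantity a user would
audit.

## Synthetic scenes and what they do (not) show

The generator plants a known trajectory and renders what the chain needs
to see, nothing more:

* **Cluster archetype** — a chain of bright disks (intensity 200 on a
  dark background, 12) trailing the leading *head* blob, which is
  slightly smaller (radius 6 vs 9, spacing 22 px) so the head cluster is
  geometrically identifiable. Planted `hPos` is the head blob's anterior
  tip, `bPos` the neighbouring blob's centre; both lie on the heading
  line, so planted `hDir = head_angle(hPos, bPos)` exactly.
* **Tuft archetype** — a dim body disk (70) plus two bright tufts (230,
  radius 12, separation 44) straddling the head axis. The spec is
  generator-enforced: tuft radius must exceed the opening scale (8) and
  the intensity contrasts must straddle the threshold (120), so the
  documented default parameters provably isolate the tufts.
* **LED sessions** — dark frames with a pure-white block in the ROI from
  the planted onset time, plus a log in the extraction format.

Additive uniform integer noise (default ±3 levels) exercises thresholds
without modelling camera physics. All images are 8-bit greyscale
replicated to three channels and written as lossless PNG — the frame
naming convention is unchanged, but planted intensities survive encoding
exactly, which JPEG would not guarantee for threshold-adjacent values.
Trajectories are smooth circular arcs (2.5°/frame heading change) with
random seed-derived phase.

Passing these closed loops shows the geometry, gating, bookkeeping and
synchronization arithmetic are correct. It does **not** show robustness
to what real footage adds: deformable bodies, occlusion, shadows,
lighting drift, compression artefacts, fur texture, or multiple animals.
On real data the algorithms are expected to fail on a nontrivial
fraction of frames — that is what the override machinery and effort
accounting are for.

## Numerical choices

* Positions are carried internally as floats; CSV rows round half-up to
  integers. Recomputing a heading from rounded endpoints can differ from
  the stored (rounded-from-float) heading by up to
  `0.5° + 2·asin(√0.5 / |hPos − bPos|)` — about 1° at body scale.
* k-means seeds are fixed and configurable; reruns are byte-identical.
* Circular difference is `min(|a − b| mod 360, 360 − ...)`, in [0, 180].
* Manual-effort SD is reported with both population and sample
  denominators (`sd_population`, `sd_sample`); "manual inputs" counts
  explicit interventions (`mHPos`), with continuous-mode frames tallied
  separately.
* Opening is implemented as n erosions followed by n dilations (the
  behaviour of the standard library routine); for n ≤ 1 this coincides
  with n repetitions of (erode + dilate), and the two interpretations
  are both expressible by calling the primitive directly.

## Validation problem sizes

The test suite and the acceptance script validate at desk scale: 40-frame
320×240 scenes, ten seeds per archetype; one default-scale LED session
(100 FPS, 16 s, 1000-frame windows) plus ten reduced-rate sessions; 100+
random instances per brute-force oracle. Measured on these conditions,
median circular error is ≈ 1.7° (cluster, k = 4) and ≈ 0.3° (tuft) with
a fallback rate below 1%, LED onset recovery is frame-exact, and the
onset sits at window position 500 of 1000.

## Known limitations

* No machine-learned pose estimation, multi-animal tracking or 3-D pose;
  one animal, one camera, static background.
* Batch replay cannot reproduce a coder navigating backwards to re-code.
* Video containers are out of scope: frames come in and go out as image
  sequences; decoding/encoding is delegated to an external tool
  (e.g. `ffmpeg`).
* The degenerate one-blob case where the head cluster and its nearest
  neighbour coincide is reported as a failure and held, not guessed.
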