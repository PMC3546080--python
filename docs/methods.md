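# Methods

## Input model and calibration

The pipeline consumes *pre-segmented* binary masks: foreground pixels
mark subbasal nerve fibres, everything else is background. Images are
treated as row-major grids with the origin at the top-left corner and
each pixel a unit square of side `pixel_pitch_um`. The default
calibration is the HRT-II / Rostock Cornea Module field — 384 px over
400 µm per axis, i.e. 1.0417 µm/px and an imaged area of 0.16 mm².
A note on that field: the acquisition literature sometimes states the
field as "400 µm²", which is dimensionally inconsistent with all
published density arithmetic; every number here assumes a 400×400 µm
(0.16 mm²) field, and the reader is warned in the log when the default
is used. Calibration can be overridden per image by a JSON sidecar
(`{"pixel_pitch_um": ...}`) or a CLI flag. Binarisation thresholds
8-bit intensity at 127 (white-on-black convention, flippable with
`--invert`) and is idempotent on already-binary input.

## Stage 1 — morphology before skeletonisation

Foreground connectivity is 8-connected (background 4-connected), the
standard Jordan-consistent pairing for thin curvilinear structures.
Connected components are interpreted as individual nerve-fibre
networks and labelled deterministically in raster order of their first
pixel. Reported quantities: component pixel count, component ratio
(100 × pixels / field pixels), component count, and homogeneity.

**Homogeneity.** No formula for the "distributional uniformity of
component pixels" is fixed by the originating study, so the package
defines it as the population variance of per-tile foreground fractions
over an 8×8 tiling (tile remainders are absorbed by the last tile per
axis, for determinism). It is 0 exactly when coverage is uniform
(including all-empty and all-full fields) and grows as a fixed pixel
budget concentrates in fewer tiles; for all foreground in one of k²
tiles it equals (k²−1)/k⁴. Absolute agreement with any other tool's
homogeneity values is *not* claimed — only the ordering semantics.

## Stage 2 — skeletonisation

The mask is reduced to a one-pixel-wide medial axis by iterative
boundary thinning (Zhang–Suen-family, via scikit-image), iterated to a
fixed point so the operation is idempotent by construction (the fixed
point is reached in one or two passes in practice).

Border handling: the mask is padded by **edge replication** (8 px)
before thinning and cropped afterwards. Replication extends a fibre
that is cut off by the field border straight outward, so its skeleton
keeps a stub reaching the outermost pixel row/column — these stubs
later become connectivity points. Plain background padding was
evaluated and rejected: free fibre ends then retract several pixels
from the border and border crossings are missed. Replication has its
own failure mode — a blunt blob flush against the border can thin into
the pad region and come back cropped or disconnected — so after each
pass any mask component whose thinned image is not exactly one
connected piece is re-thinned without padding (which is topology-safe)
and substituted. Net effect, verified by property tests: the skeleton
has exactly one 8-connected piece per mask component, is idempotent,
and keeps border stubs for elongated fibres.

## Stage 3 — graph topology

Each skeleton pixel is classified by its 8-neighbour count: 0
isolated, 1 terminal, 2 path, ≥3 junction. Digital junctions are
thicker than one pixel (an orthogonal T produces up to four ≥3-
neighbour pixels), so maximal 8-connected junction clusters collapse
into single **branch** nodes; counting raw junction pixels would
double-count every thick fork. Terminals on the outermost pixel frame
are **connectivity points** (fibres entering or leaving the imaged
field); interior terminals are true **nerve endings**. Edges are the
runs of path pixels between node pixels, traced deterministically in
raster order; a closed loop with no landmark becomes a single
self-loop edge anchored at a degree-2 node (so its length is
conserved and it counts as one fibre but contributes no branch or
endpoint). Isolated single pixels carry no measurable length and are
dropped during pruning.

Edge length is the chain code: (orthogonal steps + √2 × diagonal
steps) × pixel pitch. This estimator systematically overestimates the
length of a smooth curve — worst case ≈ 8 % for straight runs at
22.5°, ~3–5 % averaged over the orientations the phantom fibres
actually traverse. The 5 % length-recovery tolerance used in the tests
reflects this bias plus skeleton jitter at the default fibre
tortuosity; strongly tortuous curves (lateral sine amplitude ≳ 20 µm
at this field size) can push chain-code bias beyond 5 %, which is a
property of the estimator, not a pipeline defect.

**Spur pruning.** Thinning leaves one-to-two-pixel whiskers at
junctions. Traced segments shorter than `min_segment_um` (default
2 µm ≈ 2 px) that end in an interior endpoint are deleted; anchoring
junction pixels are kept, a final thinning pass flattens any leftover
one-pixel nub, and the graph is rebuilt once. Border stubs are never
pruned — a short stub at the frame is a genuine truncated fibre.

## Metric assembly and normalisation

`single_nerve_fibres` is the number of traced segments (edges);
`fibres_per_component` divides by the component count; density is
total length divided by the field area in µm². Density is stored in
**µm of fibre per µm²** even though the field traditionally prints the
unit as "mm/mm²": published length/density pairs only reconcile on the
µm/µm² scale (a healthy total of ~19 961 µm per mm² corresponds to the
printed density 0.02, and 6 223 µm per mm² to 0.006), so the printed
unit is treated as a label misprint and the CSV header names the unit
explicitly. The average single-fibre length is the mean over traced
segments of the image, not total-length-over-anything: a mean of
per-image averages is in general not the ratio of group means, which
is why published group tables show 74.8 rather than 19 961.3/302.2.
Normalisation to 1 mm² multiplies extensive quantities (pixel and node
counts, fibre counts, lengths) by 1/area_mm²; intensive ones (ratio,
homogeneity, density, averages, per-component) are unchanged, and a
flag guards against double normalisation. Empty images report zero
averages (with a warning) rather than NaN, for batch robustness.

## Phantom generator

The generator emulates the qualitative look of a healthy SBP — fibres
running roughly in parallel across the field with regular, mild
tortuosity and occasional branching — while keeping exact ground
truth. Per image one dominant orientation is drawn; each fibre gets a
stratified entry corridor, crosses to the opposite border (or, with
probability `interior_end_prob`, stops partway as a true ending) along
a chord displaced by `amp·sin(πmt)` (m ∈ {1,2}; amplitude default
12 µm, jittered ±50 % per fibre), and is rasterised at stroke width
3 px (which reproduces realistic coverage ratios: ~5.7 % for a healthy
field). With probability `branch_prob` a fibre carries one branch
event: a short (15–40 px) transversal twig ending inside the field.
Fibres are kept disjoint by rejection sampling against a dilated
occupancy mask (margin = stroke + 2 px) so that skeletons of distinct
fibres never merge and the recorded truth — analytic arc lengths
integrated on the continuous curves before rasterisation, plus event
counts — is exact. Twigs are placed in a second phase, after all main
fibres, so a twig can never block a fibre corridor; late placement
attempts fall back to straighter fibres so crowded fields still
complete. All randomness flows through one seeded generator; output is
bit-for-bit reproducible per seed.

Presets `healthy` (8 fibres, branch probability 0.5) and `neuropathic`
(2 fibres, branch probability 0.25, higher tortuosity) were calibrated
so their expected measured density falls within the published group
mean ± 1 SD (~0.02 vs ~0.006 µm/µm²). What the phantoms deliberately
do **not** model: speckle and depth blur of real confocal imaging,
fibre width variation, crossing fibres (available via
`allow_intersections` for stress testing, but then truth counts no
longer apply), and segmentation error. Passing the phantom suite
therefore validates the measurement chain on clean masks, not the
robustness of any upstream segmentation.

## Statistics layer

* `describe`: mean and sample SD (n−1).
* `dispatch_test`: each group is screened with a Lilliefors-type KS
  test (normal parameters estimated from the sample — the plain KS
  test with estimated moments is anticonservative, so the Lilliefors
  correction is used and recorded in the result). Both pass at
  α = 0.05 → Welch's t; otherwise Mann–Whitney U (exact for two untied
  groups of ≤ 8, normal approximation with tie correction beyond).
  Identical constant groups short-circuit to p = 1 with a note.
* `welch_from_summary`: t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂) with
  Welch–Satterthwaite df; agrees with the raw-data Welch test to
  10⁻⁹ when the summaries match.
* `stepwise_lda`: forward selection minimising Wilks' Λ with
  partial-F entry (p < 0.05) and removal (p > 0.10) — the classical
  SPSS-style defaults, since the originating analysis states the
  procedure but not its thresholds. The final linear discriminant uses
  equal priors (near-balanced 20/18 design) and resubstitution
  accuracy by default, matching how the published 36-of-38 figure is
  reported; leave-one-out is available. For one variable Wilks' Λ
  reduces to SS_within/SS_total; model significance uses Rao's F
  approximation.
* `simulate_cohort`: independent truncated-normal draws per variable
  (truncation at 0 for non-negative morphometrics), seeded.

## Problem sizes in the test-suite

The suite validates length recovery and exact topology on 100 seeded
default phantoms, graph invariants (handshake, pixel conservation,
density identity, 90° rotation equivariance) on 25 smaller phantoms,
idempotence and component preservation on 200 reduced-field phantoms,
and the discriminant replication on 200 simulated cohorts; the whole
run takes well under two minutes on a single core.

## Known limitations

* Chain-code length bias (above) bounds achievable length accuracy.
* A branch node can, in degenerate symmetric configurations, survive
  with degree 2 after pruning; counts are then conservative.
* The homogeneity score and the spur threshold are package choices;
  comparisons across tools should re-standardise both.
* Group means of the originating cohort are not reproducible from
  images (none were deposited); image-level validation is therefore
  phantom-based, and cohort-level validation works from the printed
  summaries.
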