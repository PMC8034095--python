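# Methods

## Pipeline model

`nodulecad` treats nodule detection as a funnel over per-slice 2D detections.
The stages, their parameters, and the reasoning behind each are described
below; all distances are millimetres in the LPS world frame, all intensities
Hounsfield units (HU).

### Geometry conventions

Voxel arrays are indexed `(z, y, x)`; headers (`origin_mm`, `spacing_mm`)
are `(x, y, z)` as in LUNA MetaImage files. Voxel `(0,0,0)`'s *centre* sits
at the origin; `world_to_voxel` / `voxel_to_world` are exact inverses.
Only axis-aligned volumes are accepted: a non-identity direction matrix is
rejected rather than silently resampled, because every downstream step
assumes the scan axes are the anatomical axes.

### Resampling

Volumes are resampled to isotropic voxels (default 1 mm) with trilinear
interpolation so that all later thresholds are true physical lengths. The
output grid has `round(extent / voxel_mm)` voxels per axis — physical extent
is preserved to within one voxel — the origin is unchanged, and no
anti-alias filter is applied (the common case is upsampling thick slices).
Single-slice volumes are rejected as degenerate.

### Overlapping MIP

Each output slice at position `p` along the projection axis is the per-pixel
maximum over the voxel planes whose centres lie in the closed window
`[p − w/2, p + w/2]` (default `w` = 25 mm). Two choices here were genuinely
open and are config-exposed:

* **Stride.** One output slice per voxel plane (stride = voxel size), i.e.
  maximally overlapping windows. This matches the per-slice density implied
  by training labels existing for every MIP slice, and it maximizes the
  number of raw inferences a real nodule can accumulate — the quantity the
  clustering stage feeds on. The stride must be an integer multiple of the
  voxel size so window centres stay on voxel planes.
* **Edge handling.** Windows are clipped at the volume boundary, not padded:
  padding with air (−1000 HU) would be equivalent under `max`, and clipping
  avoids inventing voxels.

Axial stacks project along z (images indexed `(y, x)`); coronal stacks
project along y (images `(z, x)`). Sagittal stacks are deliberately not
built. Annotation projection emits, for a nodule of diameter `d`, a square
box of side `d` on every slice whose window intersects the nodule's axial
extent `[c − d/2, c + d/2]`.

### Detector contract

The pipeline consumes `Detection2D` records (axis, slice position, in-plane
box in mm, confidence in [0, 1]) from any source. The baseline blob detector
(threshold at −300 HU, 8-connected components, equivalent-diameter gate
3–30 mm) exists to exercise the full rendered-volume path; its confidence —
mean component HU above threshold divided by 500, clipped to [0, 1] — is an
admittedly arbitrary monotone mapping whose only job is to exercise the
downstream confidence logic. No learned detector is trained or shipped.

### Clustering

Detections are lifted to world 3D points (axial: `(u, v, slice_pos)` →
`(x, y, z)`; coronal: `(u, slice_pos, v)`), pre-filtered at confidence 0.1
(the boundary value is *kept*: strictly-below is dropped), and clustered
with DBSCAN at eps = 10 mm, minPts = 4 on unweighted Euclidean distance —
confidence does not enter the metric. Border points reachable from several
clusters go to the cluster discovered first in input order (the classic
single-pass policy); this makes output deterministic and is verified against
a brute-force neighbour-matrix implementation using the same policy. Noise
points are discarded: candidates are clusters.

Each cluster is summarized by its centroid (mean of member centres — a
deliberate simplification that can offset the prediction slightly from the
true centre), a bounding diameter equal to the *largest* member box (an
envelope, roughly twice the true nodule diameter; not a size estimate), and
six metadata features: max and mean member confidence, inference count,
whether both axes contributed, and distance from the centroid's z to the top
and bottom of the scan.

### False-positive reduction

An XGBoost binary classifier over those six features produces the final
nodule confidence. Hyperparameters are fixed operating values: learning rate
0.05, max depth 6, 200 estimators, scale_pos_weight 2.7, column subsampling
0.6, row subsampling 0.8, single-threaded histogram trees with a fixed seed,
so train → score is reproducible bit-for-bit. A grid-search/CV utility was
considered and omitted: the fixed defaults keep runs deterministic and fast,
and nothing downstream depends on re-tuning.

Training labels come from an automatic distance surrogate (a manual
cluster-labelling pass is not reproducible): a candidate is positive iff its
centroid lies within `match_dist_mm` = 10 mm (the clustering eps) of a
same-scan annotation centre, matched to the nearest such annotation with
ties broken by smaller nodule id.

### Slice-assisted selection

Given a report's axial position, candidates with final score < 0.20 are
dropped, and the remaining candidate minimizing |centroid_z − target_z| is
returned if that distance is within the window (10 mm default, 20 mm
sensitive variant); otherwise no prediction (a miss). Distance is measured
along z only — a slice number constrains nothing else; full 3D distance is
available when the query carries an in-plane target. Ties break by higher
score, then lower candidate id. A helper converts slice indices to z for
both inferior-first and superior-first slice orderings, since report
conventions vary by scanner.

### Evaluation

Each query yields one outcome: `tp_intended` (hit the reported nodule),
`tp_unintended` (hit a different real nodule), `fp`, or `fn` (no
prediction). The hit criterion is centroid-to-centre distance ≤
max(annotation diameter, 10 mm) — tolerant of the MIP/centroid offsets noted
above. An annotation can be claimed as an intended hit once; later intended
hits on it are demoted to unintended (greedy in query order). Since a
false-positive prediction also misses its intended nodule,
`fn = n_queries − tp` and `recall = tp / n_queries`. Precision with zero
predictions is defined as 1 (vacuous truth). Adjusted metrics recount
unintended hits as false positives. The FROC sweep re-runs selection at each
score threshold (default grid 0.20–1.0 in 0.05 steps, 0.20 being the
pipeline floor) and records (recall, FP/scan) per point.

## Synthetic phantom and detection simulator

`generate_phantom` renders, by HU painting plus additive Gaussian noise
(σ = 20 HU default): air at −1000, a soft-tissue body ellipsoid at 40, a
lung ellipsoid at −850, tubular vessels at 50 HU (orientations: along z —
which mimics a nodule on axial MIPs only — along y, or a random walk), and
spherical nodules (soft tissue 60, ground glass −500, mixed −200, calcified
400 HU). Nodules must lie inside the lung and not overlap.

`simulate_detections` bypasses rendering and draws raw detections directly
in MIP-slice space, which is what makes clustering/reduction/selection
testable independently of detector quality (the rendered-volume + blob
detector path exists as a second, slower integration route). Defaults
emulate the regime the pipeline is designed for:

* a true nodule of diameter `d` is MIP-visible over `d + 25` mm per axis and
  fires Poisson(0.4/mm × extent) detections per axis (≈ 12 for a 5 mm
  nodule), on both axes with probability 0.9; slice positions are uniform
  over the visible extent, in-plane positions jittered with σ = 1.5 mm,
  confidences N(0.65, 0.15) clipped, box sizes 1–2× the true diameter
  (matching the bounding-diameter inflation noted above);
* vessel confounders: Poisson(2) single-axis chains per scan, each
  3 + Poisson(4) detections spread over 14 mm, confidences N(0.5, 0.2)
  clipped — deliberately *overlapping* the true-nodule confidence
  distribution, because what distinguishes a perpendicular vessel on a MIP
  is single-axis visibility and sparsity, not low confidence;
* background scatter: Poisson(30) isolated detections per scan, uniform in
  the volume, confidence ≤ 0.3 (mostly removed by the 0.1 filter or left as
  DBSCAN noise).

The standard benchmark (`nodulecad.benchmark`) builds 50 training and 20
test scans (disjoint seeds derived from one study seed), 2–4 nodules per
scan at least 40 mm apart with screening-like attenuation frequencies (85 %
soft tissue), and one slice query per nodule with a uniform ±2 mm
report-position error. These sizes keep a full study under a few seconds on
one CPU while leaving enough candidates (~150 training clusters) for the
reducer to fit stably.

### What the synthetic results do and do not show

The simulator's confounders are exactly the failure mode the reducer's
features target, so near-perfect precision/recall on the benchmark is partly
by construction. Passing tests demonstrate that the pipeline's mechanics are
correct (geometry, clustering semantics, feature computation, selection and
scoring logic, determinism) and that the dual-axis feature is informative in
the regime it was designed for — not that any particular precision or recall
would be obtained on real CTs, where nodule conspicuity, detector quality,
atelectasis and pleural contact dominate. The phantom has no airways,
fissures, subpleural geometry, reconstruction-kernel effects, or
attenuation-dependent detector sensitivity.

## Numerical choices and degenerate inputs

* Window membership uses voxel *centres* within the closed window; with a
  25 mm window on a 1 mm grid, a point structure appears on exactly 25
  slices.
* DBSCAN neighbourhoods are closed (distance ≤ eps), matching both the
  library implementation and the test oracle.
* The confidence filter keeps the boundary value (drop iff < 0.1);
  selection drops candidates strictly below the 0.20 floor.
* Empty inputs: scoring an empty candidate list returns an empty list;
  a scan with no surviving candidates yields `fn` for all its queries and
  precision falls back to the zero-prediction convention.
* Reducer training requires at least two examples of each class; single
  class is an error, not a silent fallback.
* All stochastic components (phantom, simulator, cohort sampling, XGBoost)
  consume explicit integer seeds; two runs with the same seeds are
  byte-identical down to the predictions CSV.

## Known limitations

Axis-aligned geometry only (no gantry tilt, no DICOM series assembly);
sagittal MIPs not implemented; the baseline blob detector is not a useful
clinical detector; bounding diameters are envelopes, not size estimates; the
automatic distance-based labelling surrogate can mislabel a confounder that
drifts within 10 mm of a true nodule.
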