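# nodulecad

A high-precision, axial-slice-assisted lung nodule candidate pipeline for
chest CT.

Radiology reports routinely record the axial slice on which a nodule was
seen ("series 2, image 15"). When a radiologist re-reads a screening CT to
compare against prior findings, re-locating each previously reported nodule
is slow, even though that slice number is a quasi ground-truth label.
`nodulecad` implements a detection pipeline built around that prior
knowledge, tuned for very low false-positive rates rather than maximal
sensitivity:

1. **Preprocessing** — resample to isotropic 1 mm³ voxels, then build
   25 mm *overlapping* maximum intensity projections (MIP) along both the
   axial and the coronal axis. A thick MIP makes a spherical nodule stand
   out from tubular vessels; a vessel running along one projection axis can
   still mimic a nodule, but on that axis only — hence the dual-axis design.
2. **2D detection** — a pluggable contract: anything that emits per-slice
   bounding boxes with confidences (a neural detector run elsewhere, the
   built-in baseline blob detector, or the seeded detection simulator).
3. **Clustering** — raw inferences are lifted to world (x, y, z) mm,
   pre-filtered at confidence ≥ 0.1, and aggregated with DBSCAN
   (eps = 10 mm, minPts = 4). A cluster becomes a candidate with centroid =
   mean of member centres and bounding diameter = largest member box.
4. **False-positive reduction** — an XGBoost classifier (learning rate 0.05,
   depth 6, 200 estimators, scale_pos_weight 2.7, column/row subsampling
   0.6/0.8) over six cluster-metadata features: max/mean confidence,
   inference count, dual-axis presence, and distance to scan top/bottom.
   Its probability is the candidate's final nodule confidence.
5. **Slice-assisted selection** — candidates scoring < 0.20 are dropped; the
   remaining candidate closest in z to the reported slice position, within a
   10 mm (or 20 mm) window, is the final prediction.
6. **Evaluation** — precision, recall, FP/scan, *adjusted* variants (a hit
   on a real but unintended nodule counted as a false positive), and FROC
   curves swept over the final-score threshold.

A seeded synthetic phantom module (lung ellipsoid, vessels — including
perpendicular-vessel confounders — and nodules of several attenuation
classes) plus a detection-noise simulator make the entire pipeline runnable
and testable at desk scale with no external CT data.

## Worked example

Run the seeded end-to-end synthetic benchmark (50 training scans for the
reducer, 20 disjoint test scans, 2–4 nodules per scan, one slice query per
nodule):

```sh
nodulecad run-all --out-dir results/demo --seed 1234
```

prints

```json
{
  "precision": 1.0,
  "recall": 1.0,
  "fp_per_scan": 0.0
}
```

meaning every one of the 57 slice queries on the test cohort returned a
candidate within the hit criterion of a real synthetic nodule, and no scan
produced a false positive at the 0.20 score floor with a 10 mm window. The
output directory also contains the intermediate artifacts (`candidates.csv`,
`predictions.csv` with per-query outcomes, `froc.csv`, the serialized
reducer, and `metrics.json` with the adjusted variants).

The same stages are available individually (`phantom`, `preprocess`,
`detect`, `cluster`, `reduce-train`, `reduce-score`, `select`, `evaluate`)
and as library functions; see `docs/methods.md` for the underlying model and
its assumptions.

On synthetic phantoms the pipeline is near-perfect by construction — the
simulator's confounders are exactly the failure mode the reducer's features
target. These numbers characterize the pipeline's mechanics, not clinical
performance; see the limitations section of `docs/methods.md`.

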