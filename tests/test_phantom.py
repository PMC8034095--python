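import numpy as np
import pytest

from nodulecad.clustering import candidates_from_detections
from nodulecad.detectors import detect_blobs
from nodulecad.io import world_to_voxel
from nodulecad.phantom import (ATTENUATION_HU, DetectionNoiseModel,
                               PhantomNodule, PhantomSpec, generate_phantom,
                               sample_nodules, simulate_detections)
from nodulecad.preprocess import PreprocessConfig, build_mip_stack

NODULES = (
    PhantomNodule((100.0, 100.0, 100.0), 8.0, "soft_tissue"),
    PhantomNodule((70.0, 90.0, 130.0), 6.0, "ground_glass"),
    PhantomNodule((130.0, 110.0, 70.0), 10.0, "calcified"),
)


class TestGeneratePhantom:
    def test_annotations_echo_the_spec(self):
        spec = PhantomSpec(nodules=NODULES, noise_sigma_hu=0.0)
        _, anns = generate_phantom(spec)
        assert len(anns) == 3
        for ann, nod in zip(anns, NODULES):
            assert ann.center_mm == nod.center_mm
            assert ann.diameter_mm == nod.diameter_mm
            assert ann.attenuation == nod.attenuation

    def test_noiseless_nodule_center_has_class_hu(self):
        spec = PhantomSpec(nodules=NODULES, noise_sigma_hu=0.0, n_vessels=0)
        volume, _ = generate_phantom(spec)
        for nod in NODULES:
            zi, yi, xi = (int(round(v)) for v in world_to_voxel(volume, nod.center_mm))
            assert volume.voxels[zi, yi, xi] == ATTENUATION_HU[nod.attenuation]

    def test_lung_air_and_body_regions(self):
        spec = PhantomSpec(noise_sigma_hu=0.0, n_vessels=0)
        volume, _ = generate_phantom(spec)
        zi, yi, xi = (int(round(v)) for v in world_to_voxel(volume, spec.lung_center_mm))
        assert volume.voxels[zi, yi, xi] == spec.lung_hu
        assert volume.voxels[0, 0, 0] == spec.air_hu

    def test_seed_reproducibility(self):
        spec = PhantomSpec(nodules=NODULES, seed=42)
        v1, _ = generate_phantom(spec)
        v2, _ = generate_phantom(spec)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        v3, _ = generate_phantom(PhantomSpec(nodules=NODULES, seed=43))
        assert not np.array_equal(v1.voxels, v3.voxels)

    def test_nodule_outside_lung_rejected(self):
        spec = PhantomSpec(nodules=(PhantomNodule((5.0, 5.0, 5.0), 6.0),))
        with pytest.raises(ValueError, match="lung"):
            generate_phantom(spec)

    def test_overlapping_nodules_rejected(self):
        spec = PhantomSpec(nodules=(
            PhantomNodule((100.0, 100.0, 100.0), 10.0),
            PhantomNodule((104.0, 100.0, 100.0), 10.0),
        ))
        with pytest.raises(ValueError, match="overlap"):
            generate_phantom(spec)


class TestSimulateDetections:
    def geometry(self):
        return PhantomSpec(scan_id="s1", nodules=NODULES).geometry

    def annotations(self):
        spec = PhantomSpec(scan_id="s1", nodules=NODULES, noise_sigma_hu=0.0)
        return generate_phantom(spec)[1]

    def test_deterministic_given_seed(self):
        model = DetectionNoiseModel(seed=9)
        d1, f1 = simulate_detections(self.annotations(), self.geometry(), model)
        d2, f2 = simulate_detections(self.annotations(), self.geometry(), model)
        assert d1 == d2 and f1 == f2

    def test_all_rates_zero_gives_no_detections(self):
        model = DetectionNoiseModel(rate_per_mm=0.0, chain_rate_per_scan=0.0,
                                    scatter_rate_per_scan=0.0, seed=1)
        dets, fired = simulate_detections(self.annotations(), self.geometry(), model)
        assert dets == []
        assert fired == ["none"] * 3

    def test_dual_axis_nodules_recovered_by_clustering(self):
        model = DetectionNoiseModel(dual_axis_prob=1.0, chain_rate_per_scan=0.0,
                                    scatter_rate_per_scan=0.0, seed=3)
        anns = self.annotations()
        geometry = self.geometry()
        dets, fired = simulate_detections(anns, geometry, model)
        assert fired == ["both"] * 3
        cands = candidates_from_detections(dets, geometry)
        assert len(cands) == 3
        for ann in anns:
            dists = [np.linalg.norm(np.subtract(c.centroid_mm, ann.center_mm))
                     for c in cands]
            assert min(dists) < 10.0  # centroid within eps of the true centre
        for cand in cands:
            assert cand.features.has_both_axes

    def test_confounder_chains_are_single_axis(self):
        model = DetectionNoiseModel(rate_per_mm=0.0, chain_rate_per_scan=6.0,
                                    scatter_rate_per_scan=0.0, seed=5)
        dets, _ = simulate_detections([], self.geometry(), model)
        assert dets
        cands = candidates_from_detections(dets, self.geometry())
        for cand in cands:
            assert not cand.features.has_both_axes


class TestSampleNodules:
    def test_separation_and_containment(self):
        spec = PhantomSpec()
        rng = np.random.default_rng(0)
        nodules = sample_nodules(rng, spec, 3, min_separation_mm=40.0)
        assert len(nodules) == 3
        for i, a in enumerate(nodules):
            for b in nodules[i + 1:]:
                assert np.linalg.norm(np.subtract(a.center_mm, b.center_mm)) >= 40.0


class TestEndToEndRecovery:
    def test_dual_axis_queries_recovered(self, benchmark_run):
        """With default noise and fixed seeds, the full pipeline returns a
        candidate within the hit criterion for >= 90% of queries whose
        intended nodule fired on both MIP axes."""
        from nodulecad.evaluation import evaluate_queries
        run = benchmark_run
        dual_ids = {
            ann.nodule_id
            for scan in run.test_scans
            for ann, axes in zip(scan.annotations, scan.fired_axes)
            if axes == "both"
        }
        assert dual_ids
        _, outcomes, _ = evaluate_queries(run.candidates_by_scan, run.queries,
                                          run.annotations, min_score=0.20,
                                          window_mm=10.0)
        dual_outcomes = [o for q, o in zip(run.queries, outcomes)
                         if q.intended_nodule_id in dual_ids]
        hits = sum(o.startswith("tp") for o in dual_outcomes)
        assert hits / len(dual_outcomes) >= 0.90

    def test_recovered_centroids_close_to_truth(self, benchmark_run):
        run = benchmark_run
        ann_by_id = {a.nodule_id: a for a in run.annotations}
        from nodulecad.reduction import label_candidates
        flat = [c for cs in run.candidates_by_scan.values() for c in cs]
        labels, matched = label_candidates(flat, run.annotations)
        checked = 0
        for cand, lab, mid in zip(flat, labels, matched):
            if lab:
                ann = ann_by_id[mid]
                dev = np.linalg.norm(np.subtract(cand.centroid_mm, ann.center_mm))
                assert dev < 10.0
                checked += 1
        assert checked > 0


class TestBlobDetectorRoute:
    def test_rendered_phantom_through_blob_detector(self):
        """Slow path: render a phantom, MIP both axes, run the baseline blob
        detector, cluster — the nodule must come back as a dual-axis cluster."""
        nodule = PhantomNodule((60.0, 60.0, 60.0), 10.0, "soft_tissue")
        spec = PhantomSpec(shape_mm=(120.0, 120.0, 120.0),
                           spacing_mm=(2.0, 2.0, 2.0),
                           lung_center_mm=(60.0, 60.0, 60.0),
                           lung_semiaxes_mm=(60.0, 55.0, 58.0),
                           n_vessels=2, nodules=(nodule,),
                           noise_sigma_hu=5.0, seed=7, scan_id="p1")
        volume, anns = generate_phantom(spec)
        config = PreprocessConfig(voxel_mm=2.0, mip_window_mm=25.0)
        dets = []
        for axis in ("axial", "coronal"):
            stack = build_mip_stack(volume, axis, config)
            dets.extend(detect_blobs(stack, hu_threshold=-300.0,
                                     min_diameter_mm=4.0, max_diameter_mm=30.0))
        assert dets
        cands = candidates_from_detections(dets, volume.geometry)
        dists = [np.linalg.norm(np.subtract(c.centroid_mm, anns[0].center_mm))
                 for c in cands]
        assert min(dists) < 10.0
        best = cands[int(np.argmin(dists))]
        assert best.features.has_both_axes
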