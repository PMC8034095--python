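import numpy as np
import pytest

from conftest import make_detection3d
from nodulecad.clustering import (ClusteringConfig, ClusterFeatures,
                                  candidates_from_detections,
                                  cluster_detections, filter_low_confidence,
                                  lift_to_3d, summarize_cluster)
from nodulecad.io import Detection2D, ScanGeometry
from oracles import dbscan_bruteforce, partition_of

GEO = ScanGeometry(origin_mm=(0.0, 0.0, -100.0), extent_mm=(300.0, 300.0, 250.0),
                   scan_id="s1")


def labels_of(detections, clusters, noise):
    """Recover an integer label per input detection from the cluster lists."""
    index = {id(d): i for i, d in enumerate(detections)}
    labels = np.full(len(detections), -1, dtype=int)
    for c, members in enumerate(clusters):
        for m in members:
            labels[index[id(m)]] = c
    for m in noise:
        assert labels[index[id(m)]] == -1
    return labels


class TestLift:
    def test_axial_embedding(self):
        d = Detection2D("s1", "axial", 100.0, 30.0, 40.0, 5.0, 6.0, 0.5)
        (lifted,) = lift_to_3d([d])
        assert lifted.center_mm == (30.0, 40.0, 100.0)
        assert lifted.diameter_mm == 6.0

    def test_coronal_embedding(self):
        d = Detection2D("s1", "coronal", 60.0, 30.0, 100.0, 5.0, 4.0, 0.5)
        (lifted,) = lift_to_3d([d])
        assert lifted.center_mm == (30.0, 60.0, 100.0)

    def test_dual_axis_views_of_one_point_coincide(self):
        # the same world point seen on both stacks lifts to the same centre
        x, y, z = 42.0, 77.0, -13.0
        axial = Detection2D("s1", "axial", z, x, y, 5.0, 5.0, 0.5)
        coronal = Detection2D("s1", "coronal", y, x, z, 5.0, 5.0, 0.5)
        a, c = lift_to_3d([axial, coronal])
        assert np.allclose(a.center_mm, c.center_mm)


class TestConfidenceFilter:
    def test_boundary_kept(self):
        dets = make_detection3d([(0, 0, 0)] * 3)
        dets = [type(d)(d.source, d.center_mm, d.diameter_mm, conf, d.axis)
                for d, conf in zip(dets, (0.05, 0.1, 0.5))]
        kept = filter_low_confidence(dets)
        assert [d.confidence for d in kept] == [0.1, 0.5]

    def test_all_below_threshold(self):
        dets = make_detection3d([(0, 0, 0)] * 4, confidence=0.01)
        assert filter_low_confidence(dets) == []

    def test_zero_threshold_is_identity(self):
        dets = make_detection3d([(0, 0, 0)] * 4, confidence=0.01)
        cfg = ClusteringConfig(min_confidence=0.0)
        assert filter_low_confidence(dets, cfg) == dets


class TestDbscan:
    def test_three_close_points_are_noise(self):
        dets = make_detection3d([(0, 0, 0), (0.5, 0, 0), (0, 0.5, 0)])
        clusters, noise = cluster_detections(dets)
        assert clusters == []
        assert len(noise) == 3

    def test_five_close_points_form_one_cluster(self):
        pts = [(0, 0, 0), (0.5, 0, 0), (0, 0.5, 0), (0.3, 0.3, 0), (0, 0, 0.4)]
        dets = make_detection3d(pts)
        clusters, noise = cluster_detections(dets)
        assert len(clusters) == 1 and len(clusters[0]) == 5 and not noise
        oracle = dbscan_bruteforce(np.asarray(pts, float), 10.0, 4)
        assert partition_of(oracle) == partition_of(labels_of(dets, *cluster_detections(dets)))

    def test_two_separated_groups(self):
        rng = np.random.default_rng(4)
        a = rng.normal(scale=1.0, size=(6, 3))
        b = rng.normal(scale=1.0, size=(6, 3)) + [50.0, 0, 0]
        dets = make_detection3d(np.vstack([a, b]))
        clusters, noise = cluster_detections(dets)
        assert len(clusters) == 2 and not noise
        members = {frozenset(id(m) for m in c) for c in clusters}
        assert frozenset(id(d) for d in dets[:6]) in members
        assert frozenset(id(d) for d in dets[6:]) in members

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 120))
        # mixture of tight clumps and uniform scatter in a 300 mm cube
        clumps = [rng.uniform(0, 300, 3) + rng.normal(scale=3.0, size=(rng.integers(2, 12), 3))
                  for _ in range(rng.integers(1, 5))]
        pts = np.vstack(clumps + [rng.uniform(0, 300, (n, 3))])
        dets = make_detection3d(pts)
        got = labels_of(dets, *cluster_detections(dets))
        want = dbscan_bruteforce(pts, 10.0, 4)
        assert partition_of(got) == partition_of(want)

    def test_permutation_preserves_core_points_and_partition(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 60, (60, 3))
        dets = make_detection3d(pts)
        base = partition_of(labels_of(dets, *cluster_detections(dets)))
        perm = rng.permutation(60)
        dets_p = [dets[i] for i in perm]
        labels_p = labels_of(dets_p, *cluster_detections(dets_p))
        # map permuted labels back to original indexing
        unperm = np.empty(60, dtype=int)
        unperm[perm] = labels_p
        _, got_noise = partition_of(unperm)
        _, want_noise = base
        # the noise set (non-core, density-unreachable) is order-independent;
        # only border-point cluster assignment may legally move
        assert got_noise == want_noise

    def test_multiscan_input_rejected(self):
        a = make_detection3d([(0, 0, 0)], scan_id="s1")
        b = make_detection3d([(1, 0, 0)], scan_id="s2")
        with pytest.raises(ValueError, match="multiple scans"):
            cluster_detections(a + b)


class TestSummarize:
    def make_cluster(self, confs=(0.3, 0.9, 0.6, 0.6), diams=(4, 9, 6, 5),
                     axes=("axial", "axial", "axial", "axial")):
        dets = []
        for i, (c, d, ax) in enumerate(zip(confs, diams, axes)):
            src = Detection2D("s1", ax, 10.0 + i, 50.0, 60.0, float(d), float(d), c)
            dets.extend(lift_to_3d([src]))
        return dets

    def test_confidence_summary(self):
        cand = summarize_cluster(self.make_cluster(), GEO)
        assert cand.features.max_conf == 0.9
        assert cand.features.mean_conf == pytest.approx(0.6)
        assert cand.features.n_inferences == 4

    def test_bounding_diameter_is_max_member(self):
        cand = summarize_cluster(self.make_cluster(), GEO)
        assert cand.bounding_diameter_mm == 9.0

    def test_has_both_axes_flips_with_coronal_member(self):
        axial_only = summarize_cluster(self.make_cluster(), GEO)
        assert not axial_only.features.has_both_axes
        mixed = summarize_cluster(
            self.make_cluster(confs=(0.3, 0.9, 0.6, 0.6, 0.5),
                              diams=(4, 9, 6, 5, 5),
                              axes=("axial",) * 4 + ("coronal",)), GEO)
        assert mixed.features.has_both_axes

    def test_top_bottom_distances_sum_to_extent(self):
        cand = summarize_cluster(self.make_cluster(), GEO)
        f = cand.features
        assert f.dist_top_mm + f.dist_bottom_mm == pytest.approx(250.0, abs=1e-6)
        assert f.dist_bottom_mm == pytest.approx(cand.centroid_mm[2] - (-100.0))

    def test_centroid_inside_member_bounding_region(self):
        rng = np.random.default_rng(8)
        dets = make_detection3d(rng.uniform(0, 50, (10, 3)))
        cand = summarize_cluster(dets, GEO)
        centers = np.asarray([d.center_mm for d in dets])
        assert np.all(cand.centroid_mm >= centers.min(axis=0) - 1e-12)
        assert np.all(cand.centroid_mm <= centers.max(axis=0) + 1e-12)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cluster([], GEO)


def test_candidates_respect_min_samples():
    rng = np.random.default_rng(21)
    dets2d = []
    for _ in range(80):
        dets2d.append(Detection2D(
            "s1", "axial" if rng.random() < 0.5 else "coronal",
            float(rng.uniform(0, 150)), float(rng.uniform(0, 300)),
            float(rng.uniform(0, 300)), 5.0, 5.0, float(rng.uniform(0, 1))))
    cands = candidates_from_detections(dets2d, GEO)
    for cand in cands:
        assert cand.features.n_inferences >= ClusteringConfig().min_samples
        assert cand.score is None
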