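"""The standard synthetic benchmark: seeded multi-scan phantom studies.

Builds a reproducible study from the phantom simulator — a training cohort
for the false-positive reducer and a disjoint test cohort for evaluation —
and runs the full candidate pipeline on it.  Defaults: 50 training scans,
20 test scans, 2–4 nodules per scan, one slice query per nodule with a small
report-position error.  All randomness flows from a single study seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import ClusteringConfig, NoduleCandidate, candidates_from_detections
from .io import Detection2D, NoduleAnnotation, ScanGeometry
from .phantom import DetectionNoiseModel, PhantomSpec, sample_nodules, simulate_detections
from .reduction import (ReducerConfig, ReducerModel, label_candidates,
                        score_candidates, train_reducer)
from .selection import SliceQuery


@dataclass(frozen=True)
class ScanCase:
    """One synthetic scan: geometry, truth, simulated raw detections, and the
    report-style slice queries (one per nodule).  ``fired_axes[i]`` records
    on which MIP axes nodule i produced detections."""

    geometry: ScanGeometry
    annotations: tuple[NoduleAnnotation, ...]
    detections: tuple[Detection2D, ...]
    queries: tuple[SliceQuery, ...]
    fired_axes: tuple[str, ...]


@dataclass(frozen=True)
class BenchmarkConfig:
    n_train_scans: int = 50
    n_test_scans: int = 20
    nodules_per_scan: tuple[int, int] = (2, 4)   # inclusive range
    query_z_error_mm: float = 2.0                # report slice-position error
    window_mm: float = 10.0
    min_score: float = 0.20
    seed: int = 0


def _make_scan(rng: np.random.Generator, scan_id: str,
               config: BenchmarkConfig) -> ScanCase:
    spec = PhantomSpec(scan_id=scan_id, shape_mm=(300.0, 300.0, 280.0),
                       lung_center_mm=(150.0, 150.0, 140.0),
                       lung_semiaxes_mm=(120.0, 100.0, 120.0))
    n_nodules = int(rng.integers(config.nodules_per_scan[0],
                                 config.nodules_per_scan[1] + 1))
    nodules = sample_nodules(rng, spec, n_nodules)
    annotations = tuple(
        NoduleAnnotation(nodule_id=f"{scan_id}-n{i}", scan_id=scan_id,
                         center_mm=n.center_mm, diameter_mm=n.diameter_mm,
                         attenuation=n.attenuation)
        for i, n in enumerate(nodules)
    )
    noise = DetectionNoiseModel(seed=int(rng.integers(0, 2**31 - 1)))
    detections, fired = simulate_detections(annotations, spec.geometry, noise)
    queries = tuple(
        SliceQuery(
            scan_id=scan_id,
            target_z_mm=ann.center_mm[2] + float(rng.uniform(
                -config.query_z_error_mm, config.query_z_error_mm)),
            intended_nodule_id=ann.nodule_id,
            window_mm=config.window_mm,
            min_score=config.min_score,
        )
        for ann in annotations
    )
    return ScanCase(geometry=spec.geometry, annotations=annotations,
                    detections=tuple(detections), queries=queries,
                    fired_axes=tuple(fired))


def make_cohort(n_scans: int, seed: int, config: BenchmarkConfig,
                prefix: str) -> list[ScanCase]:
    """Generate ``n_scans`` independent synthetic scans from one seed."""
    rng = np.random.default_rng(seed)
    return [_make_scan(rng, f"{prefix}{i:03d}", config) for i in range(n_scans)]


def cluster_cohort(
    scans: Sequence[ScanCase],
    clustering: ClusteringConfig | None = None,
) -> dict[str, list[NoduleCandidate]]:
    """Run lift/filter/DBSCAN/summarize on every scan of a cohort."""
    clustering = clustering or ClusteringConfig()
    out: dict[str, list[NoduleCandidate]] = {}
    next_id = 0
    for scan in scans:
        cands = candidates_from_detections(scan.detections, scan.geometry,
                                           clustering, first_candidate_id=next_id)
        next_id += len(cands)
        out[scan.geometry.scan_id] = cands
    return out


@dataclass
class BenchmarkRun:
    config: BenchmarkConfig
    train_scans: list[ScanCase]
    test_scans: list[ScanCase]
    model: ReducerModel
    candidates_by_scan: dict[str, list[NoduleCandidate]]  # test cohort, scored
    queries: list[SliceQuery]
    annotations: list[NoduleAnnotation]

    @property
    def confounder_candidates(self) -> list[NoduleCandidate]:
        labels, _ = label_candidates(
            [c for cs in self.candidates_by_scan.values() for c in cs],
            self.annotations)
        flat = [c for cs in self.candidates_by_scan.values() for c in cs]
        return [c for c, lab in zip(flat, labels) if not lab]

    @property
    def true_candidates(self) -> list[NoduleCandidate]:
        flat = [c for cs in self.candidates_by_scan.values() for c in cs]
        labels, _ = label_candidates(flat, self.annotations)
        return [c for c, lab in zip(flat, labels) if lab]


def run_benchmark(config: BenchmarkConfig | None = None) -> BenchmarkRun:
    """Generate cohorts, train the reducer on the training cohort with
    automatic distance labels, and score the test cohort's candidates.

    Train and test cohorts use disjoint seeds derived from the study seed.
    """
    config = config or BenchmarkConfig()
    train_seed = (config.seed * 2 + 1) % (2**31 - 1)
    test_seed = (config.seed * 2 + 2) % (2**31 - 1)
    train_scans = make_cohort(config.n_train_scans, train_seed, config, "train")
    test_scans = make_cohort(config.n_test_scans, test_seed, config, "test")

    train_cands_by_scan = cluster_cohort(train_scans)
    train_cands = [c for cs in train_cands_by_scan.values() for c in cs]
    train_annotations = [a for s in train_scans for a in s.annotations]
    labels, _ = label_candidates(train_cands, train_annotations)
    model = train_reducer(train_cands, labels,
                          ReducerConfig(seed=config.seed % (2**31 - 1)))

    test_cands_by_scan = cluster_cohort(test_scans)
    scored = {
        scan_id: score_candidates(model, cands)
        for scan_id, cands in test_cands_by_scan.items()
    }
    return BenchmarkRun(
        config=config,
        train_scans=train_scans,
        test_scans=test_scans,
        model=model,
        candidates_by_scan=scored,
        queries=[q for s in test_scans for q in s.queries],
        annotations=[a for s in test_scans for a in s.annotations],
    )
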