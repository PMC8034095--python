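import numpy as np
import pytest

from nodulecad.benchmark import BenchmarkConfig, run_benchmark
from nodulecad.clustering import Detection3D
from nodulecad.io import Detection2D

#: Study seed for the standard synthetic benchmark used across the suite.
BENCHMARK_SEED = 1234


def make_detection3d(points, scan_id="s1", confidence=0.5, diameter=6.0,
                     axis="axial"):
    """Wrap raw (x, y, z) points as Detection3D records for clustering tests."""
    dets = []
    for x, y, z in np.asarray(points, dtype=float):
        src = Detection2D(scan_id=scan_id, axis=axis, slice_pos_mm=float(z),
                          center_u_mm=float(x), center_v_mm=float(y),
                          width_mm=diameter, height_mm=diameter,
                          confidence=confidence)
        dets.append(Detection3D(source=src, center_mm=(float(x), float(y), float(z)),
                                diameter_mm=diameter, confidence=confidence,
                                axis=axis))
    return dets


@pytest.fixture(scope="session")
def benchmark_run():
    """The standard synthetic benchmark at the fixed study seed: 50 training
    scans for the reducer, 20 disjoint test scans with scored candidates."""
    return run_benchmark(BenchmarkConfig(seed=BENCHMARK_SEED))
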