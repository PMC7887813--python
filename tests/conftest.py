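"""Shared fixtures: synthetic benchmark images and their segmentations.

The benchmark set mirrors the evaluation design of the segmentation method:
7 fields of view from different simulated subjects, >= 150 cells in total,
moderate noise, 20% detached processes.
"""

import numpy as np
import pytest

from gliaquant import segmentation as seg
from gliaquant import synthetic as syn


def make_benchmark_image(seed: int, n_cells: int = 22, n_vessels: int = 0):
    rng = np.random.default_rng(seed)
    specs = syn.default_cell_specs(n_cells, rng, detach_probability=0.2)
    return syn.generate_image(
        (384, 384),
        specs,
        n_plaques=2,
        n_vessels=n_vessels,
        noise_sd=syn.DEFAULT_NOISE_SD,
        seed=seed,
        subject_id=f"SYN{seed}",
    )


@pytest.fixture(scope="session")
def benchmark_set():
    """7 synthetic fields (154 cells total), one with a vessel in frame."""
    return [make_benchmark_image(100 + s, n_vessels=(1 if s % 3 == 0 else 0)) for s in range(7)]


@pytest.fixture(scope="session")
def benchmark_results(benchmark_set):
    """Full staged segmentation of every benchmark field."""
    out = []
    for image, truth in benchmark_set:
        cells, plaques, vessels = seg.segment_image(image)
        out.append((image, truth, cells, plaques, vessels))
    return out
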