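import dataclasses

import numpy as np
import pytest

from wsimil import experiments as ex
from wsimil.synthetic import SynthParams
from wsimil.tiling import GridSpec


@pytest.fixture(scope="session")
def tiny_params() -> SynthParams:
    """A 12-scan cohort of small scans; fast enough to regenerate freely."""
    return SynthParams(
        seed=7,
        n_patients=6,
        scans_per_patient=2,
        scan_width_range=(320, 448),
        scan_height_range=(320, 448),
    )


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    return GridSpec(patch_size=128, overlap=0.25, resize_to=32)


@pytest.fixture(scope="session")
def artifact_model(tiny_params, tiny_grid):
    """Artifact/background QC CNN trained on the tiny cohort."""
    return ex.train_artifact_filter_on_cohort(tiny_params, tiny_grid, n_scans=12, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_params, tiny_grid, artifact_model):
    """(patches, manifest, qc_reports) for the tiny cohort after full QC."""
    return ex.build_patch_dataset(
        tiny_params, tiny_grid, artifact_model=artifact_model, keep_masks=True
    )


def make_texture_patches(rng: np.random.Generator, n: int, kind: str, size: int = 32) -> np.ndarray:
    """Separable-by-construction patch fixtures.

    ``plain``: smooth pink tissue; ``spots``: the same tissue carrying a
    dense dark-spot texture (witness-like); ``pen``: saturated marker ink.
    """
    out = np.zeros((n, size, size, 3), dtype=np.uint8)
    base = np.array([198, 152, 188], dtype=np.float64)
    for i in range(n):
        img = base + rng.normal(0, 6, size=(size, size, 3))
        if kind == "spots":
            mask = rng.random((size, size)) < 0.2
            img[mask] = [96, 58, 120]
        elif kind == "pen":
            img[:] = [12, 120, 45] + rng.normal(0, 4, size=(size, size, 3))
        out[i] = np.clip(img, 0, 255).astype(np.uint8)
    return out
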