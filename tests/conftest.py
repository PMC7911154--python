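"""Shared fixtures: small phantoms and cheap synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from metpet import PhantomSpec, ReferenceROI, generate_phantom, reference_suvmean, segment_tumor, to_suv
from metpet.phantom import default_reference_center


#: Small phantom used by Monte-Carlo texture tests: 48³ @ 2 mm, ~16 mm tumor.
SMALL_KW = dict(
    grid_shape=(48, 48, 48),
    voxel_spacing=(2.0, 2.0, 2.0),
    tumor_center=(24, 24, 14),
    tumor_radii=(20.0, 18.0, 18.0),
)


def make_small_spec(**kw) -> PhantomSpec:
    merged = {**SMALL_KW, **kw}
    return PhantomSpec(**merged)


def segment_phantom(spec: PhantomSpec):
    """Render, convert to SUV, and delineate; returns (suv, seg)."""
    vol, _ = generate_phantom(spec)
    suv = to_suv(vol, spec.dose_info)
    ref = reference_suvmean(suv, ReferenceROI(center=default_reference_center(spec)))
    return suv, segment_tumor(suv, ref)


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec(seed=7)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def default_segmentation(default_phantom):
    spec, vol, _ = default_phantom
    suv = to_suv(vol, spec.dose_info)
    ref = reference_suvmean(suv, ReferenceROI(center=default_reference_center(spec)))
    return suv, segment_tumor(suv, ref)


def random_quantized(rng: np.random.Generator, max_side: int = 6, g_max: int = 4):
    """Random small masked level grid for oracle-equivalence checks."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    g = int(rng.integers(2, g_max + 1))
    levels = rng.integers(1, g + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    # ensure a usable region: at least 2 in-mask voxels with a neighbor pair
    if mask.sum() < 4:
        mask[:2, 0, 0] = True
    return levels, mask, g
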