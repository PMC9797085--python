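import numpy as np
import pytest

from tunel3d import apoptosis, nuclei_seg, poe3d
from tunel3d.io_stacks import SegConfig
from tunel3d.synthetic_data import StackSimParams, generate_stack


@pytest.fixture(scope="session")
def iso_config() -> SegConfig:
    """Isotropic unit-voxel config with permissive POE criteria for small images."""
    return SegConfig(
        min_diameter_um=2.0,
        max_diameter_um=20.0,
        min_fit_score=0.3,
        voxel_size=(1.0, 1.0, 1.0),
    )


@pytest.fixture(scope="session")
def default_stack():
    """One default-condition synthetic stack, shared across tests."""
    return generate_stack(StackSimParams(n_nuclei=36, apoptotic_fraction=0.12, seed=3))


@pytest.fixture(scope="session")
def segmented_default_stack(default_stack):
    """The shared stack pushed through the full segmentation pipeline."""
    stack, truth = default_stack
    config = SegConfig(voxel_size=stack.voxel_size)
    nuclei = nuclei_seg.segment_nuclei(stack.channel("DAPI"), config, stack.voxel_size)
    tunel = poe3d.iterative_poe_segment(stack.channel("TUNEL"), config, stack.voxel_size)
    area = apoptosis.blastocyst_area(nuclei, config)
    return stack, truth, config, nuclei, tunel, area


def smooth_quantized_image(rng: np.random.Generator, shape, n_levels: int) -> np.ndarray:
    """Random blobby test image with at most ``n_levels`` grey levels."""
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.random(shape), 2.0)
    img = (img - img.min()) / (img.max() - img.min() + 1e-12)
    return (img * (n_levels - 1)).round().astype(np.uint8)
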