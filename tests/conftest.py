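import numpy as np
import pytest

from sipbiofilm.ion_stack_io import sum_planes
from sipbiofilm.enrichment import enrichment_maps
from sipbiofilm.synthetic_scene import SceneSpec, default_profiles, simulate_stack


@pytest.fixture(scope="session")
def small_scene():
    """A 128x128 single-filament scene with 12 cocci, fully rendered."""
    spec = SceneSpec(image_height_px=128, image_width_px=128, seed=11,
                     n_filaments=1, n_cocci=12, condition_tag="NO3_only")
    truth, stack = simulate_stack(spec)
    return spec, truth, stack


@pytest.fixture(scope="session")
def small_summed(small_scene):
    _, _, stack = small_scene
    return sum_planes(stack)


@pytest.fixture(scope="session")
def small_enrich(small_summed):
    return enrichment_maps(small_summed)


@pytest.fixture(scope="session")
def no3_profiles():
    return default_profiles("NO3_only")
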