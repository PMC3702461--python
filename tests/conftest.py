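import numpy as np
import pytest

from pction import FeatureSpec, air_mask, default_scene, render_volumes
from pction.pipeline import Sample


def make_sample(seed: int, **scene_kwargs) -> Sample:
    scene = default_scene(seed, **scene_kwargs)
    rendered = render_volumes(scene)
    return Sample(mr=rendered.mr, ct=rendered.ct, mask=air_mask(rendered.ct),
                  name=f"scene{seed}")


@pytest.fixture(scope="session")
def noiseless_samples() -> list[Sample]:
    """Three noiseless, bias-free default scenes for cross-validation."""
    return [make_sample(seed) for seed in (1, 2, 3)]


@pytest.fixture(scope="session")
def best_spec() -> FeatureSpec:
    """The strongest reported contrast/feature combination (p = 7)."""
    return FeatureSpec(contrasts=("TSE1", "UTE2"), box_sd=True, dist_center=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
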