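import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from lake_tsi.indices import get_sensor
from lake_tsi.synthetic import LakeSpec, SceneRecipe, simulate_scene


@pytest.fixture(scope="session")
def oli():
    return get_sensor("OLI")


@pytest.fixture(scope="session")
def tm():
    return get_sensor("TM")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def three_lake_recipe(shape=(256, 256), noise_sd=0.0, cloud_fraction=0.05, seed=7):
    """One scene holding an algal, a turbid and a clear lake, with scum,
    vegetation and cloud contamination."""
    return SceneRecipe(
        shape=shape,
        lakes=(
            LakeSpec(
                "L1", (64, 64), (40, 45),
                fractions={"type1": 0.8, "scum": 0.1, "vegetation": 0.1},
                tsi_range={1: (55.0, 75.0)},
            ),
            LakeSpec("L2", (64, 190), (40, 40), fractions={"type2": 1.0},
                     tsi_range={2: (45.0, 60.0)}),
            LakeSpec("L3", (190, 128), (45, 55), fractions={"type3": 1.0},
                     tsi_range={3: (18.0, 28.0)}),
        ),
        noise_sd=noise_sd,
        cloud_fraction=cloud_fraction,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free three-lake scene with its ground truth (session-cached)."""
    return simulate_scene(three_lake_recipe())
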