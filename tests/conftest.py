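import numpy as np
import pytest

import trunknav as tn
from trunknav import descent_sim as ds
from trunknav.synthetic_world import BASE_CAMERA_OFFSET


@pytest.fixture(scope="session")
def foraging_scene():
    """The default foraging-tree scene (focal tree at origin, nest 3 m away)."""
    return tn.build_scene(tn.default_scene_config())


@pytest.fixture(scope="session")
def nest_scene_blocked():
    """Nest-tree scene with the blocking screen."""
    return tn.build_scene(tn.nest_tree_scene_config(include_screen=True))


@pytest.fixture(scope="session")
def foraging_memory(foraging_scene):
    """Single base view (nest side, ground level) on the foraging tree."""
    return ds.acquire_memory(foraging_scene, "foraging")


@pytest.fixture(scope="session")
def foraging_cache(foraging_scene, foraging_memory):
    """Shared probe cache for all foraging-tree simulations in the suite."""
    return ds.ProbeCache(foraging_scene, "foraging", foraging_memory)


@pytest.fixture(scope="session")
def nest_memory(nest_scene_blocked):
    return ds.acquire_memory(nest_scene_blocked.without_screen(), "nest_tree")


@pytest.fixture(scope="session")
def nest_cache_blocked(nest_scene_blocked, nest_memory):
    return ds.ProbeCache(nest_scene_blocked, "nest_tree", nest_memory)


@pytest.fixture(scope="session")
def analysis_views(foraging_scene):
    """The image-analysis grid: ground-level base reference (camera offset)
    plus 4 directions x 2 heights on the trunk."""
    views = {
        "base": tn.render_panorama(
            foraging_scene,
            tn.trunk_viewpoint(
                foraging_scene, "foraging", 0.0, 0.0, offset=BASE_CAMERA_OFFSET
            ),
        )
    }
    for az in (0.0, 90.0, 180.0, 270.0):
        for h in (1.0, 1.75):
            views[(az, h)] = tn.render_panorama(
                foraging_scene,
                tn.trunk_viewpoint(foraging_scene, "foraging", az, h),
            )
    return views


@pytest.fixture
def random_panorama():
    def make(seed=0):
        rng = np.random.default_rng(seed)
        return tn.Panorama(rng.integers(0, 256, size=(117, 360)).astype(float))

    return make
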