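import dataclasses

import numpy as np
import pytest

from archseg import fusion, hough, pipeline, scenes
from archseg.denoise import Neighborhood, median_filter, wiener_filter


@pytest.fixture(scope="session")
def default_config():
    return pipeline.validate_config({})


@pytest.fixture(scope="session")
def default_truth(default_config):
    return scenes.build_height_map(default_config.scene)


@pytest.fixture(scope="session")
def default_processed(default_config, default_truth):
    """Fused + denoised default scene and its detected circles."""
    captures = scenes.render_standard_set(default_truth)
    fused = fusion.fuse_standard_set(captures)
    hp = default_config.hough
    work = wiener_filter(fused, Neighborhood(3, 3))
    work = median_filter(work, Neighborhood(3, 3))
    circles = hough.detect_circles(
        work, hp.r_min, hp.r_max, hp.grad_threshold, hp.max_circles, hp.min_center_sep
    )
    return work, circles


@pytest.fixture(scope="session")
def default_run(default_config):
    """One full pipeline execution on the default synthetic scene."""
    return pipeline.run_pipeline(default_config)


@pytest.fixture(scope="session")
def small_scene_spec():
    """A four-tooth scene that keeps end-to-end tests fast."""
    return dataclasses.replace(
        scenes.SceneSpec(),
        image_shape=(192, 256),
        n_bodies_per_side=2,
        body_radii=(14.0, 16.0),
    )


def make_disc(shape, center, radius):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
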