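import numpy as np
import pytest

import cassdetect as cd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic textured scene with a weak disk contour."""
    spec = cd.SceneSpec(size=(96, 96), seed=7)
    img, gt = cd.generate_scene(spec)
    return img, gt, spec


@pytest.fixture(scope="session")
def scene_fields(small_scene):
    """Gradient, kernels and diagnostics for the shared scene."""
    img, gt, _ = small_scene
    grad = cd.scale_gradient(img.pixels, 1.0)
    kernels = cd.build_distance_weights(1.0)
    diag = cd.diagnostics(img.pixels, grad)
    return img, gt, grad, kernels, diag
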