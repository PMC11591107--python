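import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stemopt import (
    OptimizationProblem,
    StemLengthEvaluator,
    daily_activity_cases,
    optimize_stem_length,
)
from stemopt.phantom import LabeledImage, PhantomParams, generate_femur_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: quick test-scale phantom: 2 mm pixels need a thicker shell to stay resolved
COARSE_PARAMS = PhantomParams(shell_head_mm=4.0, shell_shaft_mm=6.0)
COARSE_PX = 2.0


def make_strip(nr: int, nc: int, label: int = 1, rho: float = 0.5,
               pixel_size: float = 1.0) -> LabeledImage:
    """Homogeneous rectangular test image (all one region label)."""
    labels = np.full((nr, nc), label, dtype=np.uint8)
    density = np.full((nr, nc), rho)
    return LabeledImage(labels, density, pixel_size)


@pytest.fixture(scope="session")
def coarse_image():
    return generate_femur_phantom(COARSE_PARAMS, COARSE_PX)


@pytest.fixture(scope="session")
def coarse_evaluator(coarse_image):
    return StemLengthEvaluator(coarse_image, daily_activity_cases())


@pytest.fixture(scope="session")
def default_run():
    """Full-resolution (0.5 mm) end-to-end optimization, run once."""
    image = generate_femur_phantom(PhantomParams(), 0.5)
    problem = OptimizationProblem(grid_step=0.5, stop_interval=1.5)
    length, best, trace, evaluator = optimize_stem_length(
        image, daily_activity_cases(), problem)
    return {
        "image": image,
        "problem": problem,
        "length": length,
        "best": best,
        "trace": trace,
        "evaluator": evaluator,
    }
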