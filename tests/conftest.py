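import numpy as np
import pytest

from dermfractal import (
    CohortClass,
    CohortSpec,
    FractalSpec,
    make_cohort,
    make_fractal_mask,
)


@pytest.fixture(scope="session")
def carpet5():
    """Level-5 Sierpinski carpet (243x243, 8^5 foreground pixels)."""
    return make_fractal_mask(FractalSpec("sierpinski_carpet", 5))


@pytest.fixture(scope="session")
def two_class_cohort():
    """Melanoma-like vs non-melanoma-like cohort at desk scale."""
    spec = CohortSpec(
        classes=(
            CohortClass("non-metastatic melanoma", 400, 1.755),
            CohortClass("nevus", 1200, 1.651),
        ),
        seed=11,
    )
    return make_cohort(spec)


def random_mask(rng: np.random.Generator, side: int = 64, p: float = 0.3):
    from dermfractal import BinaryMask

    pixels = rng.random((side, side)) < p
    if not pixels.any():
        pixels[side // 2, side // 2] = True
    return BinaryMask(pixels)
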