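import numpy as np
import pytest

from jawscape import (
    Outline,
    SyntheticJawParams,
    generate_jaw_outline,
    standardize_area,
    triangulate,
)


@pytest.fixture(scope="session")
def unit_square():
    return Outline(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture(scope="session")
def circle600():
    t = np.linspace(0.0, 2.0 * np.pi, 600, endpoint=False)
    return Outline(np.column_stack([2.0 * np.cos(t), 2.0 * np.sin(t)]))


@pytest.fixture(scope="session")
def jaw_outline():
    """A representative smooth synthetic jaw, unit area, canonical frame."""
    params = SyntheticJawParams(
        length_depth_ratio=4.0, dorsal_curvature=0.2, taper=0.3, roughness=0.01, n_points=600
    )
    return standardize_area(generate_jaw_outline(params, seed=1))


@pytest.fixture(scope="session")
def jaw_mesh(jaw_outline):
    return triangulate(jaw_outline, target_elements=800)


@pytest.fixture(scope="session")
def jaw_family():
    """Five jaws spanning the ratio/curvature axes (for convergence suites)."""
    specs = [
        (3.0, -0.3, 0.2), (3.5, 0.0, 0.3), (4.0, 0.3, 0.3),
        (5.0, -0.15, 0.4), (6.0, 0.15, 0.25),
    ]
    return [
        standardize_area(
            generate_jaw_outline(
                SyntheticJawParams(r, c, t, 0.005, 600), seed=10 + i
            )
        )
        for i, (r, c, t) in enumerate(specs)
    ]
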