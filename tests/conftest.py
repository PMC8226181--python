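import numpy as np
import pytest

from dbsdeform import (
    make_ground_truth_curve,
    rasterize_case,
)


@pytest.fixture(scope="session")
def straight_case():
    """Straight 70 mm non-directional electrode at scanner voxel size."""
    curve = make_ground_truth_curve("non_directional", "left", (0.0, 0.0, 0.0), 70.0, seed=0)
    return rasterize_case(curve, seed=0)


@pytest.fixture(scope="session")
def bent_case():
    """Gently bowed electrode with mm-scale deviations on all axes."""
    curve = make_ground_truth_curve(
        "directional", "right", (0.8, -0.5, 0.3), 68.0, seed=11
    )
    return rasterize_case(curve, seed=11)


@pytest.fixture(scope="session")
def two_electrode_case():
    """Bilateral case: one lead per hemisphere inside a bone shell."""
    left = make_ground_truth_curve("non_directional", "left", (0.3, 0.2, -0.1), 70.0, seed=1)
    right = make_ground_truth_curve("non_directional", "right", (0.2, -0.3, 0.1), 68.0, seed=2)
    return rasterize_case([left, right], seed=3)


def cumulative_chord(points: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])
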