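import numpy as np
import pytest

from oliveshape import geometry
from oliveshape.synth import generate_cohort, get_preset


def ellipse_points(a: float, b: float, n: int = 4096, angle: float = 0.0) -> np.ndarray:
    """Exact ellipse boundary samples (vertical semi-axis a), rotated by angle."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([b * np.cos(t), a * np.sin(t)])
    c, s = np.cos(angle), np.sin(angle)
    return pts @ np.array([[c, s], [-s, c]])


def ellipse_contour(a: float, b: float, n_points: int = 512) -> geometry.Contour:
    return geometry.normalize_points(ellipse_points(a, b), mm_per_px=0.05, n_points=n_points)


@pytest.fixture(scope="session")
def separable3_cohort():
    """Small two-year separable cohort shared across classifier tests."""
    return generate_cohort(
        get_preset("separable3"), n_per_organ=10, years=(1, 2), seed=0, mode="fast"
    )


@pytest.fixture(scope="session")
def separable3_joint(separable3_cohort):
    from oliveshape.classify import pair_organs

    c = separable3_cohort
    return pair_organs(c.fruit, c.leaf, c.endocarp, seed=0)
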