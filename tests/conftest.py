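import numpy as np
import pytest

from elasticshapes import (
    NuisanceSpec,
    Outline,
    make_dataset,
    make_families,
)

#: reference nuisance condition: arbitrary orientation/scale/position,
#: random start vertex, moderate smooth reparametrization, mild vertex noise
MODERATE_NUISANCE = NuisanceSpec(
    rotation_range=2 * np.pi,
    scale_range=(0.8, 1.25),
    translation_range=0.5,
    start_shift=True,
    reparam_strength=0.3,
    vertex_noise_sd=0.01,
)


def circle_outline(n: int = 120, radius: float = 1.0, closed: bool = True) -> Outline:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline(
        np.column_stack([radius * np.cos(t), radius * np.sin(t)]),
        closed=closed,
        object_id=f"circle_r{radius}",
    )


def ellipse_outline(a: float, b: float = 1.0, n: int = 120) -> Outline:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline(
        np.column_stack([a * np.cos(t), b * np.sin(t)]),
        object_id=f"ellipse_{a}_{b}",
    )


@pytest.fixture(scope="session")
def families():
    return make_families(5, separation=0.25, seed=7)


@pytest.fixture(scope="session")
def small_dataset(families):
    """5 classes x 6 members under the reference nuisance condition."""
    return make_dataset(families, MODERATE_NUISANCE, n_per_class=6, n_points=100, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
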