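import numpy as np
import pytest

from morphdrift.morphio import LandmarkTemplate, ShapeDataset, SpecimenRecord
from morphdrift.synthgen import SyntheticShapeConfig, make_template, simulate_shapes


@pytest.fixture(scope="session")
def small_template():
    """3 bilateral pairs + 4 midline landmarks = 10 landmarks."""
    template, base = make_template(n_pairs=3, n_midline=4, seed=11)
    return template, base


@pytest.fixture(scope="session")
def cranium_like_template():
    """19 pairs + 5 midline = the cranium landmark count (43)."""
    template, base = make_template(n_pairs=19, n_midline=5, seed=7)
    return template, base


@pytest.fixture()
def small_dataset(small_template):
    template, base = small_template
    config = SyntheticShapeConfig(
        template=template,
        base_shape=base,
        n_per_group={("1890s", "F"): 3, ("1890s", "M"): 3, ("2010s", "F"): 3, ("2010s", "M"): 3},
        individual_sd=0.2,
        digitizing_sd=0.02,
        seed=42,
    )
    return simulate_shapes(config)


def random_configuration(rng: np.random.Generator, p: int = 6, scale: float = 10.0) -> np.ndarray:
    """Well-conditioned random landmark configuration."""
    return rng.uniform(-scale, scale, size=(p, 3))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random proper rotation matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
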