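import numpy as np
import pytest

from stereovol.phantom import Phantom, PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def default_phantom() -> Phantom:
    """The default 500-cell scaled layer used across estimator tests."""
    return generate_phantom(PhantomParams(), seed=1)


@pytest.fixture(scope="session")
def mono_phantom() -> Phantom:
    """Monodisperse spheres with centred nucleoli (exact-value cases)."""
    return generate_phantom(PhantomParams(n_cells=120, somal_cv=0.0), seed=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def single_cell_phantom(
    center=(50.0, 50.0, 50.0),
    semi_axes=(5.0, 5.0, 5.0),
    region=(100.0, 100.0, 100.0),
    nucleolus=None,
) -> Phantom:
    """Hand-built one-cell phantom for geometry edge cases."""
    c = np.asarray([center], dtype=float)
    s = np.asarray([semi_axes], dtype=float)
    n = c.copy() if nucleolus is None else np.asarray([nucleolus], dtype=float)
    return Phantom(
        region_size_um=tuple(region),
        centers=c,
        semi_axes=s,
        nucleoli=n,
        seed=None,
        periodic_lateral=False,
    )
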