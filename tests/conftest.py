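import numpy as np
import pytest

from wellcyto.synthetic import SyntheticPopulation, SyntheticWellSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(
    n_cells=20,
    diameter=300,
    seed=0,
    stains=("nuclear",),
    noise_sd=0.0,
    vignette=0.0,
    ring=0.0,
    max_place_attempts=500,
    **pop_kwargs,
):
    """Compact single-population well spec for unit tests."""
    return SyntheticWellSpec(
        well_diameter_px=diameter,
        tile_size_px=diameter,
        max_place_attempts=max_place_attempts,
        populations=(
            SyntheticPopulation(
                name="cells", n_cells=n_cells, stain_channels=tuple(stains), **pop_kwargs
            ),
        ),
        vignette_strength=vignette,
        edge_ring_amplitude=ring,
        gaussian_sd=noise_sd,
        rng_seed=seed,
    )


@pytest.fixture
def clean_spec():
    return small_spec()
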