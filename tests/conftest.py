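import numpy as np
import pytest

from mpq.synthetic import (
    ACTIVIN_PRESETS,
    NEURULOID_PRESETS,
    NoiseParams,
    assign_activation,
    generate_colony_layout,
    render_colony_image,
    render_neuruloid_image,
)

# Unit-test colonies use a scaled-down geometry (240 µm pattern, ~300
# nuclei) so each render/segment cycle stays fast; full 500 µm colonies are
# exercised in the acceptance tests.
# ~420 nuclei in a 120 µm disc matches the areal density of the default
# 1800-nuclei / 250 µm colony (confluent hESC packing)
SMALL_RADIUS = 120.0
SMALL_COUNT = 420


@pytest.fixture(scope="session")
def small_layout():
    return generate_colony_layout(SMALL_RADIUS, SMALL_COUNT, 8.0, seed=11)


@pytest.fixture(scope="session")
def wt_sample(small_layout):
    """Small WT colony with default noise."""
    pheno = ACTIVIN_PRESETS["WT"]
    act = assign_activation(small_layout, pheno, seed=12)
    return render_colony_image(small_layout, act, pheno, seed=13)


@pytest.fixture(scope="session")
def noiseless_sample(small_layout):
    """Small half-activated colony with noise disabled (exact intensities)."""
    from dataclasses import replace

    pheno = replace(ACTIVIN_PRESETS["HET"], patchiness=0.0, noise=NoiseParams.off())
    act = assign_activation(small_layout, pheno, seed=21)
    sample = render_colony_image(small_layout, act, pheno, seed=22)
    return sample, act, pheno


@pytest.fixture(scope="session")
def neuruloid_sample():
    return render_neuruloid_image(NEURULOID_PRESETS["WT"], pixel_size=1.0, seed=31)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
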