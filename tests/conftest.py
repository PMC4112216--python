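import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wallnet.datasets import PlantedDesign, TraitLink, generate_expression, generate_traits

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design():
    """Three planted modules of 60 genes plus 40 noise genes, 29 samples."""
    return PlantedDesign(
        n_samples=29,
        module_sizes=(60, 60, 60),
        n_noise_genes=40,
        noise_sd=0.5,
        seed=7,
        trait_links=(
            TraitLink("cellulose", 1, 1.0, 0.3, "% dry matter", target_range=(0.29, 31.33)),
            TraitLink("Xyl", 1, 1.0, 0.3, "mg/g", target_range=(3.49, 245.82)),
            TraitLink("Ara", 2, 1.0, 0.3, "mg/g", target_range=(3.26, 41.07)),
        ),
    )


@pytest.fixture(scope="session")
def small_data(small_design):
    expr, truth = generate_expression(small_design)
    traits = generate_traits(truth, small_design)
    return expr, truth, traits


@pytest.fixture(scope="session")
def default_design():
    """The reference study conditions: 5x100 planted + 200 noise, 29 samples."""
    return PlantedDesign(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_adjacency(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random symmetric adjacency in [0,1] with unit diagonal (test helper)."""
    m = rng.uniform(0, 1, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    ids = [f"g{i:03d}" for i in range(n)]
    return pd.DataFrame(m, index=ids, columns=ids)
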