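import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None, database=None)
settings.load_profile("repro")

from plsipa import LatentVariable, ModelSpec, PLSPCAModel
from plsipa.synthetic import GeneratorConfig, district_profile_config, generate


@pytest.fixture(scope="session")
def district_config():
    """Study-shaped generator config: 5 latents, 15 indicators, 6 paths."""
    return district_profile_config(n_obs=38, seed=11)


@pytest.fixture(scope="session")
def district_data(district_config):
    return generate(district_config)


@pytest.fixture(scope="session")
def district_fit(district_config, district_data):
    return PLSPCAModel(district_data, district_config.spec).fit()


@pytest.fixture(scope="session")
def two_latent_config():
    """Minimal exogenous -> endogenous model, two indicators per block."""

    def make(path=0.7, n=200, seed=0, loadings=0.9):
        spec = ModelSpec(
            [
                LatentVariable("A", ("a1", "a2")),
                LatentVariable("B", ("b1", "b2")),
            ],
            [("A", "B")],
            ipma_target="B",
        )
        return GeneratorConfig(
            spec=spec,
            population_paths={("A", "B"): path},
            population_loadings={k: loadings for k in ("a1", "a2", "b1", "b2")},
            n_obs=n,
            seed=seed,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def composite_loading(lam: float, n_ind: int) -> float:
    """Population correlation between an indicator and the equal-weight
    composite of its block (all indicators sharing factor loading lam).

    The composite estimand exceeds the factor loading: an indicator is
    correlated with its own measurement error, which the composite contains.
    """
    return float(np.sqrt(((n_ind - 1) * lam**2 + 1) / n_ind))


def score_reliability(lam: float, n_ind: int) -> float:
    """Population correlation between the equal-weight composite and the
    latent it proxies; squares to the attenuation factor of a simple path."""
    return float(lam * np.sqrt(n_ind) / np.sqrt((n_ind - 1) * lam**2 + 1))


def random_standardized_block(rng, n, k):
    """Standardised block with correlated columns (helper, not a fixture)."""
    base = rng.standard_normal((n, 1))
    X = 0.6 * base + rng.standard_normal((n, k))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return X
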