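"""Synthetic data with known population structure.

The generating process follows the reflective composite model literally:
exogenous latents are standard normal; each endogenous latent is the linear
combination of its parents under the population path coefficients plus a
disturbance scaled so its population variance is exactly 1 (the implied
latent covariance matrix is propagated in topological order, so correlated
parents are handled exactly); each indicator is loading x latent + error
with error variance 1 - loading², optionally affine-mapped to a
(location, spread) scale.  Single-indicator blocks conventionally get
loading 1 and zero measurement error.

Disturbances and errors are Gaussian by default; a shifted-lognormal option
(standardised to mean 0, variance 1) exercises estimator behaviour under
skewed, non-normal errors — the estimator itself is distribution-free.

``district_profile_config`` returns the default study-shaped fixture: one
exogenous socioeconomic construct and four endogenous constructs (two of
them single-indicator), 15 indicators in blocks of (3, 1, 1, 7, 3), six
structural paths, n = 38 observational units — the structure of a
provincial district-level malnutrition study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AdmissibilityError
from .model_spec import LatentVariable, ModelSpec, topological_order

__all__ = ["GeneratorConfig", "generate", "district_profile_config"]


@dataclass
class GeneratorConfig:
    """Population model for the generator.

    ``population_paths`` maps (source, target) to the structural coefficient;
    ``population_loadings`` maps each indicator to its loading in (0, 1].
    ``indicator_scales`` optionally maps indicators to (location, spread) for
    unstandardised output.  ``error_distribution`` is "gaussian" or
    "lognormal" (standardised shifted lognormal, skewness ~ 4).
    """

    spec: ModelSpec
    population_paths: dict
    population_loadings: dict
    n_obs: int
    seed: int
    indicator_scales: dict | None = None
    error_distribution: str = "gaussian"


def _latent_covariance(config: GeneratorConfig) -> tuple:
    """Implied latent covariance and per-latent disturbance SD.

    Raises :class:`AdmissibilityError` if any endogenous latent's explained
    variance reaches 1 (no room for a positive-variance disturbance).
    """
    spec = config.spec
    order = topological_order(spec)
    pos = {n: j for j, n in enumerate(order)}
    L = len(order)
    cov = np.zeros((L, L))
    dist_sd = {}
    for name in order:
        j = pos[name]
        parents = spec.adjacency.parents(name)
        if not parents:
            cov[j, j] = 1.0
            continue
        b = np.array([config.population_paths[(p, name)] for p in parents])
        pidx = [pos[p] for p in parents]
        explained = float(b @ cov[np.ix_(pidx, pidx)] @ b)
        if explained >= 1.0:
            raise AdmissibilityError(
                f"equation for {name!r}: explained variance {explained:.3f} >= 1; "
                "population paths are inadmissible"
            )
        dist_sd[name] = float(np.sqrt(1.0 - explained))
        for k in range(L):
            cov[j, k] = cov[k, j] = float(b @ cov[np.ix_(pidx, [k])][:, 0])
        cov[j, j] = 1.0
    return cov, dist_sd, order, pos


def _noise(rng: np.random.Generator, size, kind: str) -> np.ndarray:
    """Unit-variance, zero-mean noise draws."""
    if kind == "gaussian":
        return rng.standard_normal(size)
    if kind == "lognormal":
        sigma = 0.6  # skewness ~ 2.3: clearly non-normal, still well-behaved
        raw = rng.lognormal(mean=0.0, sigma=sigma, size=size)
        mu = np.exp(sigma**2 / 2)
        sd = np.sqrt((np.exp(sigma**2) - 1) * np.exp(sigma**2))
        return (raw - mu) / sd
    raise ValueError(f"unknown error_distribution {kind!r}")


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Draw an observation-by-indicator table from the population model."""
    spec = config.spec
    for ind in spec.indicator_names:
        lam = config.population_loadings[ind]
        if not 0 < lam <= 1:
            raise AdmissibilityError(f"loading for {ind!r} must lie in (0, 1], got {lam}")
    _, dist_sd, order, pos = _latent_covariance(config)
    rng = np.random.default_rng(config.seed)
    n = int(config.n_obs)
    kind = config.error_distribution
    scores = {}
    for name in order:
        parents = spec.adjacency.parents(name)
        if not parents:
            scores[name] = _noise(rng, n, kind)
        else:
            eta = np.zeros(n)
            for p in parents:
                eta += config.population_paths[(p, name)] * scores[p]
            scores[name] = eta + dist_sd[name] * _noise(rng, n, kind)
    cols = {}
    for lv in spec.latents:
        for ind in lv.indicators:
            lam = float(config.population_loadings[ind])
            err_sd = float(np.sqrt(1.0 - lam**2))
            x = lam * scores[lv.name]
            if err_sd > 0:
                x = x + err_sd * _noise(rng, n, kind)
            if config.indicator_scales and ind in config.indicator_scales:
                loc, spread = config.indicator_scales[ind]
                x = loc + spread * x
            cols[ind] = x
    return pd.DataFrame(cols, columns=list(spec.indicator_names))


def district_profile_config(
    n_obs: int = 38, seed: int = 0, scaled: bool = True
) -> GeneratorConfig:
    """Default study-shaped fixture.

    Five latents — socio_economic (3 indicators), parenting (1),
    food_security (1), health_env (7), malnutrition (3) — with the
    socioeconomic construct driving the three mediators and all three
    mediators driving malnutrition (6 paths).  Population paths default to
    the magnitudes typical of a district-level malnutrition model (a strong
    socioeconomic -> food-security link, weak mixed-sign effects on
    malnutrition); loadings are 0.9 for multi-indicator blocks and 1.0 for
    single-indicator blocks.  ``scaled=True`` puts indicators on plausible
    percentage-like scales; n defaults to the tens of districts such a
    study observes.
    """
    latents = [
        LatentVariable("socio_economic", ("x1_1", "x1_2", "x1_3")),
        LatentVariable("parenting", ("y1_1",)),
        LatentVariable("food_security", ("y2_1",)),
        LatentVariable(
            "health_env", ("y3_1", "y3_2", "y3_3", "y3_4", "y3_5", "y3_6", "y3_7")
        ),
        LatentVariable("malnutrition", ("y4_1", "y4_2", "y4_3")),
    ]
    paths = (
        ("socio_economic", "parenting"),
        ("socio_economic", "food_security"),
        ("socio_economic", "health_env"),
        ("parenting", "malnutrition"),
        ("food_security", "malnutrition"),
        ("health_env", "malnutrition"),
    )
    spec = ModelSpec(latents, paths, ipma_target="malnutrition")
    population_paths = {
        ("socio_economic", "parenting"): 0.464,
        ("socio_economic", "food_security"): 0.720,
        ("socio_economic", "health_env"): 0.513,
        ("parenting", "malnutrition"): -0.185,
        ("food_security", "malnutrition"): 0.178,
        ("health_env", "malnutrition"): -0.011,
    }
    population_loadings = {}
    for lv in latents:
        for ind in lv.indicators:
            population_loadings[ind] = 1.0 if len(lv.indicators) == 1 else 0.9
    indicator_scales = None
    if scaled:
        # percentage-like locations/spreads, deterministic per indicator
        indicator_scales = {
            ind: (40.0 + 3.0 * k, 8.0 + (k % 5))
            for k, ind in enumerate(spec.indicator_names)
        }
    return GeneratorConfig(
        spec=spec,
        population_paths=population_paths,
        population_loadings=population_loadings,
        n_obs=n_obs,
        seed=seed,
        indicator_scales=indicator_scales,
    )
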