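"""PCA-weighted PLS path-model estimation.

The estimator is *one-shot*: each measurement block's outer weight vector is
the dominant eigenvector of the block covariance matrix, normalised so the
sum of absolute components is one.  There is no inner/outer iteration loop —
the classic PLS algorithm alternates outside and inside approximations until
the weights converge (typically to 1e-5), but the PCA weighting scheme
declares the first-principal-component vector the final weight vector
directly, which makes the whole fit deterministic.

Pipeline: standardise the data -> PCA weights per block -> latent scores
(re-standardised) -> outer loadings (indicator/score correlations) ->
per-equation OLS for path coefficients -> total effects by path-product
accumulation -> affine location parameters linking standardised scores to
their 0-100-scale counterparts used by the importance-performance stage.

Scores are re-standardised before loadings and OLS so that loadings are
correlations and path coefficients are standardised regression coefficients;
the abs-sum-one weights are retained for the IPMA rescaling stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError, SingularityError
from .model_spec import ModelSpec, topological_order

__all__ = [
    "PcaExtraction",
    "PLSPCAModel",
    "PLSPCAResults",
    "standardize",
    "pca_block_weights",
    "latent_scores",
    "outer_loadings",
    "path_coefficients",
    "total_effects",
    "location_params",
    "fit",
]

_MIN_OBS = 3


@dataclass(frozen=True)
class PcaExtraction:
    """First-principal-component extraction for one block.

    ``eigenvector`` is the unit-norm dominant eigenvector of the block
    covariance matrix (before abs-sum normalisation), ``eigenvalue`` the
    variance it explains and ``explained_proportion`` its share of the
    block's total variance (eigenvalue / trace).
    """

    eigenvector: np.ndarray
    eigenvalue: float
    explained_proportion: float


# ---------------------------------------------------------------------------
# data validation and standardisation
# ---------------------------------------------------------------------------

def validate_data(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Check completeness/shape and reorder columns to model order."""
    missing = [c for c in spec.indicator_names if c not in data.columns]
    if missing:
        raise SchemaError(f"data is missing indicator columns: {missing}")
    data = data.loc[:, list(spec.indicator_names)]
    if data.isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise SchemaError(f"missing values in columns {bad}; complete cases are required")
    try:
        data = data.astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric data: {exc}") from exc
    if len(data) < _MIN_OBS:
        raise DegenerateDataError(f"need at least {_MIN_OBS} observations, got {len(data)}")
    return data


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores with the sample (n-1) standard deviation."""
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    dead = sd[~(sd > 0)].index.tolist()
    if dead:
        raise DegenerateDataError(f"zero-variance column(s): {dead}")
    return (data - mu) / sd


# ---------------------------------------------------------------------------
# array-level core (kept free of pandas so the bootstrap can refit cheaply)
# ---------------------------------------------------------------------------

class _Compiled:
    """Index-level view of a ModelSpec against a fixed indicator ordering."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.latent_names = spec.latent_names
        pos = {ind: i for i, ind in enumerate(spec.indicator_names)}
        self.blocks = [
            np.array([pos[i] for i in lv.indicators], dtype=int) for lv in spec.latents
        ]
        lpos = {n: j for j, n in enumerate(self.latent_names)}
        self.topo = [lpos[n] for n in topological_order(spec)]
        self.parents = [
            [lpos[s] for s in spec.adjacency.parents(n)] for n in self.latent_names
        ]
        # reachability closure for total effects
        L = len(self.latent_names)
        adj = np.zeros((L, L), dtype=bool)
        for s, t in spec.adjacency.paths:
            adj[lpos[s], lpos[t]] = True
        reach = adj.copy()
        for _ in range(max(L - 2, 0)):
            reach = reach | (reach @ adj)
        self.adj = adj
        self.reach = reach


def _standardize_array(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateDataError("zero-variance column in resample")
    return (X - mu) / sd


def _pca_weights_array(block: np.ndarray):
    """Dominant-eigenvector weights for one standardised block.

    Returns the abs-sum-one weight vector and the raw extraction.  Sign is
    oriented so the component of largest magnitude (first on ties) is
    positive — a deterministic, dataset-independent rule resolving the
    eigenvector's sign ambiguity.
    """
    k = block.shape[1]
    if k == 1:
        var = float(block[:, 0].var(ddof=1))
        if not var > 0:
            raise DegenerateDataError("single-indicator block has zero variance")
        return np.array([1.0]), PcaExtraction(np.array([1.0]), var, 1.0)
    cov = np.cov(block, rowvar=False, ddof=1)
    trace = float(np.trace(cov))
    if not trace > 0:
        raise DegenerateDataError("rank-0 (all-zero) measurement block")
    evals, evecs = np.linalg.eigh(cov)
    lam = float(evals[-1])
    v = evecs[:, -1]
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        v = -v
    w = v / np.abs(v).sum()
    return w, PcaExtraction(v, lam, lam / trace)


def _fit_core(Z: np.ndarray, comp: _Compiled, align_to: Sequence[np.ndarray] | None = None):
    """Full estimation on a standardised array.

    Returns (weights, extractions, scores, loadings, path_matrix, r2) where
    ``path_matrix[s, t]`` is the coefficient of the s -> t path and
    ``loadings`` is a flat array in indicator order.
    """
    n = Z.shape[0]
    L = len(comp.latent_names)
    weights, extractions = [], []
    T = np.empty((n, L))
    for j, idx in enumerate(comp.blocks):
        w, ext = _pca_weights_array(Z[:, idx])
        if align_to is not None and float(w @ align_to[j]) < 0:
            w = -w
        t = Z[:, idx] @ w
        sd = t.std(ddof=1)
        if not sd > 0:
            raise DegenerateDataError(
                f"latent {comp.latent_names[j]!r}: raw score has zero variance"
            )
        T[:, j] = (t - t.mean()) / sd
        weights.append(w)
        extractions.append(ext)

    loadings = np.empty(Z.shape[1])
    for j, idx in enumerate(comp.blocks):
        loadings[idx] = Z[:, idx].T @ T[:, j] / (n - 1)

    path = np.zeros((L, L))
    r2 = np.full(L, np.nan)
    for j in range(L):
        pa = comp.parents[j]
        if not pa:
            continue
        X = T[:, pa]
        gram = X.T @ X
        if np.linalg.matrix_rank(gram, tol=1e-10 * n) < len(pa):
            names = [comp.latent_names[p] for p in pa]
            raise SingularityError(
                f"perfectly collinear parent scores {names} in the equation for "
                f"{comp.latent_names[j]!r}"
            )
        beta = np.linalg.solve(gram, X.T @ T[:, j])
        path[pa, j] = beta
        resid = T[:, j] - X @ beta
        r2[j] = 1.0 - float(resid @ resid) / float(T[:, j] @ T[:, j])
    return weights, extractions, T, loadings, path, r2


def _total_effects_matrix(path: np.ndarray) -> np.ndarray:
    """Sum of path products over all directed routes: sum_k path^k."""
    L = path.shape[0]
    total = path.copy()
    power = path.copy()
    for _ in range(L - 2):
        power = power @ path
        total += power
    return total


# ---------------------------------------------------------------------------
# public operations (pandas surface)
# ---------------------------------------------------------------------------

def pca_block_weights(block: pd.DataFrame | np.ndarray):
    """Abs-sum-one PCA weights for one standardised indicator block.

    Returns ``(weights, PcaExtraction)``; ``weights`` is a Series when the
    input is a DataFrame, else a plain array.
    """
    if isinstance(block, pd.DataFrame):
        w, ext = _pca_weights_array(block.to_numpy(dtype=float))
        return pd.Series(w, index=block.columns), ext
    return _pca_weights_array(np.asarray(block, dtype=float))


def latent_scores(
    data: pd.DataFrame, spec: ModelSpec, weights: Mapping[str, Sequence]
) -> pd.DataFrame:
    """Standardised latent scores t = Zw per block, re-standardised.

    ``data`` must already be standardised; ``weights`` maps each latent to
    its block weight vector (indicator order of the spec).
    """
    out = {}
    for lv in spec.latents:
        missing = [i for i in lv.indicators if i not in data.columns]
        if missing:
            raise SchemaError(f"latent {lv.name!r}: indicators missing from data: {missing}")
        w = np.asarray(weights[lv.name], dtype=float)
        t = data.loc[:, list(lv.indicators)].to_numpy() @ w
        sd = t.std(ddof=1)
        if not sd > 0:
            raise DegenerateDataError(f"latent {lv.name!r}: score has zero variance")
        out[lv.name] = (t - t.mean()) / sd
    return pd.DataFrame(out, index=data.index)


def outer_loadings(data: pd.DataFrame, scores: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    """Correlation of each indicator with its own latent's score."""
    vals = {}
    for lv in spec.latents:
        s = scores[lv.name]
        for ind in lv.indicators:
            vals[ind] = float(np.corrcoef(data[ind], s)[0, 1])
    return pd.Series(vals, name="loading")


def path_coefficients(scores: pd.DataFrame, spec: ModelSpec) -> dict:
    """Standardised OLS coefficients, one multiple regression per equation."""
    comp = _Compiled(spec)
    T = scores.loc[:, list(spec.latent_names)].to_numpy(dtype=float)
    n, L = T.shape
    out = {}
    for j in range(L):
        pa = comp.parents[j]
        if not pa:
            continue
        X = T[:, pa]
        gram = X.T @ X
        if np.linalg.matrix_rank(gram, tol=1e-10 * n) < len(pa):
            names = [comp.latent_names[p] for p in pa]
            raise SingularityError(f"perfectly collinear parent scores {names}")
        beta = np.linalg.solve(gram, X.T @ T[:, j])
        for p, b in zip(pa, beta):
            out[(comp.latent_names[p], comp.latent_names[j])] = float(b)
    return out


def total_effects(path_coeffs: Mapping[tuple, float], spec: ModelSpec) -> dict:
    """Direct-plus-indirect effects for every connected ordered pair.

    The total effect of one latent on another is the sum over all directed
    routes of the product of path coefficients along each route; it equals
    the direct coefficient when no mediation exists.
    """
    comp = _Compiled(spec)
    L = len(comp.latent_names)
    lpos = {n: j for j, n in enumerate(comp.latent_names)}
    path = np.zeros((L, L))
    for (s, t), b in path_coeffs.items():
        path[lpos[s], lpos[t]] = b
    tot = _total_effects_matrix(path)
    return {
        (comp.latent_names[s], comp.latent_names[t]): float(tot[s, t])
        for s in range(L)
        for t in range(L)
        if comp.reach[s, t]
    }


def location_params(
    data: pd.DataFrame, spec: ModelSpec, weights: Mapping[str, Sequence]
) -> dict:
    """Affine constants mapping each standardised score to its 0-100 score.

    The unstandardised score of a latent is the weighted combination of its
    0-100-rescaled indicators under block-normalised unstandardised weights;
    because both scores are affine in the same weighted indicator
    combination, an exact (slope, intercept) pair links them.  The intercept
    equals the mean unstandardised score (standardised scores have mean 0).
    """
    from .ipma import normalized_unstandardized_weights, rescale

    data = validate_data(data, spec)
    std = standardize(data)
    scores = latent_scores(std, spec, weights)
    rescaled = rescale(data, spec.scale_bounds or None)
    norm_w = normalized_unstandardized_weights(weights, spec, rescaled)
    out = {}
    for lv in spec.latents:
        v = np.array([norm_w[i] for i in lv.indicators])
        u = rescaled.values.loc[:, list(lv.indicators)].to_numpy() @ v
        z = scores[lv.name].to_numpy()
        slope = float(z @ (u - u.mean()) / (z @ z))
        out[lv.name] = (slope, float(u.mean()))
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PLSPCAModel:
    """PCA-weighted PLS structural equation model.

    Parameters
    ----------
    data : DataFrame
        Observation-by-indicator table; columns must include every indicator
        named in ``spec`` (exact, case-sensitive); complete cases only.
    spec : ModelSpec
        Validated structural/measurement specification.

    Examples
    --------
    >>> model = PLSPCAModel(df, spec)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.data = validate_data(data, spec)
        self._comp = _Compiled(spec)

    @classmethod
    def from_csv(cls, data_path, spec, id_column=None) -> "PLSPCAModel":
        from .io_ import read_indicator_csv

        data = read_indicator_csv(data_path, spec, id_column=id_column)
        return cls(data, spec)

    def fit(self) -> "PLSPCAResults":
        """Estimate the model; deterministic (no iteration, no randomness)."""
        Z = standardize(self.data).to_numpy()
        weights, exts, T, load, path, r2 = _fit_core(Z, self._comp)
        return PLSPCAResults(self, Z, weights, exts, T, load, path, r2)


class PLSPCAResults:
    """Estimates from a :class:`PLSPCAModel` fit.

    Attributes
    ----------
    weights : dict of Series
        Abs-sum-one outer weight vector per latent.
    scores : DataFrame
        Standardised latent scores (mean 0, variance 1 per column).
    loadings : Series
        Outer loading (indicator-score correlation) per indicator.
    path_coefficients : dict
        Standardised coefficient per directed path (source, target).
    total_effects : dict
        Direct-plus-indirect effect per connected ordered pair.
    r2 : dict
        Coefficient of determination per endogenous latent.
    residual_variances : dict
        Disturbance variance proxy 1 - R² per endogenous latent.
    """

    def __init__(self, model, Z, weights, extractions, T, loadings, path, r2):
        self.model = model
        self.spec = model.spec
        self.data = model.data
        comp = model._comp
        self._comp = comp
        self._weights_arrays = weights
        self._path_matrix = path
        names = comp.latent_names
        self.weights = {
            names[j]: pd.Series(weights[j], index=list(model.spec.latents[j].indicators))
            for j in range(len(names))
        }
        self.pca = {names[j]: extractions[j] for j in range(len(names))}
        self.scores = pd.DataFrame(T, columns=list(names), index=model.data.index)
        self.loadings = pd.Series(loadings, index=list(model.spec.indicator_names), name="loading")
        self.path_coefficients = {
            (s, t): float(path[names.index(s), names.index(t)])
            for s, t in model.spec.adjacency.paths
        }
        self.r2 = {names[j]: float(r2[j]) for j in range(len(names)) if not np.isnan(r2[j])}
        self.residual_variances = {k: 1.0 - v for k, v in self.r2.items()}
        tot = _total_effects_matrix(path)
        self.total_effects = {
            (names[s], names[t]): float(tot[s, t])
            for s in range(len(names))
            for t in range(len(names))
            if comp.reach[s, t]
        }
        self._location_params = None

    @property
    def location_params(self) -> dict:
        """(slope, intercept) per latent: standardised -> 0-100-scale score."""
        if self._location_params is None:
            self._location_params = location_params(self.data, self.spec, self.weights)
        return self._location_params

    @property
    def nobs(self) -> int:
        return len(self.data)

    # -- downstream stages ------------------------------------------------
    def evaluate(self):
        """Measurement/structural evaluation report (AVE, CR, FL, R², GoF, Q²)."""
        from .evaluation import evaluate

        return evaluate(self)

    def bootstrap(self, B: int = 2000, seed: int | None = None, alpha: float = 0.05):
        """Nonparametric bootstrap t-tests for loadings and path coefficients."""
        from .bootstrap import bootstrap_fit

        return bootstrap_fit(self.data, self.spec, B=B, seed=seed, alpha=alpha, results=self)

    def ipma(self, target: str | None = None, bounds: Mapping | None = None, crosshair=None):
        """Importance-performance map toward ``target`` (default: spec's)."""
        from .ipma import ipma

        return ipma(self, target=target, bounds=bounds, crosshair=crosshair)

    def summary(self) -> str:
        """Plain-text summary of weights, loadings, paths and R²."""
        lines = [
            "PCA-weighted PLS-SEM results",
            "=" * 60,
            f"observations: {self.nobs}   latents: {len(self.spec.latents)}   "
            f"indicators: {len(self.spec.indicator_names)}",
            "",
            "Outer model (weights / loadings)",
            "-" * 60,
        ]
        for lv in self.spec.latents:
            ext = self.pca[lv.name]
            lines.append(f"{lv.name} (explained variance {ext.explained_proportion:.1%})")
            for ind in lv.indicators:
                lines.append(
                    f"  {ind:<20} w = {self.weights[lv.name][ind]:7.3f}   "
                    f"loading = {self.loadings[ind]:6.3f}"
                )
        lines += ["", "Inner model (standardised path coefficients)", "-" * 60]
        for (s, t), b in self.path_coefficients.items():
            lines.append(f"  {s} -> {t:<25} {b:7.3f}")
        lines += ["", "R² per endogenous latent", "-" * 60]
        for k, v in self.r2.items():
            lines.append(f"  {k:<30} {v:7.3f}")
        return "\n".join(lines)


def fit(data: pd.DataFrame, spec: ModelSpec) -> PLSPCAResults:
    """Convenience wrapper: ``PLSPCAModel(data, spec).fit()``."""
    return PLSPCAModel(data, spec).fit()
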