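"""Nonparametric bootstrap inference for loadings and path coefficients.

B row-resamples of size n are drawn with replacement; the full PCA-scheme
estimator is refitted on each.  The standard error of a parameter is the
sample standard deviation of its B replicates (B - 1 denominator); the test
statistic t = estimate / se is referred to a Student t distribution with
n - 1 degrees of freedom, two-tailed (for n well above 30 the 5% critical
value is effectively the normal 1.96).

PCA weight vectors are sign-ambiguous, and an unlucky resample can flip a
latent's orientation, which would corrupt the replicate spread.  Each
replicate therefore applies an individual sign-change correction: a block's
weight vector (and hence its score, loadings and incident paths) is flipped
whenever its dot product with the original-sample weight vector is negative.

Resamples containing a zero-variance column cannot be standardised; they
are discarded and counted.  More than 10% discarded aborts the run.  The
resample stream is consumed in a fixed order, so results are bit-reproducible
for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, NumericalError
from .estimator import _Compiled, _fit_core, _standardize_array, validate_data
from .model_spec import ModelSpec

__all__ = ["BootstrapResult", "bootstrap_se", "t_test", "bootstrap_fit"]


@dataclass
class BootstrapResult:
    """Replicates and test summary for a single parameter.

    ``testable`` is False when every replicate is identical (se = 0), in
    which case t and p are NaN and ``significant`` is False.
    """

    parameter: str
    estimate: float
    replicates: np.ndarray
    se: float
    t_statistic: float
    p_value: float
    significant: bool
    testable: bool = True


def bootstrap_se(replicates) -> float:
    """Sample standard deviation of the replicates (B - 1 denominator)."""
    r = np.asarray(list(replicates), dtype=float)
    if r.size < 2:
        raise ValueError("need at least two replicates")
    return float(np.sqrt(np.sum((r - r.mean()) ** 2) / (r.size - 1)))


def t_test(estimate: float, se: float, df: int, alpha: float = 0.05) -> tuple:
    """Two-tailed Student-t test of estimate / se against zero.

    Returns ``(t, p, significant)``.
    """
    if not se > 0:
        raise ValueError("standard error must be positive")
    t = estimate / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, p, p < alpha


def bootstrap_fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    B: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    results=None,
) -> dict:
    """Bootstrap the whole estimator; one :class:`BootstrapResult` per
    loading (``lambda:<indicator>``) and path (``path:<source>-><target>``).

    Parameters
    ----------
    B : int
        Number of resamples (>= 2).  2000 mirrors common practice.
    seed : int
        Mandatory; there is no hidden global random state.
    alpha : float
        Two-tailed significance level.
    results : PLSPCAResults, optional
        Original-sample fit to reuse; refitted from ``data`` if omitted.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if seed is None:
        raise ValueError("a seed is required for reproducible resampling")
    from .estimator import PLSPCAModel

    data = validate_data(data, spec)
    if results is None:
        results = PLSPCAModel(data, spec).fit()
    comp = _Compiled(spec)
    X = data.to_numpy(dtype=float)
    n = X.shape[0]
    ref_weights = results._weights_arrays

    n_load = X.shape[1]
    path_keys = list(spec.adjacency.paths)
    lpos = {name: j for j, name in enumerate(comp.latent_names)}
    load_reps = np.empty((B, n_load))
    path_reps = np.empty((B, len(path_keys)))
    rng = np.random.default_rng(seed)
    kept = 0
    discarded = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            Z = _standardize_array(X[idx])
            _, _, _, load, path, _ = _fit_core(Z, comp, align_to=ref_weights)
        except DegenerateDataError:
            discarded += 1
            continue
        load_reps[kept] = load
        path_reps[kept] = [path[lpos[s], lpos[t]] for s, t in path_keys]
        kept += 1
    if discarded > 0.1 * B:
        raise NumericalError(
            f"{discarded}/{B} bootstrap resamples were degenerate (>10%); aborting"
        )
    if kept < 2:
        raise NumericalError("fewer than two usable bootstrap replicates")
    load_reps = load_reps[:kept]
    path_reps = path_reps[:kept]

    out = {}
    df = n - 1
    ind_names = list(spec.indicator_names)
    for j, ind in enumerate(ind_names):
        out[f"lambda:{ind}"] = _summarise(
            f"lambda:{ind}", float(results.loadings[ind]), load_reps[:, j], df, alpha
        )
    for k, (s, t) in enumerate(path_keys):
        out[f"path:{s}->{t}"] = _summarise(
            f"path:{s}->{t}", results.path_coefficients[(s, t)], path_reps[:, k], df, alpha
        )
    out["__meta__"] = {"B": B, "kept": kept, "discarded": discarded, "alpha": alpha, "df": df}
    return out


def _summarise(name, estimate, reps, df, alpha):
    se = bootstrap_se(reps)
    # replicates identical up to float jitter carry no sampling information
    if se <= 1e-12 * max(1.0, abs(estimate)):
        se = 0.0
    if se > 0:
        t, p, sig = t_test(estimate, se, df, alpha)
        return BootstrapResult(name, estimate, reps, se, t, p, sig, testable=True)
    return BootstrapResult(
        name, estimate, reps, 0.0, float("nan"), float("nan"), False, testable=False
    )


def bootstrap_table(boot: dict) -> pd.DataFrame:
    """Tabulate bootstrap results (parameter, estimate, se, t, p, flag)."""
    rows = []
    for key, r in boot.items():
        if key == "__meta__":
            continue
        rows.append((r.parameter, r.estimate, r.se, r.t_statistic, r.p_value, r.significant))
    return pd.DataFrame(
        rows, columns=["parameter", "estimate", "se", "t", "p_value", "significant"]
    )
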