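"""Measurement- and structural-model evaluation statistics.

Convergent validity: outer loadings (valid if > 0.5, ideal > 0.7) and the
average variance extracted, AVE = sum(lambda_i^2) / (sum(lambda_i^2) +
sum(var(eps_i))) with var(eps_i) = 1 - lambda_i^2 (criterion > 0.5).
Discriminant validity: cross-loadings (an indicator must correlate more
strongly with its own latent score than with any other) and the
Fornell-Larcker criterion (sqrt(AVE) of each latent must exceed its
correlations with every other latent).  Reliability: composite reliability
rho_c = (sum lambda_i)^2 / ((sum lambda_i)^2 + sum var(eps_i)), criterion
> 0.7.  Structural model: R^2 per endogenous latent decomposed as
sum_h beta_h * corr(parent_h, child); global fit GoF = sqrt(mean AVE x mean
R^2); predictive relevance Q^2 = 1 - prod(1 - R_j^2).

Cronbach's alpha is deliberately not computed; composite reliability is the
reported internal-consistency measure for composite models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_spec import ModelSpec

__all__ = [
    "EvaluationReport",
    "ave",
    "composite_reliability",
    "loading_validity",
    "cross_loadings",
    "fornell_larcker",
    "r_squared",
    "gof",
    "q_squared",
    "evaluate",
]

LOADING_THRESHOLD = 0.5
AVE_THRESHOLD = 0.5
CR_THRESHOLD = 0.7


def _check_loadings(loadings: Sequence[float]) -> np.ndarray:
    lam = np.asarray(list(loadings), dtype=float)
    if lam.size == 0:
        raise ValueError("need at least one loading")
    if np.any(np.abs(lam) > 1 + 1e-8):
        raise ValueError("loadings are correlations; |loading| must be <= 1")
    return lam


def ave(loadings: Sequence[float]) -> float:
    """Average variance extracted for one reflective block.

    sum(lambda^2) / (sum(lambda^2) + sum(1 - lambda^2)); with the
    measurement-error variance defined as 1 - lambda^2 this simplifies to
    mean(lambda^2) — the full ratio is evaluated here, the identity is
    asserted in the test suite.
    """
    lam = _check_loadings(loadings)
    num = float(np.sum(lam**2))
    return num / (num + float(np.sum(1.0 - lam**2)))


def composite_reliability(loadings: Sequence[float]) -> float:
    """rho_c = (sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2))."""
    lam = _check_loadings(loadings)
    s2 = float(np.sum(lam)) ** 2
    return s2 / (s2 + float(np.sum(1.0 - lam**2)))


def loading_validity(
    loadings: Mapping[str, float], threshold: float = LOADING_THRESHOLD
) -> dict:
    """Valid iff loading strictly exceeds the threshold (default 0.5)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return {k: bool(v > threshold) for k, v in loadings.items()}


def cross_loadings(data: pd.DataFrame, scores: pd.DataFrame, spec: ModelSpec) -> tuple:
    """Correlation of every indicator with every latent score.

    Returns ``(table, flags)``: the indicator x latent correlation table and
    per-indicator discriminant flags — pass iff the own-latent entry
    *strictly* exceeds all others in the row (ties fail).
    """
    table = pd.DataFrame(
        {
            lat: [float(np.corrcoef(data[ind], scores[lat])[0, 1]) for ind in spec.indicator_names]
            for lat in spec.latent_names
        },
        index=list(spec.indicator_names),
    )
    flags = {}
    for ind in spec.indicator_names:
        own = spec.owner_of(ind)
        own_val = table.loc[ind, own]
        others = table.loc[ind, [c for c in table.columns if c != own]]
        flags[ind] = bool(own_val > others.max())
    return table, flags


def fornell_larcker(
    ave_values: Mapping[str, float], score_correlations: pd.DataFrame
) -> tuple:
    """Fornell-Larcker matrix and per-latent discriminant flags.

    Diagonal = sqrt(AVE); off-diagonal = latent score correlations.  A
    latent passes iff its sqrt(AVE) strictly exceeds the absolute value of
    every off-diagonal entry in its row/column.
    """
    names = list(score_correlations.columns)
    mat = score_correlations.astype(float).copy()
    for n in names:
        mat.loc[n, n] = math.sqrt(ave_values[n])
    flags = {}
    for n in names:
        off = np.abs([mat.loc[n, m] for m in names if m != n]) if len(names) > 1 else [0.0]
        flags[n] = bool(mat.loc[n, n] > np.max(off))
    return mat, flags


def r_squared(
    scores: pd.DataFrame, spec: ModelSpec, path_coefficients: Mapping[tuple, float]
) -> dict:
    """R² per endogenous latent, via the standardised decomposition
    sum_h beta_h x corr(parent_h, child), with its strength category.

    Categories: weak below 0.33, moderate in [0.33, 0.67), strong at or
    above 0.67 (boundaries go to the higher category).
    """
    out = {}
    for name in spec.latent_names:
        parents = spec.adjacency.parents(name)
        if not parents:
            continue
        val = 0.0
        for p in parents:
            r = float(np.corrcoef(scores[p], scores[name])[0, 1])
            val += path_coefficients[(p, name)] * r
        out[name] = (val, _r2_category(val))
    return out


def _r2_category(value: float) -> str:
    if value >= 0.67:
        return "strong"
    if value >= 0.33:
        return "moderate"
    return "weak"


def gof(ave_values: Sequence[float], r2_values: Sequence[float]) -> float:
    """Global goodness of fit: sqrt(mean(AVE) x mean(R²))."""
    a = np.asarray(list(ave_values), dtype=float)
    r = np.asarray(list(r2_values), dtype=float)
    if a.size == 0 or r.size == 0:
        raise ValueError("gof needs non-empty AVE and R² lists")
    return math.sqrt(a.mean() * r.mean())


def q_squared(r2_values: Sequence[float]) -> float:
    """Predictive relevance: 1 - prod(1 - R_j^2) over endogenous latents."""
    r = np.asarray(list(r2_values), dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("every R² must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - r))


@dataclass
class EvaluationReport:
    """Bundle of all evaluation statistics for one fit."""

    ave: dict
    composite_reliability: dict
    loadings_with_flags: dict  # indicator -> (loading, valid)
    cross_loadings: pd.DataFrame
    cross_loading_flags: dict
    fornell_larcker: pd.DataFrame
    fornell_larcker_flags: dict
    r_squared: dict  # endogenous -> (value, category)
    gof: float
    q_squared: float
    formative_blocks: tuple = ()

    def to_dict(self) -> dict:
        return {
            "ave": dict(self.ave),
            "composite_reliability": dict(self.composite_reliability),
            "loadings": {k: {"loading": v, "valid": f} for k, (v, f) in self.loadings_with_flags.items()},
            "cross_loadings": self.cross_loadings.to_dict(),
            "cross_loading_flags": dict(self.cross_loading_flags),
            "fornell_larcker": self.fornell_larcker.to_dict(),
            "fornell_larcker_flags": dict(self.fornell_larcker_flags),
            "r_squared": {k: {"value": v, "category": c} for k, (v, c) in self.r_squared.items()},
            "gof": self.gof,
            "q_squared": self.q_squared,
            "formative_blocks": list(self.formative_blocks),
        }

    def summary(self) -> str:
        """Tables mirroring the usual reporting layout, 3 decimals half-up."""

        def f3(x):
            from decimal import ROUND_HALF_UP, Decimal

            return str(Decimal(repr(float(x))).quantize(Decimal("0.001"), ROUND_HALF_UP))

        lines = ["Measurement model", "=" * 60, "Outer loadings", "-" * 60]
        for ind, (lo, ok) in self.loadings_with_flags.items():
            lines.append(f"  {ind:<20} {f3(lo):>8}   {'valid' if ok else 'NOT valid'}")
        lines += ["", "AVE (criterion > 0.5) / composite reliability (> 0.7)", "-" * 60]
        for lat, a in self.ave.items():
            cr = self.composite_reliability[lat]
            ok = "valid" if a > AVE_THRESHOLD else "NOT valid"
            rel = "reliable" if cr > CR_THRESHOLD else "NOT reliable"
            lines.append(f"  {lat:<30} AVE {f3(a):>7} {ok:<10} CR {f3(cr):>7} {rel}")
        lines += ["", "Fornell-Larcker (diagonal = sqrt AVE)", "-" * 60]
        lines.append(self.fornell_larcker.round(3).to_string())
        lines += ["", "Structural model", "=" * 60]
        for lat, (v, cat) in self.r_squared.items():
            lines.append(f"  R²({lat}) = {f3(v)}  ({cat})")
        lines.append(f"  GoF = {f3(self.gof)}")
        lines.append(f"  Q²  = {f3(self.q_squared)}")
        return "\n".join(lines)


def evaluate(results) -> EvaluationReport:
    """Build the full :class:`EvaluationReport` from fitted results.

    AVE and composite reliability are computed for reflective blocks only;
    formative blocks are listed in ``formative_blocks``.  The default GoF
    averages the AVEs of all reflective blocks and the R² of all endogenous
    latents.
    """
    spec = results.spec
    from .estimator import standardize

    data_std = standardize(results.data)
    ave_vals, cr_vals = {}, {}
    formative = tuple(lv.name for lv in spec.latents if lv.mode == "formative")
    for lv in spec.latents:
        if lv.mode != "reflective":
            continue
        lam = [results.loadings[i] for i in lv.indicators]
        ave_vals[lv.name] = ave(lam)
        cr_vals[lv.name] = composite_reliability(lam)
    validity = loading_validity(dict(results.loadings))
    loadings_with_flags = {
        i: (float(results.loadings[i]), validity[i]) for i in spec.indicator_names
    }
    cl_table, cl_flags = cross_loadings(data_std, results.scores, spec)
    score_corr = results.scores.corr()
    fl_input = {n: ave_vals.get(n, 1.0) for n in spec.latent_names}
    fl_mat, fl_flags = fornell_larcker(fl_input, score_corr)
    r2 = r_squared(results.scores, spec, results.path_coefficients)
    r2_list = [v for v, _ in r2.values()]
    g = gof(list(ave_vals.values()), r2_list) if ave_vals and r2_list else float("nan")
    q2 = q_squared([min(max(v, 0.0), 1.0) for v in r2_list]) if r2_list else float("nan")
    return EvaluationReport(
        ave=ave_vals,
        composite_reliability=cr_vals,
        loadings_with_flags=loadings_with_flags,
        cross_loadings=cl_table,
        cross_loading_flags=cl_flags,
        fornell_larcker=fl_mat,
        fornell_larcker_flags=fl_flags,
        r_squared=r2,
        gof=g,
        q_squared=q2,
        formative_blocks=formative,
    )
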