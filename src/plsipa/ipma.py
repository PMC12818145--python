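"""Importance-performance map analysis (IPMA) on a fitted PLS model.

Performance is the 0-100-rescaled achievement of an indicator or latent
variable: indicators are rescaled with value' = (value - min)/(max - min) x
100 (empirical or theoretical bounds), latent performances are weighted means
of their indicators under block-normalised unstandardised outer weights.

Importance is the *unstandardised* total effect on the chosen target latent:
the structural equations are re-estimated by OLS on the 0-100-scale latent
scores, path products are accumulated over every directed route, and each
indicator inherits its latent's importance in proportion to its normalised
weight — so a block's indicator importances sum exactly to the latent
importance.

Items are classified into the four classic quadrants relative to a crosshair
at the mean importance/mean performance (or user-supplied constants):
keep_up (high/high), concentrate_here (important but underperforming),
low_priority (low/low), possible_overkill (performing but unimportant).
Importance is plotted on x, performance on y; negative importances (negative
total effects) are retained with their sign, never clipped — interpret such
items with the indicator's coding direction in mind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, NumericalError, OutOfRangeError, SpecificationError
from .model_spec import ModelSpec

__all__ = [
    "RescaledData",
    "IpmaResult",
    "rescale",
    "normalized_unstandardized_weights",
    "performance_scores",
    "importance_scores",
    "quadrant_map",
    "ipma",
]

QUADRANTS = ("keep_up", "concentrate_here", "low_priority", "possible_overkill")


@dataclass
class RescaledData:
    """Indicator table mapped onto the 0-100 performance scale."""

    values: pd.DataFrame
    bounds_used: dict  # indicator -> (min, max, "empirical" | "theoretical")


@dataclass
class IpmaResult:
    """Importance-performance coordinates and quadrant labels.

    ``latent_points`` / ``indicator_points`` map each item to an
    (importance, performance) pair; the target latent and its indicators are
    excluded from the importance map.  Quadrants are assigned per level
    against that level's own crosshair.
    """

    target: str
    latent_points: dict
    indicator_points: dict
    quadrants: dict
    crosshair: tuple
    crosshair_latents: tuple
    performance: dict = field(default_factory=dict)  # includes the target latent

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, (imp, perf) in self.indicator_points.items():
            rows.append((name, "indicator", imp, perf, self.quadrants[name]))
        for name, (imp, perf) in self.latent_points.items():
            rows.append((name, "latent", imp, perf, self.quadrants[name]))
        return pd.DataFrame(
            rows, columns=["item", "level", "importance", "performance", "quadrant"]
        )

    def plot(self, level: str = "indicator", ax=None, flip_axes: bool = False):
        """Scatter the map with crosshair lines.

        ``flip_axes=True`` uses the classic-IPA convention (importance on the
        vertical axis) instead of the default importance-on-x layout.
        """
        import matplotlib.pyplot as plt

        points = self.indicator_points if level == "indicator" else self.latent_points
        cross = self.crosshair if level == "indicator" else self.crosshair_latents
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        for name, (imp, perf) in points.items():
            x, y = (perf, imp) if flip_axes else (imp, perf)
            ax.scatter([x], [y], zorder=3)
            ax.annotate(name, (x, y), textcoords="offset points", xytext=(4, 4), fontsize=8)
        cx, cy = (cross[1], cross[0]) if flip_axes else cross
        ax.axvline(cx, color="grey", lw=0.8)
        ax.axhline(cy, color="grey", lw=0.8)
        if flip_axes:
            ax.set_xlabel("performance (0-100)")
            ax.set_ylabel("importance (unstandardised total effect)")
        else:
            ax.set_xlabel("importance (unstandardised total effect)")
            ax.set_ylabel("performance (0-100)")
        ax.set_title(f"Importance-performance map -> {self.target}")
        return ax


def rescale(data: pd.DataFrame, bounds: Mapping[str, tuple] | None = None) -> RescaledData:
    """Map each column onto [0, 100] via (value - min)/(max - min) x 100.

    Columns without an entry in ``bounds`` use their empirical min/max.
    Theoretical bounds that the data violate raise :class:`OutOfRangeError`
    naming the offending indicator and row.
    """
    bounds = dict(bounds or {})
    out = {}
    used = {}
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        if col in bounds:
            lo, hi = map(float, bounds[col])
            source = "theoretical"
            if x.min() < lo or x.max() > hi:
                row = data.index[int(np.argmax((x < lo) | (x > hi)))]
                raise OutOfRangeError(
                    f"indicator {col!r}, row {row!r}: value outside theoretical "
                    f"bounds [{lo}, {hi}]"
                )
        else:
            lo, hi = float(x.min()), float(x.max())
            source = "empirical"
        if not lo < hi:
            raise DegenerateDataError(f"indicator {col!r}: min == max, cannot rescale")
        out[col] = (x - lo) / (hi - lo) * 100.0
        used[col] = (lo, hi, source)
    return RescaledData(pd.DataFrame(out, index=data.index), used)


def normalized_unstandardized_weights(
    fit_or_weights, spec: ModelSpec | None = None, rescaled: RescaledData | None = None
) -> dict:
    """Block-normalised unstandardised outer weights.

    The standardised (abs-sum-one) weight of each indicator is divided by
    the indicator's standard deviation on the rescaled 0-100 scale, then the
    block is normalised to sum to one, so a latent's 0-100 score is a
    weighted mean of its rescaled indicators.

    Accepts either a :class:`~plsipa.estimator.PLSPCAResults` (spec/rescaled
    derived from it) or an explicit weights mapping plus ``spec`` and
    ``rescaled``.
    """
    if hasattr(fit_or_weights, "weights") and hasattr(fit_or_weights, "spec"):
        results = fit_or_weights
        weights = results.weights
        spec = results.spec
        if rescaled is None:
            rescaled = rescale(results.data, spec.scale_bounds or None)
    else:
        weights = fit_or_weights
        if spec is None or rescaled is None:
            raise TypeError("spec and rescaled are required with a plain weights mapping")
    out = {}
    for lv in spec.latents:
        w = np.asarray([np.asarray(weights[lv.name])[k] for k in range(len(lv.indicators))])
        sd = rescaled.values.loc[:, list(lv.indicators)].std(ddof=1).to_numpy()
        if np.any(sd <= 0):
            raise DegenerateDataError(f"latent {lv.name!r}: rescaled indicator with zero spread")
        unstd = w / sd
        total = unstd.sum()
        if not total > 0:
            raise NumericalError(
                f"latent {lv.name!r}: unstandardised weights sum to {total:.3g} <= 0 "
                "(mixed-sign weights); 0-100 performance scores are undefined"
            )
        for ind, v in zip(lv.indicators, unstd / total):
            out[ind] = float(v)
    return out


def performance_scores(
    rescaled: RescaledData, norm_weights: Mapping[str, float], spec: ModelSpec
) -> tuple:
    """Mean rescaled value per indicator; weighted block mean per latent."""
    ind_perf = {c: float(rescaled.values[c].mean()) for c in rescaled.values.columns}
    lat_perf = {
        lv.name: float(sum(norm_weights[i] * ind_perf[i] for i in lv.indicators))
        for lv in spec.latents
    }
    return lat_perf, ind_perf


def unstandardized_scores(
    rescaled: RescaledData, norm_weights: Mapping[str, float], spec: ModelSpec
) -> pd.DataFrame:
    """0-100-scale latent scores: rescaled indicators x normalised weights."""
    out = {}
    for lv in spec.latents:
        v = np.array([norm_weights[i] for i in lv.indicators])
        out[lv.name] = rescaled.values.loc[:, list(lv.indicators)].to_numpy() @ v
    return pd.DataFrame(out, index=rescaled.values.index)


def _unstandardized_total_effects(scores_u: pd.DataFrame, spec: ModelSpec) -> dict:
    """Total effects from per-equation OLS (with intercept) on 0-100 scores."""
    from .estimator import _Compiled, _total_effects_matrix

    comp = _Compiled(spec)
    names = comp.latent_names
    U = scores_u.loc[:, list(names)].to_numpy(dtype=float)
    Uc = U - U.mean(axis=0)
    L = len(names)
    path = np.zeros((L, L))
    for j in range(L):
        pa = comp.parents[j]
        if not pa:
            continue
        X = Uc[:, pa]
        beta = np.linalg.lstsq(X, Uc[:, j], rcond=None)[0]
        path[pa, j] = beta
    tot = _total_effects_matrix(path)
    return {
        (names[s], names[t]): float(tot[s, t])
        for s in range(L)
        for t in range(L)
        if comp.reach[s, t]
    }


def importance_scores(
    fit, norm_weights: Mapping[str, float], target: str, rescaled: RescaledData | None = None
) -> tuple:
    """Unstandardised total effect on ``target`` per predecessor latent,
    apportioned to indicators by their normalised weights.

    The target latent and its own indicators are excluded.
    """
    spec = fit.spec
    if spec.role(target) != "endogenous":
        raise SpecificationError(f"IPMA target {target!r} must be endogenous")
    if rescaled is None:
        rescaled = rescale(fit.data, spec.scale_bounds or None)
    scores_u = unstandardized_scores(rescaled, norm_weights, spec)
    tot = _unstandardized_total_effects(scores_u, spec)
    lat_imp = {s: eff for (s, t), eff in tot.items() if t == target}
    ind_imp = {}
    for lv in spec.latents:
        if lv.name not in lat_imp:
            continue
        for ind in lv.indicators:
            ind_imp[ind] = norm_weights[ind] * lat_imp[lv.name]
    return lat_imp, ind_imp


def quadrant_map(points: Mapping[str, tuple], crosshair: tuple | None = None) -> tuple:
    """Classify (importance, performance) points into the four quadrants.

    The crosshair defaults to the means of the plotted items.  Points on a
    crosshair line go to the higher-importance / higher-performance side
    (>= convention).
    """
    if not points:
        raise ValueError("quadrant_map needs at least one point")
    if crosshair is None:
        imp = np.array([p[0] for p in points.values()], dtype=float)
        perf = np.array([p[1] for p in points.values()], dtype=float)
        crosshair = (float(imp.mean()), float(perf.mean()))
    cx, cy = crosshair
    labels = {}
    for name, (i, p) in points.items():
        if i >= cx:
            labels[name] = "keep_up" if p >= cy else "concentrate_here"
        else:
            labels[name] = "possible_overkill" if p >= cy else "low_priority"
    return labels, crosshair


def ipma(
    fit,
    target: str | None = None,
    bounds: Mapping[str, tuple] | None = None,
    crosshair: tuple | None = None,
) -> IpmaResult:
    """Full importance-performance analysis for a fitted model."""
    spec = fit.spec
    target = target or spec.ipma_target
    if target is None:
        raise SpecificationError("no IPMA target: pass target= or set ipma_target in the spec")
    if bounds is None:
        bounds = spec.scale_bounds or None
    rescaled = rescale(fit.data, bounds)
    norm_w = normalized_unstandardized_weights(fit.weights, spec, rescaled)
    lat_perf, ind_perf = performance_scores(rescaled, norm_w, spec)
    lat_imp, ind_imp = importance_scores(fit, norm_w, target, rescaled)
    if not lat_imp:
        import warnings

        warnings.warn(f"IPMA target {target!r} has no predecessors; empty map", stacklevel=2)
    latent_points = {k: (lat_imp[k], lat_perf[k]) for k in lat_imp}
    indicator_points = {k: (ind_imp[k], ind_perf[k]) for k in ind_imp}
    quadrants = {}
    cross_ind = crosshair
    cross_lat = crosshair
    if indicator_points:
        q_ind, cross_ind = quadrant_map(indicator_points, crosshair)
        quadrants.update(q_ind)
    if latent_points:
        q_lat, cross_lat = quadrant_map(latent_points, crosshair)
        quadrants.update(q_lat)
    return IpmaResult(
        target=target,
        latent_points=latent_points,
        indicator_points=indicator_points,
        quadrants=quadrants,
        crosshair=cross_ind if cross_ind is not None else (np.nan, np.nan),
        crosshair_latents=cross_lat if cross_lat is not None else (np.nan, np.nan),
        performance=lat_perf,
    )
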