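"""Structural and measurement model specification.

A composite SEM is declared as a set of latent variables, each measured by a
block of observed indicators (reflective or formative mode), plus a directed
acyclic graph of structural paths between latents.  The specification is pure
data, independent of any dataset: ``ModelSpec`` validates itself on
construction and can round-trip through a JSON document.

Latent roles are *derived* from the adjacency, never user-declared: a latent
with no incoming path is exogenous, any path target is endogenous.  This rules
out contradictory declarations by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CycleError, SpecificationError

__all__ = [
    "LatentVariable",
    "StructuralAdjacency",
    "ModelSpec",
    "parse_model_spec",
    "topological_order",
]

_MODES = ("reflective", "formative")


@dataclass(frozen=True)
class LatentVariable:
    """One latent construct and its measurement block.

    Parameters
    ----------
    name : str
        Unique latent name.
    indicators : tuple of str
        Ordered, non-empty block of indicator (column) names.
    mode : {"reflective", "formative"}
        Measurement mode.  Defaults to reflective; evaluation statistics
        (AVE, composite reliability) are only defined for reflective blocks.
    """

    name: str
    indicators: tuple
    mode: str = "reflective"

    def __post_init__(self):
        if not self.name:
            raise SpecificationError("latent variable name must be non-empty")
        if self.mode not in _MODES:
            raise SpecificationError(
                f"latent {self.name!r}: mode must be one of {_MODES}, got {self.mode!r}"
            )
        inds = tuple(self.indicators)
        object.__setattr__(self, "indicators", inds)
        if len(inds) == 0:
            raise SpecificationError(f"latent {self.name!r} has an empty indicator block")
        if len(set(inds)) != len(inds):
            raise SpecificationError(f"latent {self.name!r} lists a duplicate indicator")


@dataclass(frozen=True)
class StructuralAdjacency:
    """Directed structural paths between latent variables.

    ``paths`` is an ordered tuple of (source, target) pairs.  The graph must
    be acyclic (the model is recursive and estimated equation by equation).
    """

    paths: tuple

    def __post_init__(self):
        object.__setattr__(self, "paths", tuple((str(s), str(t)) for s, t in self.paths))
        seen = set()
        for p in self.paths:
            if p in seen:
                raise SpecificationError(f"duplicate path {p[0]!r} -> {p[1]!r}")
            if p[0] == p[1]:
                raise CycleError([p[0]])
            seen.add(p)

    def parents(self, latent: str) -> tuple:
        return tuple(s for s, t in self.paths if t == latent)

    def children(self, latent: str) -> tuple:
        return tuple(t for s, t in self.paths if s == latent)


class ModelSpec:
    """Validated full model: latents, adjacency, optional IPMA target/bounds.

    Invariants enforced on construction:

    * every indicator belongs to exactly one latent;
    * every path endpoint is a declared latent;
    * the structural graph is acyclic;
    * ``ipma_target``, when given, is an endogenous latent;
    * ``scale_bounds`` entries satisfy min < max and name known indicators.
    """

    def __init__(
        self,
        latents: Sequence[LatentVariable],
        adjacency: StructuralAdjacency | Iterable = (),
        ipma_target: str | None = None,
        scale_bounds: Mapping[str, tuple] | None = None,
    ):
        self.latents = tuple(latents)
        if not isinstance(adjacency, StructuralAdjacency):
            adjacency = StructuralAdjacency(tuple(adjacency))
        self.adjacency = adjacency
        self.ipma_target = ipma_target
        self.scale_bounds = {k: (float(v[0]), float(v[1])) for k, v in (scale_bounds or {}).items()}
        self._validate()

    # -- validation -----------------------------------------------------
    def _validate(self):
        names = [lv.name for lv in self.latents]
        if len(set(names)) != len(names):
            raise SpecificationError("latent names must be unique")
        owner: dict = {}
        for lv in self.latents:
            for ind in lv.indicators:
                if ind in owner:
                    raise SpecificationError(
                        f"indicator {ind!r} assigned to both {owner[ind]!r} and {lv.name!r}"
                    )
                owner[ind] = lv.name
        known = set(names)
        for s, t in self.adjacency.paths:
            for endpoint in (s, t):
                if endpoint not in known:
                    raise SpecificationError(f"path references unknown latent {endpoint!r}")
        self._order = _toposort(names, self.adjacency.paths)  # raises CycleError
        if self.ipma_target is not None:
            if self.ipma_target not in known:
                raise SpecificationError(f"ipma_target {self.ipma_target!r} is not a latent")
            if self.role(self.ipma_target) != "endogenous":
                raise SpecificationError(
                    f"ipma_target {self.ipma_target!r} must be endogenous (have an incoming path)"
                )
        for ind, (lo, hi) in self.scale_bounds.items():
            if ind not in owner:
                raise SpecificationError(f"scale_bounds names unknown indicator {ind!r}")
            if not lo < hi:
                raise SpecificationError(f"scale_bounds for {ind!r}: need min < max, got {lo}, {hi}")
        for lv in self.latents:
            if lv.mode == "formative":
                warnings.warn(
                    f"latent {lv.name!r} is declared formative; reflective evaluation "
                    "statistics (AVE, composite reliability) will not be reported for it",
                    stacklevel=3,
                )

    # -- derived structure ----------------------------------------------
    @property
    def latent_names(self) -> tuple:
        return tuple(lv.name for lv in self.latents)

    @property
    def indicator_names(self) -> tuple:
        return tuple(ind for lv in self.latents for ind in lv.indicators)

    def latent(self, name: str) -> LatentVariable:
        for lv in self.latents:
            if lv.name == name:
                return lv
        raise KeyError(name)

    def owner_of(self, indicator: str) -> str:
        for lv in self.latents:
            if indicator in lv.indicators:
                return lv.name
        raise KeyError(indicator)

    def role(self, name: str) -> str:
        """'endogenous' if the latent has at least one incoming path."""
        self.latent(name)
        return "endogenous" if self.adjacency.parents(name) else "exogenous"

    @property
    def endogenous(self) -> tuple:
        return tuple(n for n in self.latent_names if self.role(n) == "endogenous")

    @property
    def exogenous(self) -> tuple:
        return tuple(n for n in self.latent_names if self.role(n) == "exogenous")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "latents": [
                {"name": lv.name, "mode": lv.mode, "indicators": list(lv.indicators)}
                for lv in self.latents
            ],
            "paths": [list(p) for p in self.adjacency.paths],
        }
        if self.ipma_target is not None:
            d["ipma_target"] = self.ipma_target
        if self.scale_bounds:
            d["scale_bounds"] = {k: list(v) for k, v in self.scale_bounds.items()}
        return d

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        try:
            raw_latents = d["latents"]
        except KeyError:
            raise SpecificationError("model config must have a 'latents' section") from None
        latents = []
        for entry in raw_latents:
            latents.append(
                LatentVariable(
                    name=str(entry["name"]),
                    indicators=tuple(str(i) for i in entry["indicators"]),
                    mode=str(entry.get("mode", "reflective")),
                )
            )
        paths = tuple((str(s), str(t)) for s, t in d.get("paths", ()))
        return cls(
            latents,
            StructuralAdjacency(paths),
            ipma_target=d.get("ipma_target"),
            scale_bounds=d.get("scale_bounds"),
        )

    def __eq__(self, other):
        return isinstance(other, ModelSpec) and self.to_dict() == other.to_dict()

    def __repr__(self):
        return (
            f"ModelSpec({len(self.latents)} latents, {len(self.indicator_names)} indicators, "
            f"{len(self.adjacency.paths)} paths)"
        )


def parse_model_spec(document: str) -> ModelSpec:
    """Parse a JSON model configuration into a validated :class:`ModelSpec`.

    The document has top-level keys ``latents`` (list of objects with
    ``name``, optional ``mode``, ``indicators``), ``paths`` (list of
    ``[source, target]`` pairs), optional ``ipma_target`` and
    ``scale_bounds``.  Indicator names are case-sensitive and must match the
    data's CSV column headers exactly.
    """
    try:
        d = json.loads(document)
    except json.JSONDecodeError as exc:
        raise SpecificationError(f"model config is not valid JSON: {exc}") from exc
    if not isinstance(d, Mapping):
        raise SpecificationError("model config must be a JSON object")
    return ModelSpec.from_dict(d)


def topological_order(spec: ModelSpec) -> list:
    """Latent names ordered so every path source precedes its target.

    Deterministic: among the latents available at each step, declaration
    order breaks ties (Kahn's algorithm with a declaration-ordered frontier).
    """
    return list(spec._order)


def _toposort(names: Sequence[str], paths: Iterable) -> tuple:
    incoming = {n: set() for n in names}
    outgoing = {n: set() for n in names}
    for s, t in paths:
        incoming[t].add(s)
        outgoing[s].add(t)
    remaining = list(names)
    order = []
    while remaining:
        for n in remaining:
            if not incoming[n]:
                break
        else:
            raise CycleError(_find_cycle(remaining, incoming))
        order.append(n)
        remaining.remove(n)
        for t in outgoing[n]:
            incoming[t].discard(n)
    return tuple(order)


def _find_cycle(nodes, incoming):
    # every remaining node has a remaining predecessor, so a backward walk
    # must revisit a node; the revisited segment, reversed, is a cycle
    node = nodes[0]
    trail = [node]
    seen = {node: 0}
    while True:
        node = next(iter(incoming[node]))
        if node in seen:
            return list(reversed(trail[seen[node]:]))
        seen[node] = len(trail)
        trail.append(node)
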