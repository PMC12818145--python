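"""File I/O, pruning, the full pipeline, and the run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import PlsIpaError, SchemaError, SpecificationError
from .model_spec import LatentVariable, ModelSpec, parse_model_spec

log = logging.getLogger("plsipa")

__all__ = ["read_indicator_csv", "RunManifest", "prune_spec", "run_pipeline"]


def read_indicator_csv(path, spec: ModelSpec, id_column: str | None = None) -> pd.DataFrame:
    """Read an observation-by-indicator CSV, matched to the model by header.

    Columns are matched to model indicators by exact (case-sensitive) name
    and reordered to model order; extra columns are ignored with a warning.
    ``id_column`` names a non-indicator identifier column to use as the row
    index.  Decimal points only (locale-independent parsing).
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    if id_column is not None:
        if id_column not in raw.columns:
            raise SchemaError(f"id column {id_column!r} not found in {path}")
        raw = raw.set_index(id_column)
    missing = [c for c in spec.indicator_names if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing indicator column(s): {missing}")
    extra = [c for c in raw.columns if c not in spec.indicator_names]
    if extra:
        warnings.warn(f"{path}: ignoring non-model column(s) {extra}", stacklevel=2)
    data = raw.loc[:, list(spec.indicator_names)]
    for col in data.columns:
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = data.index[coerced.isna() & ~data[col].isna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric cell in column {col!r}, row {bad[0]!r}"
            )
        blank = data.index[coerced.isna()]
        if len(blank):
            raise SchemaError(f"{path}: blank cell in column {col!r}, row {blank[0]!r}")
        data[col] = coerced
    return data


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run."""

    data_path: str
    model_path: str
    model_hash: str
    seed: int | None
    B: int | None
    alpha: float
    pruned_indicators: dict = field(default_factory=dict)  # indicator -> reason
    pruning_enabled: bool = True
    version: str = __version__

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def prune_spec(spec: ModelSpec, results, boot: dict, threshold: float = 0.5, alpha: float = 0.05):
    """Drop indicators that are invalid (loading <= threshold) or whose
    loading is not bootstrap-significant; returns (new_spec, reasons).

    Single-indicator blocks are never pruned (their loading is fixed at 1
    and carries no sampling variability).  Emptied multi-indicator blocks
    raise :class:`SpecificationError` — the model cannot lose a construct.
    """
    reasons = {}
    new_latents = []
    for lv in spec.latents:
        if len(lv.indicators) == 1:
            new_latents.append(lv)
            continue
        keep = []
        for ind in lv.indicators:
            loading = float(results.loadings[ind])
            why = []
            if loading <= threshold:
                why.append(f"loading {loading:.3f} <= {threshold}")
            br = boot.get(f"lambda:{ind}") if boot else None
            if br is not None and br.testable and not br.significant:
                why.append(f"not significant (p = {br.p_value:.3f})")
            if why:
                reasons[ind] = "; ".join(why)
            else:
                keep.append(ind)
        if not keep:
            raise SpecificationError(
                f"pruning would remove every indicator of {lv.name!r} "
                f"({dict((i, reasons[i]) for i in lv.indicators)}); "
                "relax the threshold or revise the measurement block"
            )
        new_latents.append(LatentVariable(lv.name, tuple(keep), lv.mode))
    new_spec = ModelSpec(
        new_latents,
        spec.adjacency,
        ipma_target=spec.ipma_target,
        scale_bounds={k: v for k, v in spec.scale_bounds.items() if k not in reasons},
    )
    return new_spec, reasons


def run_pipeline(
    data_path,
    model_path,
    out_dir,
    B: int = 2000,
    seed: int = 42,
    alpha: float = 0.05,
    prune: bool = True,
    bounds_path=None,
) -> dict:
    """fit -> evaluate -> bootstrap -> (optional) prune+refit -> IPMA.

    Writes ``evaluation.json``/``evaluation.txt``, ``bootstrap.csv``,
    ``ipma.csv`` (when the model names an IPMA target) and
    ``manifest.json`` under ``out_dir``.  Any stage failure removes partial
    outputs and re-raises with a stage tag.
    """
    from .bootstrap import bootstrap_fit, bootstrap_table
    from .estimator import PLSPCAModel

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    stage = "setup"
    try:
        model_text = Path(model_path).read_text()
        spec = parse_model_spec(model_text)
        if bounds_path is not None:
            bounds = json.loads(Path(bounds_path).read_text())
            spec = ModelSpec(
                spec.latents, spec.adjacency, ipma_target=spec.ipma_target, scale_bounds=bounds
            )
        data = read_indicator_csv(data_path, spec)

        stage = "fit"
        t0 = time.perf_counter()
        results = PLSPCAModel(data, spec).fit()
        for name, ext in results.pca.items():
            log.info("fit: block %s explained variance %.3f", name, ext.explained_proportion)
        log.info("fit: done in %.3fs", time.perf_counter() - t0)

        stage = "evaluate"
        report = results.evaluate()
        _write(out_dir / "evaluation.json", json.dumps(report.to_dict(), indent=2), written)
        _write(out_dir / "evaluation.txt", report.summary(), written)

        stage = "bootstrap"
        t0 = time.perf_counter()
        boot = bootstrap_fit(data, spec, B=B, seed=seed, alpha=alpha, results=results)
        meta = boot["__meta__"]
        log.info(
            "bootstrap: B=%d kept=%d discarded=%d in %.2fs",
            meta["B"], meta["kept"], meta["discarded"], time.perf_counter() - t0,
        )
        bootstrap_table(boot).to_csv(out_dir / "bootstrap.csv", index=False)
        written.append(out_dir / "bootstrap.csv")

        pruned = {}
        if prune:
            stage = "prune"
            spec2, pruned = prune_spec(spec, results, boot, alpha=alpha)
            if pruned:
                log.info("prune: removed %s", pruned)
                stage = "refit"
                data2 = data.loc[:, list(spec2.indicator_names)]
                results = PLSPCAModel(data2, spec2).fit()
            else:
                spec2 = spec
        else:
            spec2 = spec

        ipma_res = None
        if spec2.ipma_target is not None:
            stage = "ipma"
            ipma_res = results.ipma()
            ipma_res.to_frame().to_csv(out_dir / "ipma.csv", index=False)
            written.append(out_dir / "ipma.csv")

        stage = "manifest"
        manifest = RunManifest(
            data_path=str(data_path),
            model_path=str(model_path),
            model_hash=hashlib.sha256(model_text.encode()).hexdigest(),
            seed=seed,
            B=B,
            alpha=alpha,
            pruned_indicators=pruned,
            pruning_enabled=prune,
        )
        manifest.to_json(out_dir / "manifest.json")
        written.append(out_dir / "manifest.json")
        return {
            "results": results,
            "evaluation": report,
            "bootstrap": boot,
            "ipma": ipma_res,
            "manifest": manifest,
            "pruned": pruned,
        }
    except PlsIpaError as exc:
        for p in written:
            Path(p).unlink(missing_ok=True)
        exc.args = (f"[stage: {stage}] {exc}",)
        raise


def _write(path: Path, text: str, written: list):
    path.write_text(text + "\n")
    written.append(path)
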