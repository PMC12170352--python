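"""End-to-end orchestration: transform -> zones -> metrics -> shapes, plus the
full-vs-XRF-only robustness comparison and a reproducibility manifest.

A run is described by one structured config (YAML or JSON) mirroring
:class:`~elemtraj.core.AnalysisConfig` plus input/output locations.  Every
stage writes a flat CSV; a JSON manifest recording the config, input hashes,
package version, seed and per-stage outputs is written only when all
requested stages succeed, so a manifest's presence certifies a complete,
reproducible run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import AnalysisConfig, ElementRecord, read_record, write_record, write_table
from .shapes import ShapeMetrics, explored_area, pca, three_centroid_length, write_shapes
from .synthetic import generate, preset, with_seed, write_truth
from .trajectory import compute_metrics, write_metrics
from .transform import ElementSubsetSpec, sqrt_minmax
from .zonation import ZoneComparison, compare_zonations, coniss, cut_zones, write_zonation

logger = logging.getLogger(__name__)

STAGES = ("transform", "zones", "metrics", "shapes", "compare_subsets")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunManifest:
    """Provenance of one completed pipeline run."""

    config: dict
    input_hashes: dict[str, str]
    version: str
    seed: int
    outputs: dict[str, dict] = field(default_factory=dict)

    def add_output(self, stage: str, path: Path, rows: int) -> None:
        self.outputs[stage] = {"path": str(path), "rows": rows}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise PipelineError(f"config {path} did not parse to a mapping")
    return dict(cfg)


def analysis_config(cfg: Mapping[str, Any]) -> AnalysisConfig:
    """Build an AnalysisConfig from the ``analysis:`` section of a run config."""
    section = dict(cfg.get("analysis", {}))
    if "seed" in cfg:
        section.setdefault("rng_seed", int(cfg["seed"]))
    return AnalysisConfig(**section)


def subset_spec(cfg: Mapping[str, Any]) -> ElementSubsetSpec:
    raw = cfg.get("subset", "all")
    if isinstance(raw, str) and raw in ("all", "xrf_only"):
        return ElementSubsetSpec(raw)
    if isinstance(raw, str):
        raw = [e.strip() for e in raw.split(",") if e.strip()]
    return ElementSubsetSpec("explicit", tuple(raw))


def _load_input(cfg: Mapping[str, Any], outdir: Path, manifest: RunManifest) -> ElementRecord:
    if "input" in cfg:
        path = Path(cfg["input"])
        manifest.input_hashes[str(path)] = _sha256(path)
        return read_record(path, record_id=cfg.get("record_id"))
    if "preset" in cfg:
        spec = preset(cfg["preset"])
        if "seed" in cfg:
            spec = with_seed(spec, int(cfg["seed"]))
        record, truth = generate(spec)
        truth_path = outdir / "truth.csv"
        write_truth(truth, record.ages, truth_path)
        manifest.add_output("simulate_truth", truth_path, record.n_samples)
        return record
    raise PipelineError("config needs either 'input: <path>' or 'preset: <name>'")


def record_shapes(
    trec, acfg: AnalysisConfig, scores2: np.ndarray | None = None
) -> ShapeMetrics:
    """Shape metrics of one transformed record.

    ``scores2`` are the record's scores on the first two axes of a shared
    (pooled) ordination when available; otherwise a per-record PCA is used.
    """
    if scores2 is None:
        scores2 = pca(trec.values, elements=trec.elements).scores[:, :2]
    area = explored_area(scores2, level=acfg.ellipse_level)
    z3 = cut_zones(coniss(trec), 3)
    length = three_centroid_length(trec, z3, mode=acfg.centroid_length_mode)
    return ShapeMetrics(
        record_id=trec.record_id,
        explored_area=area,
        three_centroid_length=length,
        centroid_mode=acfg.centroid_length_mode,
        ellipse_kind="norm",
    )


def compare_subsets(
    record: ElementRecord, acfg: AnalysisConfig
) -> tuple[ZoneComparison, pd.DataFrame]:
    """Zonation and metric agreement between the full and XRF-only elementomes.

    The record is transformed twice — with all elements and with the XRF
    subset (C/N dropped) — and zoned and measured identically under both.
    Returns the breakpoint-offset/Rand-agreement comparison and a long table
    of per-window metric values under both subsets with their difference.
    """
    if not {"C", "N"} <= set(record.elements):
        raise ValueError("compare_subsets needs a record containing C and N")
    t_all = sqrt_minmax(record, ElementSubsetSpec("all"))
    t_xrf = sqrt_minmax(record, ElementSubsetSpec("xrf_only"))
    z_all = cut_zones(coniss(t_all), acfg.n_zones)
    z_xrf = cut_zones(coniss(t_xrf), acfg.n_zones)
    comparison = compare_zonations(z_all, z_xrf)
    m_all = compute_metrics(t_all, acfg)
    m_xrf = compute_metrics(t_xrf, acfg)
    frames = []
    for metric in m_all:
        a = m_all[metric].rows
        b = m_xrf[metric].rows
        frames.append(
            pd.DataFrame(
                {
                    "metric": metric,
                    "center_age": a["center_age"],
                    "value_all": a["value"],
                    "value_xrf_only": b["value"],
                    "delta": b["value"] - a["value"],
                    "n": a["n"],
                }
            )
        )
    return comparison, pd.concat(frames, ignore_index=True)


def run_pipeline(config: str | Path | Mapping[str, Any], outdir: str | Path | None = None) -> RunManifest:
    """Run the requested stages end-to-end and write the manifest.

    Any stage failure aborts with the stage name and cause; the manifest is
    written only on full success.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(outdir or cfg.get("outdir", "."))
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(cfg.get("stages", ("transform", "zones", "metrics", "shapes")))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    acfg = analysis_config(cfg)
    manifest = RunManifest(
        config={k: v for k, v in cfg.items()},
        input_hashes={},
        version=__version__,
        seed=acfg.rng_seed,
    )
    stage = "load"
    try:
        record = _load_input(cfg, out, manifest)
        stage = "transform"
        trec = sqrt_minmax(record, subset_spec(cfg))
        tpath = out / "transformed.csv"
        write_record(trec, tpath)
        manifest.add_output("transform", tpath, trec.n_samples)

        zon_cut = None
        if "zones" in stages:
            stage = "zones"
            zon_cut = cut_zones(coniss(trec), acfg.n_zones)
            zpath, bpath = out / "zones.csv", out / "breakpoints.csv"
            write_zonation(zon_cut, zpath, bpath)
            manifest.add_output("zones", zpath, zon_cut.n_samples)
            manifest.add_output("breakpoints", bpath, len(zon_cut.breakpoints))

        if "metrics" in stages:
            stage = "metrics"
            series = compute_metrics(trec, acfg)
            mpath = out / "metrics.csv"
            write_metrics(series, mpath)
            manifest.add_output("metrics", mpath, sum(len(s.rows) for s in series.values()))

        if "shapes" in stages:
            stage = "shapes"
            shapes = [record_shapes(trec, acfg)]
            spath = out / "shapes.csv"
            write_shapes(shapes, spath)
            manifest.add_output("shapes", spath, len(shapes))

        if "compare_subsets" in stages:
            stage = "compare_subsets"
            comparison, deltas = compare_subsets(record, acfg)
            cpath, dpath = out / "subset_offsets.csv", out / "subset_metric_deltas.csv"
            write_table(comparison.to_frame(), cpath)
            write_table(deltas, dpath)
            manifest.add_output("compare_subsets", cpath, len(comparison.offsets))
            manifest.add_output("compare_subsets_deltas", dpath, len(deltas))
            (out / "subset_agreement.json").write_text(
                json.dumps({"rand_agreement": comparison.agreement}, indent=2) + "\n"
            )
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    manifest.write(out / "manifest.json")
    return manifest
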