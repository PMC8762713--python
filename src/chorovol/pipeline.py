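"""End-to-end orchestration: enhance -> slab -> segment -> quantify.

A single :class:`PipelineConfig` (serializable to/from JSON) records every
parameter of a run; identical config and inputs yield identical outputs.
Each stage logs one line (name, parameters, duration) and every
intermediate artifact is written to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import core_io, quantify, segment, slab
from .core_io import OCTVolume, SurfacePair, VesselMask
from .enhance import EnhanceConfig, enhance_pipeline
from .quantify import EtdrsGrid
from .segment import ThresholdParams

logger = logging.getLogger("chorovol")

__all__ = ["PipelineConfig", "run_all", "report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; one JSON file per run for reproducibility."""

    volume_path: str
    out_dir: str
    surfaces_path: Optional[str] = None  # None -> phantom-style detection
    extent_mm: Tuple[float, float] = core_io.DEFAULT_EXTENT_MM
    dz_mm: Optional[float] = None
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    params: ThresholdParams = field(default_factory=ThresholdParams)
    grid: EtdrsGrid = field(default_factory=EtdrsGrid)
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key, sub in (("enhance", EnhanceConfig), ("params", ThresholdParams), ("grid", EtdrsGrid)):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                for k, v in d.items():
                    if isinstance(v, list):
                        d[k] = tuple(v)
                raw[key] = sub(**d)
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)


def _timed(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    logger.info("stage=%s duration=%.2fs", name, time.perf_counter() - t0)
    return out


def run_all(config: PipelineConfig) -> pd.DataFrame:
    """Execute the full pipeline, writing every intermediate to ``out_dir``.

    Returns the per-region metrics table (also written as metrics.csv).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    vol = _timed(
        "read", core_io.read_volume, config.volume_path, extent=config.extent_mm, dz=config.dz_mm
    )
    if config.surfaces_path is not None:
        surfaces = core_io.read_surfaces(config.surfaces_path)
    else:
        surfaces = _timed("detect_surfaces", slab.detect_surfaces_phantom, vol)
    surfaces.validate_against(vol.shape)
    core_io.write_surfaces(surfaces, out / "surfaces.csv")

    enhanced = _timed("enhance", enhance_pipeline, vol, config.enhance)
    core_io.write_volume(enhanced, out / "enhanced.nii.gz")

    mask = _timed("segment", segment.segment_vessels, enhanced, surfaces, config.params)
    core_io.write_volume(
        OCTVolume(mask.labels.astype(np.float64), vol.spacing), out / "vessel_mask.nii.gz"
    )

    vv_map = quantify.vessel_volume_map(mask, vol.spacing)
    vc_map = quantify.choroid_volume_map(surfaces, vol.spacing)
    core_io.write_map(vv_map, out / "vessel_volume_map.csv")
    core_io.write_map(vc_map, out / "choroid_volume_map.csv")
    metrics = _timed("quantify", quantify.region_metrics, vv_map, vc_map, config.grid)
    metrics.to_csv(out / "metrics.csv", index=False)
    return metrics


def report(metrics: pd.DataFrame, roc_results: Optional[dict] = None, config=None) -> str:
    """Render a markdown summary of regional metrics and optional ROC results."""
    lines = ["# Choroidal quantification report", ""]
    if config is not None:
        lines += ["## Parameters", "```json", json.dumps(dataclasses.asdict(config), indent=2), "```", ""]
    lines += ["## Regional metrics (ETDRS)", ""]
    ordered = metrics.sort_values("region").reset_index(drop=True)
    cols = list(ordered.columns)
    lines.append("| " + " | ".join(cols) + " |")
    lines.append("|" + "|".join("---" for _ in cols) + "|")
    for _, row in ordered.iterrows():
        cells = [f"{v:.4f}" if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    if roc_results:
        lines += ["## Diagnostic statistics", ""]
        for name in sorted(roc_results):
            res = roc_results[name]
            lines.append(f"- **{name}**: " + ", ".join(f"{k}={v:.4g}" for k, v in res.items()))
        lines.append("")
    return "\n".join(lines)
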