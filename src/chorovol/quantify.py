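"""Quantitative en-face maps and ETDRS regional aggregation.

Volumes follow the pixel-counting rule throughout: a map value is the
number of counted voxels under each A-line multiplied by the voxel volume,
so the sum of any map equals (count x voxel volume) exactly.  The vessel
index is the percentage ratio of vessel volume to total choroidal volume,
reported on aggregated volumes (ratio of sums).

The ETDRS grid is the standard macular chart: a central 1-mm-diameter
subfield, an inner ring (1-3 mm) and an outer ring (3-6 mm), the rings
split into superior / inferior / nasal / temporal quadrants at +-45 deg to
the horizontal (fast) axis.  An A-line belongs to a region iff its
footprint centre lies inside; the "6-mm circle" aggregate is the union of
all subfields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core_io import EnFaceMap, SurfacePair, VesselMask

__all__ = [
    "EtdrsGrid",
    "vessel_volume_map",
    "choroid_volume_map",
    "etdrs_aggregate",
    "region_metrics",
    "vessel_index",
    "render_map",
]


@dataclass(frozen=True)
class EtdrsGrid:
    """ETDRS grid geometry over the lateral scan plane.

    ``center_mm`` is (slow-axis, fast-axis) position of the fovea in mm;
    ``None`` defaults to the scan centre.  ``laterality`` controls which
    horizontal side is nasal: for a right eye (OD) the nasal retina lies at
    increasing fast-axis coordinate, for a left eye (OS) at decreasing.
    """

    center_mm: Optional[Tuple[float, float]] = None
    ring_diameters_mm: Tuple[float, float, float] = (1.0, 3.0, 6.0)
    laterality: str = "OD"

    def __post_init__(self) -> None:
        d = self.ring_diameters_mm
        if not (0 < d[0] < d[1] < d[2]):
            raise ValueError("ring diameters must be strictly increasing and positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")


def vessel_volume_map(mask: VesselMask, spacing: Tuple[float, float, float]) -> EnFaceMap:
    """Vessel volume per A-line footprint, in mm^3."""
    db, da, dz = spacing
    counts = mask.labels.sum(axis=2)
    return EnFaceMap(counts * (db * da * dz), "mm3", (db, da))


def choroid_volume_map(
    surfaces: SurfacePair,
    spacing: Tuple[float, float, float],
    thickness: bool = False,
) -> EnFaceMap:
    """Choroidal volume (mm^3) or thickness (mm) per A-line footprint."""
    db, da, dz = spacing
    t = surfaces.thickness()
    if thickness:
        return EnFaceMap(t * dz, "mm", (db, da))
    return EnFaceMap(t * (db * da * dz), "mm3", (db, da))


def _region_masks(emap: EnFaceMap, grid: EtdrsGrid) -> Dict[str, np.ndarray]:
    nb, na = emap.shape
    db, da = emap.spacing
    if grid.center_mm is None:
        cb, ca = nb * db / 2.0, na * da / 2.0
    else:
        cb, ca = grid.center_mm
    if not (0 <= cb <= nb * db and 0 <= ca <= na * da):
        raise ValueError("grid centre lies outside the scan extent")
    b = (np.arange(nb) + 0.5) * db - cb
    a = (np.arange(na) + 0.5) * da - ca
    bb, aa = np.meshgrid(b, a, indexing="ij")
    r = np.hypot(bb, aa)

    r0, r1, r2 = (d / 2.0 for d in grid.ring_diameters_mm)
    central = r < r0
    inner = (r >= r0) & (r < r1)
    outer = (r >= r1) & (r < r2)

    # quadrants at +-45 deg to the horizontal (fast) axis; slow axis grows
    # downward in image coordinates, so negative bb is superior
    horizontal = np.abs(aa) >= np.abs(bb)
    superior = ~horizontal & (bb < 0)
    inferior = ~horizontal & (bb >= 0)
    right = horizontal & (aa >= 0)
    left = horizontal & (aa < 0)
    nasal, temporal = (right, left) if grid.laterality == "OD" else (left, right)

    regions: Dict[str, np.ndarray] = {"central": central}
    for ring_name, ring in (("inner", inner), ("outer", outer)):
        for quad_name, quad in (
            ("superior", superior),
            ("inferior", inferior),
            ("nasal", nasal),
            ("temporal", temporal),
        ):
            regions[f"{ring_name}_{quad_name}"] = ring & quad
    regions["inner"] = inner
    regions["outer"] = outer
    regions["circle_6mm"] = r < r2
    return regions


def etdrs_aggregate(emap: EnFaceMap, grid: EtdrsGrid = EtdrsGrid()) -> pd.Series:
    """Sum an en-face map over each ETDRS region.

    Returns a Series indexed by region name (central, the eight ring
    quadrants, and the inner / outer / circle_6mm aggregates).  The nine
    disjoint subfields sum exactly to circle_6mm.
    """
    regions = _region_masks(emap, grid)
    return pd.Series(
        {name: float(emap.values[m].sum()) for name, m in regions.items()},
        name=emap.units,
    )


def vessel_index(vv_mm3: float, vc_mm3: float) -> float:
    """Vessel index: 100 * vessel volume / choroidal volume (percent).

    Returns NaN (the undefined flag) when the choroidal volume is zero.
    """
    if vc_mm3 < 0 or vv_mm3 < 0:
        raise ValueError("volumes must be non-negative")
    if vc_mm3 == 0:
        return float("nan")
    return 100.0 * vv_mm3 / vc_mm3


def region_metrics(
    vessel_map: EnFaceMap,
    choroid_map: EnFaceMap,
    grid: EtdrsGrid = EtdrsGrid(),
) -> pd.DataFrame:
    """Per-region choroidal volume, vessel volume and vessel index.

    Columns: ``region, Vc_mm3, Vv_mm3, VI_percent``; the index is reported
    on aggregated volumes (ratio of regional sums).
    """
    if vessel_map.shape != choroid_map.shape:
        raise ValueError("vessel and choroid maps must be congruent")
    vv = etdrs_aggregate(vessel_map, grid)
    vc = etdrs_aggregate(choroid_map, grid)
    rows = [
        {
            "region": name,
            "Vc_mm3": vc[name],
            "Vv_mm3": vv[name],
            "VI_percent": vessel_index(vv[name], vc[name]),
        }
        for name in vv.index
    ]
    return pd.DataFrame(rows)


_COLORMAPS = {"warm": "hot", "cool": "cool"}


def render_map(
    emap: EnFaceMap,
    path,
    colormap: str = "warm",
    limits: Optional[Tuple[float, float]] = None,
) -> None:
    """Render an en-face map to PNG with a physical-unit colorbar.

    ``limits`` fixes the colour scale; pass the same limits across calls to
    make maps directly comparable (identical colorbars).  The warm map
    highlights vasculature; the cool map suits volume-change reading.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if colormap not in _COLORMAPS:
        raise ValueError(f"colormap must be one of {sorted(_COLORMAPS)}")
    if limits is not None and not (limits[0] < limits[1]):
        raise ValueError("limits must be an increasing pair")
    vmin, vmax = limits if limits is not None else (0.0, float(emap.values.max()) or 1.0)
    nb, na = emap.shape
    db, da = emap.spacing
    fig, ax = plt.subplots(figsize=(6, 6 * nb * db / (na * da)))
    im = ax.imshow(
        emap.values,
        cmap=_COLORMAPS[colormap],
        vmin=vmin,
        vmax=vmax,
        extent=(0, na * da, nb * db, 0),
        interpolation="nearest",
    )
    ax.set_xlabel("fast axis (mm)")
    ax.set_ylabel("slow axis (mm)")
    fig.colorbar(im, ax=ax, label=emap.units)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
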