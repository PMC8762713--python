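"""Choroid slab geometry: BM flattening, slab extraction and C-scan views.

Flattening applies an integer axial shift per A-line so that Bruch's
membrane sits at one constant reference depth; C-scans are then en-face
slices at fixed offsets below the flattened BM, i.e. at constant physical
depth below the membrane.  Integer shifts (no interpolation) keep voxel
counting conservative: the slab's voxel count is identical before and after
flattening, so pixel-based volumes are unaffected.

For real scans the BM/CSI surfaces are *inputs* (produced by a device's
layer segmentation and manual review); :func:`detect_surfaces_phantom` is a
gradient-based finder adequate only for the high-contrast synthetic layer
stacks produced by :mod:`chorovol.phantom`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core_io import OCTVolume, SurfacePair, slab_mask

__all__ = [
    "FlattenedVolume",
    "flatten",
    "unflatten",
    "extract_slab",
    "cscan",
    "detect_surfaces_phantom",
]


@dataclass(frozen=True)
class FlattenedVolume:
    """A volume re-indexed in depth so that BM is constant.

    ``shift[b, a]`` is the signed number of voxels each A-line was moved
    toward greater depth; ``surfaces`` are the flattened surfaces (BM equal
    to ``reference_depth`` everywhere).
    """

    intensities: np.ndarray
    spacing: Tuple[float, float, float]
    reference_depth: int
    shift: np.ndarray
    surfaces: SurfacePair

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape

    def as_volume(self) -> OCTVolume:
        return OCTVolume(np.clip(self.intensities, 0.0, None), self.spacing)


def _shift_axial(arr: np.ndarray, shift: np.ndarray, fill=0) -> np.ndarray:
    """Shift each A-line ``arr[b, a, :]`` by ``shift[b, a]`` voxels (positive
    = deeper), filling vacated voxels with ``fill``."""
    nb, na, nz = arr.shape
    z = np.arange(nz)
    src = z[None, None, :] - shift[:, :, None]
    valid = (src >= 0) & (src < nz)
    out = np.take_along_axis(arr, np.clip(src, 0, nz - 1), axis=2)
    out[~valid] = fill
    return out


def flatten(
    vol: OCTVolume, surfaces: SurfacePair, reference_depth: Optional[int] = None
) -> FlattenedVolume:
    """Flatten the volume with respect to BM by integer per-A-line shifts.

    The default reference depth is the maximum BM depth, which guarantees no
    slab voxel is pushed off the shallow end; a depth-overflow check
    guarantees none is pushed off the deep end either.
    """
    surfaces.validate_against(vol.shape)
    nz = vol.shape[2]
    if reference_depth is None:
        reference_depth = int(surfaces.bm.max())
    if not (0 <= reference_depth < nz):
        raise ValueError(f"reference_depth {reference_depth} outside [0, {nz})")
    shift = reference_depth - surfaces.bm
    if int((surfaces.csi + shift).max()) > nz:
        raise ValueError("flattening would push the slab beyond the depth axis")
    flat = _shift_axial(vol.intensities, shift)
    flat_surfaces = SurfacePair(surfaces.bm + shift, surfaces.csi + shift)
    return FlattenedVolume(flat, vol.spacing, reference_depth, shift, flat_surfaces)


def unflatten(flat: FlattenedVolume, arr: Optional[np.ndarray] = None) -> np.ndarray:
    """Invert the flattening shifts (identity on the unpadded support)."""
    data = flat.intensities if arr is None else arr
    if data.shape != flat.shape:
        raise ValueError("array to unflatten must match the flattened shape")
    return _shift_axial(data, -flat.shift, fill=0 if data.dtype != bool else False)


def extract_slab(vol: OCTVolume | FlattenedVolume, surfaces: Optional[SurfacePair] = None) -> np.ndarray:
    """Boolean mask of choroid voxels ``bm <= z < csi``."""
    if isinstance(vol, FlattenedVolume):
        surfaces = surfaces or vol.surfaces
        shape = vol.shape
    else:
        if surfaces is None:
            raise ValueError("surfaces are required for an unflattened volume")
        shape = vol.shape
    return slab_mask(shape, surfaces)


def cscan(flat: FlattenedVolume, offset: int) -> np.ndarray:
    """En-face slice ``offset`` voxels below the flattened BM.

    Voxels at or beyond the CSI (slab exhausted at that A-line) are zeroed.
    """
    max_depth = int(flat.surfaces.thickness().max())
    if not (0 <= offset < max_depth):
        raise ValueError(f"offset {offset} outside the slab depth range [0, {max_depth})")
    z = flat.reference_depth + offset
    plane = flat.intensities[:, :, z].copy()
    plane[z >= flat.surfaces.csi] = 0.0
    return plane


# ---------------------------------------------------------------------------
# phantom-only surface detection


def _pick_edge(score: np.ndarray, frac: float, which: str, label: str) -> np.ndarray:
    """Per A-line, locate the gradient peak of the first (or last) contiguous
    run of 'strong' candidates, where strong means >= ``frac`` of that
    A-line's maximum score.  ``score`` is -inf outside the search range."""
    peak = score.max(axis=2)
    if not np.all(peak > 0):
        bad = np.argwhere(~(peak > 0))
        raise ValueError(f"no {label} edge found at A-lines {bad[:5].tolist()} ...")
    if which == "last":
        score = score[..., ::-1]
    strong = score >= frac * peak[..., None]
    nz = score.shape[2]
    z = np.arange(nz)
    first = np.argmax(strong, axis=2)
    # mask of the contiguous strong run starting at `first`
    after = z[None, None, :] >= first[..., None]
    broken = np.cumsum(~strong & after, axis=2) > 0
    run = strong & after & ~broken
    idx = np.argmax(np.where(run, score, -np.inf), axis=2)
    if which == "last":
        idx = (nz - 1) - idx
    return idx


def detect_surfaces_phantom(
    vol: OCTVolume,
    min_edge_fraction: float = 0.5,
    median_mm: float = 0.33,
) -> SurfacePair:
    """Detect BM and CSI on a phantom-like layered volume.

    The detector assumes the phantom's layer contrast: a bright retina/RPE
    complex above a darker choroidal stroma (BM is the shallowest strong
    *negative* axial edge below the inner retinal surface) and a sclera
    brighter than the stroma (CSI is the deepest strong *positive* axial
    edge below BM).  Intensities are lightly median-filtered and the axial
    gradient Gaussian-smoothed before edge picking; the depth maps are
    median-filtered laterally.  Raises if any A-line shows no usable edge.
    """
    arr = vol.intensities
    nb, na, nz = arr.shape
    smooth = ndimage.median_filter(arr, size=(3, 3, 3), mode="nearest")
    smooth = ndimage.gaussian_filter(smooth, sigma=(3.0, 3.0, 2.0), mode="nearest")
    g = np.diff(smooth, axis=2)  # g[..., z] = I[z+1] - I[z]

    # inner retinal surface: strongest positive edge per A-line
    inner = np.argmax(g, axis=2)

    z = np.arange(nz - 1)
    below_inner = z[None, None, :] > inner[..., None] + 1

    neg = np.where(below_inner, -g, -np.inf)
    bm = _pick_edge(neg, min_edge_fraction, which="first", label="BM") + 1

    below_bm = z[None, None, :] >= bm[..., None] + 1
    pos = np.where(below_bm, g, -np.inf)
    csi = _pick_edge(pos, min_edge_fraction, which="last", label="CSI") + 1

    size = (
        max(1, int(round(median_mm / vol.spacing[0])) | 1),
        max(1, int(round(median_mm / vol.spacing[1])) | 1),
    )
    bm = ndimage.median_filter(bm, size=size, mode="nearest")
    csi = ndimage.median_filter(csi, size=size, mode="nearest")
    csi = np.maximum(csi, bm + 1)
    return SurfacePair(bm.astype(np.int64), np.minimum(csi, nz).astype(np.int64))
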