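"""Domain types and file I/O for volumetric OCT data.

Coordinate convention used throughout the package: every volume is indexed
``(b, a, z)`` where ``b`` is the slow axis (one index per B-scan), ``a`` is
the fast axis (one index per A-line within a B-scan) and ``z`` is depth,
increasing from the vitreous toward the sclera.  Indices are 0-based and the
choroid slab between Bruch's membrane (BM) and the choroidal–scleral
interface (CSI) is the half-open depth interval ``[bm, csi)``.

Physical scale is carried as a per-axis voxel pitch in millimetres.  The
lateral pitch is derived as ``extent / n`` (pixel-pitch convention) so that
any volume computed downstream is exactly ``voxel count x voxel volume``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "OCTVolume",
    "SurfacePair",
    "VesselMask",
    "EnFaceMap",
    "read_volume",
    "write_volume",
    "read_surfaces",
    "write_surfaces",
    "voxel_volume",
    "slab_mask",
    "DEFAULT_EXTENT_MM",
    "DEFAULT_DZ_MM",
]

#: Default lateral scan extent in mm, (slow axis, fast axis).  Macular
#: volume scans in this pipeline cover 9 mm (slow) x 12 mm (fast).
DEFAULT_EXTENT_MM: Tuple[float, float] = (9.0, 12.0)

#: Default axial pixel pitch in mm, typical of swept-source OCT, used when a
#: file header carries no axial spacing.  Always overridable.
DEFAULT_DZ_MM: float = 0.0026


@dataclass(frozen=True)
class OCTVolume:
    """A 3-D OCT intensity volume with physical voxel spacing.

    Parameters
    ----------
    intensities
        Non-negative arbitrary-unit reflectivities, shape ``(nb, na, nz)``.
    spacing
        Voxel pitch ``(db, da, dz)`` in mm.
    """

    intensities: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={arr.ndim}")
        if arr.size and float(arr.min()) < 0:
            raise ValueError("OCT intensities must be non-negative")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape

    @property
    def extent(self) -> Tuple[float, float]:
        """Physical lateral scan size (slow, fast) in mm."""
        nb, na, _ = self.shape
        return (nb * self.spacing[0], na * self.spacing[1])

    def with_intensities(self, arr: np.ndarray) -> "OCTVolume":
        """Return a volume with the same spacing and new intensities."""
        return OCTVolume(arr, self.spacing)


@dataclass(frozen=True)
class SurfacePair:
    """Per-A-line depth indices of BM and CSI delimiting the choroid slab."""

    bm: np.ndarray
    csi: np.ndarray

    def __post_init__(self) -> None:
        bm = np.asarray(self.bm)
        csi = np.asarray(self.csi)
        if bm.shape != csi.shape or bm.ndim != 2:
            raise ValueError("bm and csi must be congruent 2-D grids")
        if not (np.issubdtype(bm.dtype, np.integer) and np.issubdtype(csi.dtype, np.integer)):
            bm = np.rint(bm).astype(np.int64)
            csi = np.rint(csi).astype(np.int64)
        if bm.size:
            if bm.min() < 0:
                raise ValueError("bm depth indices must be non-negative")
            if np.any(bm >= csi):
                raise ValueError("surfaces must satisfy bm < csi at every A-line")
        object.__setattr__(self, "bm", bm)
        object.__setattr__(self, "csi", csi)

    @property
    def lateral_shape(self) -> Tuple[int, int]:
        return self.bm.shape

    def thickness(self) -> np.ndarray:
        """Slab thickness in voxels, ``csi - bm``, per A-line."""
        return self.csi - self.bm

    def validate_against(self, shape: Tuple[int, int, int]) -> None:
        if self.bm.shape != shape[:2]:
            raise ValueError(f"surface grids {self.bm.shape} do not match lateral shape {shape[:2]}")
        if self.csi.max() > shape[2]:
            raise ValueError("csi depth exceeds the volume's depth axis")


def slab_mask(shape: Tuple[int, int, int], surfaces: SurfacePair) -> np.ndarray:
    """Boolean mask of choroid-slab voxels: ``bm <= z < csi`` per A-line."""
    surfaces.validate_against(shape)
    z = np.arange(shape[2])
    return (z >= surfaces.bm[..., None]) & (z < surfaces.csi[..., None])


@dataclass(frozen=True)
class VesselMask:
    """Per-voxel binary vessel labels restricted to the choroid slab.

    The constructor enforces that no label lies outside ``[bm, csi)``; the
    stroma mask is always the complement of the labels within the slab, so
    vessel + stroma voxel counts partition the slab exactly.
    """

    labels: np.ndarray
    slab: SurfacePair

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        labels = labels.astype(bool)
        inside = slab_mask(labels.shape, self.slab)
        if np.any(labels & ~inside):
            raise ValueError("vessel labels found outside the choroid slab")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def stroma(self) -> np.ndarray:
        """Stroma labels: slab voxels not labelled vessel."""
        return slab_mask(self.shape, self.slab) & ~self.labels

    def count(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class EnFaceMap:
    """A quantitative 2-D en-face map over the lateral ``(b, a)`` grid."""

    values: np.ndarray
    units: str
    spacing: Tuple[float, float]

    _ALLOWED_UNITS = ("mm3", "mm", "dimensionless")

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("en-face map must be 2-D")
        if values.size and float(values.min()) < 0:
            raise ValueError("en-face map values must be non-negative")
        if self.units not in self._ALLOWED_UNITS:
            raise ValueError(f"units must be one of {self._ALLOWED_UNITS}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be two positive lengths")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


def voxel_volume(vol: OCTVolume) -> float:
    """Volume of one voxel in mm^3 (product of the three pitches)."""
    db, da, dz = vol.spacing
    return db * da * dz


# ---------------------------------------------------------------------------
# volume I/O


def _spacing_from(extent, dz, shape):
    nb, na = shape[0], shape[1]
    eb, ea = (float(extent[0]), float(extent[1]))
    if eb <= 0 or ea <= 0 or dz <= 0:
        raise ValueError("extent and dz must be positive")
    return (eb / nb, ea / na, float(dz))


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Rescale integer payloads to [0, 1] by the global maximum."""
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64)
        m = arr.max() if arr.size else 0.0
        if m > 0:
            arr = arr / m
        return arr
    return arr.astype(np.float64)


def read_volume(
    path,
    extent: Tuple[float, float] = DEFAULT_EXTENT_MM,
    dz: float | None = None,
) -> OCTVolume:
    """Read a NIfTI or multi-page TIFF volume as ``(b, a, z)``.

    Lateral spacing is derived as ``extent / axis length``.  For NIfTI the
    axial pitch is taken from the header zooms unless ``dz`` is given; for
    TIFF (which carries no axial calibration) ``dz`` defaults to
    :data:`DEFAULT_DZ_MM`.  Integer payloads are rescaled to [0, 1].
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error paths
            raise ValueError(f"unreadable NIfTI file {path}: {exc}") from exc
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D NIfTI payload, got shape {arr.shape}")
        if dz is None:
            zooms = img.header.get_zooms()
            dz = float(zooms[2]) if len(zooms) >= 3 and zooms[2] > 0 else DEFAULT_DZ_MM
    elif suffixes.endswith((".tif", ".tiff")):
        try:
            arr = tifffile.imread(str(path))
        except Exception as exc:
            raise ValueError(f"unreadable TIFF file {path}: {exc}") from exc
        if arr.ndim != 3:
            raise ValueError(f"expected a multi-page TIFF volume, got shape {arr.shape}")
        if dz is None:
            dz = DEFAULT_DZ_MM
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    arr = _normalize(np.asarray(arr))
    return OCTVolume(arr, _spacing_from(extent, dz, arr.shape))


def write_volume(vol: OCTVolume, path) -> None:
    """Write a volume (or binary mask) to NIfTI or multi-page TIFF.

    The NIfTI affine carries the voxel spacing on its diagonal; TIFF pages
    run along the slow axis (one page per B-scan).
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    data = vol.intensities.astype(np.float32)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(vol.spacing) + [1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), data)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


# ---------------------------------------------------------------------------
# surface I/O (CSV with two stacked depth grids labelled "bm" and "csi")


def write_surfaces(surfaces: SurfacePair, path) -> None:
    nb, na = surfaces.lateral_shape
    frames = []
    for name, grid in (("bm", surfaces.bm), ("csi", surfaces.csi)):
        df = pd.DataFrame(grid, columns=[f"a{j}" for j in range(na)])
        df.insert(0, "b", np.arange(nb))
        df.insert(0, "surface", name)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


def read_surfaces(path) -> SurfacePair:
    df = pd.read_csv(path)
    if "surface" not in df.columns:
        raise ValueError("surface CSV must have a 'surface' column naming bm/csi")
    grids = {}
    value_cols = [c for c in df.columns if c.startswith("a")]
    for name in ("bm", "csi"):
        sub = df[df["surface"] == name].sort_values("b")
        if sub.empty:
            raise ValueError(f"surface CSV is missing the '{name}' grid")
        grids[name] = sub[value_cols].to_numpy(dtype=np.int64)
    if grids["bm"].shape != grids["csi"].shape:
        raise ValueError("bm and csi grids differ in shape")
    return SurfacePair(grids["bm"], grids["csi"])


def write_map(emap: EnFaceMap, path) -> None:
    """Write an en-face map as CSV (one row per B-scan position)."""
    pd.DataFrame(emap.values).to_csv(path, index=False, header=False)
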