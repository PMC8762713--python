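"""Synthetic layered OCT phantoms with known vessel ground truth.

The phantom emulates, in order, the degradations the enhancement pipeline is
built to remove: fully developed multiplicative speckle (Gamma L-look
model, unit mean), columnar shadows cast by retinal vessels onto everything
below Bruch's membrane, and exponential depth attenuation.  The clean scene
is a four-layer stack (vitreous, retina/RPE complex, choroidal stroma,
sclera) whose choroid contains hyporeflective cylindrical vessels; per-voxel
ground-truth labels and analytic cylinder volumes accompany every render.

Default parameters define the package's standard phantom: an L=4 speckle
field, two shadow stripes, attenuation 0.5 /mm and six vessels with radii
0.05-0.2 mm, on an 80 x 224 x 120 grid at (0.03, 0.03, 0.01) mm pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .core_io import OCTVolume, SurfacePair, VesselMask, slab_mask, voxel_volume

__all__ = [
    "Vessel",
    "ShadowStripe",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "speckle_contrast",
]


@dataclass(frozen=True)
class Vessel:
    """A straight cylindrical vessel between two points.

    ``start`` and ``end`` are centerline endpoints in mm as ``(b, a, z)``.
    Choroidal vessels run roughly parallel to the en-face plane, so the
    default phantom uses segments with constant depth that sweep obliquely
    across the slow axis while spanning the fast axis.
    """

    start: Tuple[float, float, float]
    end: Tuple[float, float, float]
    radius_mm: float
    lumen_intensity: float = 0.25

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("vessel radius must be positive")
        if self.length_mm <= 0:
            raise ValueError("vessel must have positive length")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))

    @property
    def analytic_volume_mm3(self) -> float:
        """pi r^2 L for the straight cylinder."""
        return np.pi * self.radius_mm**2 * self.length_mm


@dataclass(frozen=True)
class ShadowStripe:
    """A retinal-vessel shadow: a stripe at fixed fast-axis position that
    multiplies every voxel below BM by its transmission factor."""

    a_center_mm: float
    width_mm: float
    transmission: float

    def __post_init__(self) -> None:
        if not (0 < self.transmission <= 1):
            raise ValueError("shadow transmission must lie in (0, 1]")
        if self.width_mm <= 0:
            raise ValueError("shadow width must be positive")


def _default_vessels() -> Tuple[Vessel, ...]:
    # Six parallel oblique cylinders spanning the fast axis while sweeping
    # +-0.3 mm across the slow axis, staggered in depth so each stays inside
    # the 0.30-0.80 mm slab with margin; together their slow-axis footprints
    # cover the whole field, as a vascularised choroid would.
    rows = [  # (b center, z, radius)
        (0.40, 0.45, 0.05),
        (0.75, 0.60, 0.08),
        (1.15, 0.50, 0.11),
        (1.57, 0.58, 0.14),
        (2.00, 0.53, 0.17),
        (2.48, 0.55, 0.20),
    ]
    return tuple(
        Vessel((b - 0.3, 0.36, z), (b + 0.3, 6.36, z), r) for b, z, r in rows
    )


def _default_shadows() -> Tuple[ShadowStripe, ...]:
    return (
        ShadowStripe(2.0, 0.12, 0.35),
        ShadowStripe(4.6, 0.12, 0.35),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic volume; defaults are the standard phantom."""

    shape: Tuple[int, int, int] = (100, 224, 120)
    spacing: Tuple[float, float, float] = (0.03, 0.03, 0.01)
    # layer depths: scalars, or smooth 2-D (nb, na) fields in mm
    retina_top_mm: float | np.ndarray = 0.10
    bm_mm: float | np.ndarray = 0.30
    csi_mm: float | np.ndarray = 0.80
    vitreous_intensity: float = 0.04
    retina_intensity: float = 0.85
    stroma_intensity: float = 0.55
    sclera_intensity: float = 0.75
    vessels: Tuple[Vessel, ...] = field(default_factory=_default_vessels)
    shadows: Tuple[ShadowStripe, ...] = field(default_factory=_default_shadows)
    speckle_looks: Optional[float] = 4.0  # Gamma L; None disables speckle
    attenuation_per_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        top, bm, csi = (np.asarray(f) for f in (self.retina_top_mm, self.bm_mm, self.csi_mm))
        if not (np.all(0 <= top) and np.all(top < bm) and np.all(bm < csi)):
            raise ValueError("layer depths must satisfy retina_top < bm < csi")
        if np.any(csi >= self.shape[2] * self.spacing[2]):
            raise ValueError("csi must lie inside the depth axis")
        if self.speckle_looks is not None and self.speckle_looks <= 0:
            raise ValueError("speckle looks L must be positive")
        if self.attenuation_per_mm < 0:
            raise ValueError("attenuation coefficient must be non-negative")
        for v in self.vessels:
            if v.lumen_intensity >= self.stroma_intensity:
                raise ValueError("vessel lumens must be darker than stroma")

    def without_noise(self) -> "PhantomSpec":
        """Copy with speckle, shadows and attenuation disabled."""
        return replace(self, speckle_looks=None, shadows=(), attenuation_per_mm=0.0)


@dataclass(frozen=True)
class PhantomTruth:
    """A rendered phantom with its ground truth."""

    volume: OCTVolume
    vessel_truth: VesselMask
    surfaces: SurfacePair
    analytic_volumes_mm3: Tuple[float, ...]
    spec: PhantomSpec

    @property
    def total_analytic_volume_mm3(self) -> float:
        return float(sum(self.analytic_volumes_mm3))


def _voxel_index(x_mm: float, pitch: float) -> int:
    return int(np.floor(x_mm / pitch))


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render a phantom: clean tissue, then speckle, shadows, attenuation.

    A voxel belongs to the truth mask iff its centre lies within a vessel
    radius of some centerline; the mask is clipped to the slab.  The render
    is deterministic given ``spec.seed``.
    """
    nb, na, nz = spec.shape
    db, da, dz = spec.spacing

    # voxel-centre coordinate grids (mm)
    bc = (np.arange(nb) + 0.5) * db
    ac = (np.arange(na) + 0.5) * da
    zc = (np.arange(nz) + 0.5) * dz

    lateral = np.ones((nb, na), dtype=np.float64)
    top_mm = np.asarray(spec.retina_top_mm, dtype=np.float64) * lateral
    bm_mm = np.asarray(spec.bm_mm, dtype=np.float64) * lateral
    csi_mm = np.asarray(spec.csi_mm, dtype=np.float64) * lateral
    z_top = np.floor(top_mm / dz).astype(np.int64)[..., None]
    z_bm = np.floor(bm_mm / dz).astype(np.int64)[..., None]
    z_csi = np.floor(csi_mm / dz).astype(np.int64)[..., None]

    zi = np.arange(nz)
    clean = np.full(spec.shape, spec.vitreous_intensity, dtype=np.float64)
    clean[(zi >= z_top) & (zi < z_bm)] = spec.retina_intensity
    clean[(zi >= z_bm) & (zi < z_csi)] = spec.stroma_intensity
    clean[zi >= z_csi] = spec.sclera_intensity

    surfaces = SurfacePair(z_bm[..., 0], z_csi[..., 0])

    # vessels: centre-within-radius voxelization of each centerline segment
    truth = np.zeros(spec.shape, dtype=bool)
    bounds = np.array([nb * db, na * da, nz * dz])
    for v in spec.vessels:
        p0 = np.asarray(v.start, dtype=np.float64)
        p1 = np.asarray(v.end, dtype=np.float64)
        if np.any(p0 < 0) or np.any(p1 < 0) or np.any(p0 > bounds) or np.any(p1 > bounds):
            raise ValueError(f"vessel centerline {v.start}->{v.end} mm lies outside the grid")
        axis = p1 - p0
        # projection parameter of each voxel centre onto the segment
        t = (
            (bc[:, None, None] - p0[0]) * axis[0]
            + (ac[None, :, None] - p0[1]) * axis[1]
            + (zc[None, None, :] - p0[2]) * axis[2]
        ) / float(axis @ axis)
        # flat-capped cylinder: perpendicular distance within the projection
        # span, so the voxelized volume converges to pi r^2 L exactly
        d2 = (
            (bc[:, None, None] - p0[0] - t * axis[0]) ** 2
            + (ac[None, :, None] - p0[1] - t * axis[1]) ** 2
            + (zc[None, None, :] - p0[2] - t * axis[2]) ** 2
        )
        lumen = (t >= 0.0) & (t <= 1.0) & (d2 <= v.radius_mm**2)
        clean[lumen] = v.lumen_intensity
        truth |= lumen
    truth &= slab_mask(spec.shape, surfaces)

    img = clean
    if spec.speckle_looks is not None:
        rng = np.random.default_rng(spec.seed)
        L = spec.speckle_looks
        img = img * rng.gamma(shape=L, scale=1.0 / L, size=spec.shape)
    sub_bm = zi >= z_bm
    for sh in spec.shadows:
        cols = np.abs(ac - sh.a_center_mm) <= sh.width_mm / 2
        factor = np.where(sub_bm[:, cols, :], sh.transmission, 1.0)
        img = img.copy() if img is clean else img
        img[:, cols, :] *= factor
    if spec.attenuation_per_mm > 0:
        # depth measured from the (possibly tilted) retinal surface
        depth = np.clip(zc[None, None, :] - top_mm[..., None], 0.0, None)
        img = img * np.exp(-spec.attenuation_per_mm * depth)

    volume = OCTVolume(img, spec.spacing)
    mask = VesselMask(truth, surfaces)
    analytic = tuple(v.analytic_volume_mm3 for v in spec.vessels)
    return PhantomTruth(volume, mask, surfaces, analytic, spec)


def speckle_contrast(vol: OCTVolume, region: Optional[np.ndarray] = None) -> float:
    """Speckle contrast sd/mean over a region (whole volume by default).

    For fully developed L-look speckle on homogeneous tissue this is
    approximately ``1/sqrt(L)``; a denoising stage should reduce it.
    """
    vals = vol.intensities if region is None else vol.intensities[region]
    vals = np.asarray(vals, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("speckle_contrast requires a non-empty region")
    mean = vals.mean()
    if mean == 0:
        return 0.0
    return float(vals.std() / mean)
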