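"""Synthetic breath-hold thorax phantom.

Generates a voxelized thorax CT (Hounsfield units) together with a structure
set (body, two lungs, spherical tumor/CTV, heart, esophagus, aorta, spinal
cord, chest wall) on a shared :class:`~bhrobust.grid.VoxelGrid`.  Organ shapes
are fixed, documented primitives (ellipsoids and cylinders) chosen to give a
realistic density contrast for proton range sensitivity: low-density lungs,
soft-tissue mediastinum and a high-density chest wall / vertebral column.

The phantom stands in for a single breath-hold planning CT; it is the input
to the deformation, planning and evaluation stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import GeometryError, VoxelGrid

# Nominal tissue HU values (documented package constants, not patient data).
TISSUE_HU = {
    "air": -1000.0,
    "lung": -750.0,
    "soft": 40.0,
    "heart": 30.0,
    "aorta": 50.0,
    "bone": 700.0,
    "tumor": 20.0,
}

STRUCTURE_NAMES = (
    "CTV", "lung_ipsi", "lung_contra", "heart", "esophagus",
    "aorta", "spinal_cord", "chest_wall", "body",
)

# Piecewise-linear HU -> stopping-power-ratio curve (monotone, anchored at
# air ~0.001 and water = 1.0; soft/bone slopes are generic literature-shaped
# values, adequate for an analytic range model).
_SPR_CURVE_HU = np.array([-1024.0, -1000.0, 0.0, 1000.0, 3000.0])
_SPR_CURVE_SPR = np.array([0.001, 0.001, 1.0, 1.55, 2.4])


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic thorax.

    ``tumor_center_mm`` of ``None`` auto-places the tumor inside the
    ipsilateral lung, offset toward the lateral chest wall.
    """

    shape: tuple[int, int, int] = (64, 56, 48)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tumor_diameter_mm: float = 25.0
    tumor_center_mm: tuple[float, float, float] | None = None
    laterality: str = "left"  # which lung hosts the tumor
    noise_hu_sd: float = 0.0  # optional seeded Gaussian HU texture

    def grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.shape, spacing=self.spacing)


@dataclass
class Phantom:
    """HU volume plus named binary structure masks on one grid."""

    grid: VoxelGrid
    hu: np.ndarray
    structures: dict[str, np.ndarray]
    config: PhantomConfig | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid.validate_volume(self.hu)
        for name, mask in self.structures.items():
            self.grid.validate_volume(mask)
            if mask.dtype != bool:
                raise ValueError(f"structure {name!r} must be a boolean mask")
        ctv = self.structures.get("CTV")
        if ctv is None or not ctv.any():
            raise GeometryError("phantom requires a nonempty CTV")

    @property
    def lung_union(self) -> np.ndarray:
        return self.structures["lung_ipsi"] | self.structures["lung_contra"]

    def structure_volume_cm3(self, name: str) -> float:
        return float(self.structures[name].sum()) * self.grid.voxel_volume_mm3 / 1000.0


def _ellipsoid(grid: VoxelGrid, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    x, y, z = grid.meshgrid()
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def _cylinder_z(grid: VoxelGrid, cx: float, cy: float, radius: float,
                z_lo: float | None = None, z_hi: float | None = None) -> np.ndarray:
    x, y, z = grid.meshgrid()
    m = ((x - cx) ** 2 + (y - cy) ** 2) <= radius ** 2
    m = np.broadcast_to(m, grid.shape).copy()
    if z_lo is not None:
        m &= z >= z_lo
    if z_hi is not None:
        m &= z <= z_hi
    return m


def _dilate_mm(mask: np.ndarray, grid: VoxelGrid, radius_mm: float) -> np.ndarray:
    d = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    return d <= radius_mm


def generate_phantom(config: PhantomConfig, seed: int = 0) -> Phantom:
    """Build the synthetic breath-hold thorax CT and structure set.

    Deterministic for a given ``(config, seed)``; the seed only drives the
    optional HU texture noise.

    Raises
    ------
    GeometryError
        If the tumor center falls outside the ipsilateral lung or the tumor
        diameter is not resolved by the grid.
    """
    grid = config.grid()
    ext = grid.extent_mm
    c = grid.center_mm

    if config.tumor_diameter_mm <= max(grid.spacing):
        raise GeometryError(
            f"tumor diameter {config.tumor_diameter_mm} mm is <= 1 voxel on this grid")
    if config.laterality not in ("left", "right"):
        raise GeometryError(f"laterality must be 'left' or 'right', got {config.laterality!r}")

    body = _ellipsoid(grid, c, np.array([0.46 * ext[0], 0.42 * ext[1], 10.0 * ext[2]]))

    lung_semi = np.array([0.155 * ext[0], 0.26 * ext[1], 0.40 * ext[2]])
    lung_off = np.array([0.225 * ext[0], 0.02 * ext[1], 0.0])
    sign = -1.0 if config.laterality == "left" else 1.0
    ipsi_center = c + sign * np.array([lung_off[0], 0, 0]) + np.array([0, lung_off[1], 0])
    contra_center = c - sign * np.array([lung_off[0], 0, 0]) + np.array([0, lung_off[1], 0])
    lung_ipsi = _ellipsoid(grid, ipsi_center, lung_semi)
    lung_contra = _ellipsoid(grid, contra_center, lung_semi)

    heart = _ellipsoid(grid, c + np.array([-0.03 * ext[0], 0.12 * ext[1], -0.10 * ext[2]]),
                       np.array([0.105 * ext[0], 0.11 * ext[1], 0.14 * ext[2]]))
    esophagus = _cylinder_z(grid, c[0] + 0.015 * ext[0], c[1] - 0.08 * ext[1], 5.0)
    aorta = _cylinder_z(grid, c[0] - 0.045 * ext[0], c[1] - 0.14 * ext[1], 8.0)
    vertebra = _cylinder_z(grid, c[0], c[1] - 0.30 * ext[1], 13.0)
    spinal_cord = _cylinder_z(grid, c[0], c[1] - 0.30 * ext[1], 4.5)

    # Mediastinal organs take precedence over lungs; keep masks disjoint.
    mediastinum = heart | esophagus | aorta | vertebra
    lung_ipsi &= ~mediastinum
    lung_contra &= ~mediastinum
    for m in (lung_ipsi, lung_contra, heart, esophagus, aorta, vertebra, spinal_cord):
        m &= body

    if config.tumor_center_mm is None:
        tumor_center = ipsi_center + np.array([sign * 0.45 * lung_semi[0],
                                               -0.15 * lung_semi[1],
                                               0.15 * lung_semi[2]])
    else:
        tumor_center = np.asarray(config.tumor_center_mm, dtype=float)

    x, y, z = grid.meshgrid()
    r = config.tumor_diameter_mm / 2.0
    ctv = (((x - tumor_center[0]) ** 2 + (y - tumor_center[1]) ** 2
            + (z - tumor_center[2]) ** 2) <= r ** 2)
    if not ctv.any():
        raise GeometryError("tumor not resolved on grid")

    idx = np.clip(np.round(grid.world_to_index(tumor_center)).astype(int),
                  0, np.asarray(grid.shape) - 1)
    if not lung_ipsi[tuple(idx)]:
        raise GeometryError(
            f"tumor center {tuple(np.round(tumor_center, 1))} lies outside the ipsilateral lung")
    if (ctv & ~lung_ipsi).any():
        raise GeometryError("tumor sphere escapes the ipsilateral lung")

    lungs = lung_ipsi | lung_contra
    chest_wall = _dilate_mm(lungs, grid, 12.0) & body & ~lungs & ~mediastinum & ~ctv

    hu = np.full(grid.shape, TISSUE_HU["air"], dtype=float)
    hu[body] = TISSUE_HU["soft"]
    hu[chest_wall] = TISSUE_HU["bone"]
    hu[vertebra] = TISSUE_HU["bone"]
    hu[lungs] = TISSUE_HU["lung"]
    hu[heart] = TISSUE_HU["heart"]
    hu[aorta] = TISSUE_HU["aorta"]
    hu[ctv] = TISSUE_HU["tumor"]
    if config.noise_hu_sd > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, config.noise_hu_sd, size=grid.shape)
        hu[~body] = TISSUE_HU["air"]

    # Distance from tumor surface to the lung wall (recorded for the
    # lung-wall clamping stage).
    dist_to_wall = ndimage.distance_transform_edt(lung_ipsi | ctv, sampling=grid.spacing)
    gap_mm = float(dist_to_wall[ctv].min()) if ctv.any() else 0.0

    structures = {
        "CTV": ctv,
        "lung_ipsi": lung_ipsi | ctv,
        "lung_contra": lung_contra,
        "heart": heart,
        "esophagus": esophagus,
        "aorta": aorta,
        "spinal_cord": spinal_cord,
        "chest_wall": chest_wall,
        "body": body,
    }
    return Phantom(grid=grid, hu=hu, structures=structures, config=config,
                   meta={"tumor_center_mm": tuple(float(v) for v in tumor_center),
                         "tumor_wall_gap_mm": gap_mm, "seed": int(seed)})


def hu_to_spr(hu: np.ndarray) -> np.ndarray:
    """Piecewise-linear monotone HU -> stopping-power-ratio conversion.

    Anchored at SPR(-1000) ~ 0.001 (air) and SPR(0) = 1.0 (water); HU outside
    [-1024, 3000] are clamped.
    """
    h = np.clip(np.asarray(hu, dtype=float), _SPR_CURVE_HU[0], _SPR_CURVE_HU[-1])
    return np.interp(h, _SPR_CURVE_HU, _SPR_CURVE_SPR)


def hu_to_density(hu: np.ndarray) -> np.ndarray:
    """Relative (to water) density used by the photon attenuation model."""
    return np.clip((np.asarray(hu, dtype=float) + 1000.0) / 1000.0, 0.0, 3.0)


def save_phantom(phantom: Phantom, directory: str | Path) -> Path:
    """Write HU volume and masks as NIfTI plus a JSON sidecar."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = phantom.grid.affine()
    nib.save(nib.Nifti1Image(phantom.hu.astype(np.float32), aff), directory / "hu.nii.gz")
    for name, mask in phantom.structures.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), directory / f"mask_{name}.nii.gz")
    sidecar = {
        "structures": list(phantom.structures),
        "grid": {"shape": phantom.grid.shape, "spacing": phantom.grid.spacing,
                 "origin": phantom.grid.origin},
        "meta": phantom.meta,
        "config": None if phantom.config is None else {
            "shape": phantom.config.shape, "spacing": phantom.config.spacing,
            "tumor_diameter_mm": phantom.config.tumor_diameter_mm,
            "tumor_center_mm": phantom.config.tumor_center_mm,
            "laterality": phantom.config.laterality,
            "noise_hu_sd": phantom.config.noise_hu_sd,
        },
    }
    (directory / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return directory
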