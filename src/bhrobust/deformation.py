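"""Breath-hold anatomy deformation by harmonic displacement fields.

A reproduced breath-hold is modeled as a rigid shift of the tumor inside the
lung, interpolated to zero at the lung wall by a harmonic (Laplace) field:
each displacement component solves the discrete Laplace equation in the lung
interior with Dirichlet data ``u = tumor_shift`` on the tumor and ``u = 0``
on and outside the lung boundary.  Tissue outside the lung is static.

Because the Laplace problem is linear and the boundary data is the same
rigid vector everywhere on the tumor, every field is ``shift x phi(x)`` for a
single scalar harmonic potential ``phi`` (1 on the tumor, 0 at the wall);
``phi`` is solved once per phantom and reused for all shifts.

Shifts are clamped so the displaced tumor cannot cross the lung wall, the
field inverse (fixed-point iteration) enables dose accumulation on the
reference geometry, and pull-back resampling warps images and masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .grid import GeometryError, VoxelGrid
from .phantom import Phantom

_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass
class DeformationSpec:
    """A requested breath-hold deformation: rigid tumor shift plus the masks."""

    tumor_shift: tuple[float, float, float]
    tumor_mask: np.ndarray
    lung_mask: np.ndarray


@dataclass
class DisplacementField:
    """Per-voxel 3D displacement (mm) with its lazily-computed inverse.

    ``vectors`` is the forward displacement: a tissue element at reference
    position x sits at ``x + vectors(x)`` in the deformed geometry (tumor
    voxels carry the full rigid shift).  ``inverse_vectors`` maps the other
    way and is populated on demand by :func:`invert_dvf`.
    """

    grid: VoxelGrid
    vectors: np.ndarray  # shape + (3,)
    domain: np.ndarray  # lung mask: displacement is zero outside
    inverse_vectors: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vectors.shape != (*self.grid.shape, 3):
            raise ValueError("vectors must have shape grid.shape + (3,)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("displacement field contains non-finite values")

    @property
    def is_zero(self) -> bool:
        return not self.vectors.any()

    def ensure_inverse(self, iters: int = 20) -> np.ndarray:
        if self.inverse_vectors is None:
            invert_dvf(self, iters=iters)
        return self.inverse_vectors


def _field_bbox(displacement_mm: np.ndarray, grid: VoxelGrid,
                pad_voxels: int = 2) -> tuple[slice, slice, slice] | None:
    """Bounding slab where the field (or anything it can reach) is nonzero."""
    nz = np.abs(displacement_mm).max(axis=-1) > 0
    if not nz.any():
        return None
    reach = int(np.ceil(np.abs(displacement_mm).max() / min(grid.spacing))) + pad_voxels
    sl = []
    for a in range(3):
        axes = tuple(i for i in range(3) if i != a)
        prof = nz.any(axis=axes)
        lo = max(0, int(np.argmax(prof)) - reach)
        hi = min(grid.shape[a], len(prof) - int(np.argmax(prof[::-1])) + reach)
        sl.append(slice(lo, hi))
    return tuple(sl)


def _sample_displaced(volume: np.ndarray, displacement_mm: np.ndarray,
                      grid: VoxelGrid, order: int,
                      bbox: tuple[slice, slice, slice] | None = None) -> np.ndarray:
    """Sample ``volume`` at x + displacement(x) (pull-back, mm displacement).

    With ``bbox``, only voxels inside the box are resampled (the displacement
    must vanish outside); the rest are copied, which keeps the cost
    proportional to the deforming region.
    """
    spacing = np.asarray(grid.spacing)
    vol = volume.astype(float, copy=False)
    if bbox is None:
        idx = np.indices(grid.shape, dtype=float)
        coords = [idx[a] + displacement_mm[..., a] / spacing[a] for a in range(3)]
        return ndimage.map_coordinates(vol, coords, order=order, mode="nearest")
    out = vol.copy()
    sub = np.indices(tuple(s.stop - s.start for s in bbox), dtype=float)
    coords = [sub[a] + bbox[a].start + displacement_mm[bbox + (a,)] / spacing[a]
              for a in range(3)]
    out[bbox] = ndimage.map_coordinates(vol, coords, order=order, mode="nearest")
    return out


def clamp_shift_to_lung_wall(shift, tumor_mask: np.ndarray, lung_mask: np.ndarray,
                             grid: VoxelGrid, clearance_voxels: float = 1.0):
    """Scale a tumor shift so the shifted tumor stays inside the lung.

    The direction is preserved; the magnitude is reduced (if needed) so no
    tumor voxel's distance to the lung wall drops below min(the target
    clearance, its initial clearance).  The relative floor lets a tumor that
    already hugs the wall slide along or away from it while still forbidding
    any motion *into* the wall; a feasible shift is returned unchanged.
    """
    shift = np.asarray(shift, dtype=float)
    if tumor_mask.any() and (tumor_mask & ~lung_mask).any():
        raise GeometryError("tumor mask is not inside the lung mask")
    norm = float(np.linalg.norm(shift))
    if norm == 0:
        return np.zeros(3)

    spacing = np.asarray(grid.spacing)
    # extra half voxel absorbs mask-voxelization rounding of the shifted tumor
    clearance_mm = (clearance_voxels + 0.5) * float(spacing.min())
    # Distance to the lung wall, measured inside the lung (0 outside).
    edt = ndimage.distance_transform_edt(lung_mask, sampling=grid.spacing)

    # March every tumor voxel along the shift direction on the clearance map
    # (surface voxels alone can miss thin non-lung protrusions, e.g. the
    # mediastinal boundary, that end up interior to the moved tumor).
    pts = np.argwhere(tumor_mask).astype(float)
    h = float(spacing.min())
    # per-voxel floor: allow half a voxel of degradation for wall-hugging
    # voxels, but never drop below one voxel of lung (containment guarantee)
    thresholds = np.clip(np.minimum(clearance_mm, edt[tumor_mask] - 0.5 * h),
                         h, None) - 1e-9
    direction = shift / norm
    step = 0.5 * float(spacing.min())
    n_steps = int(np.ceil(norm / step)) + 1
    ts = np.arange(1, n_steps + 1) * step
    d_vox = direction / spacing
    # coords: (3, n_pts, n_steps)
    coords = pts.T[:, :, None] + d_vox[:, None, None] * ts[None, None, :]
    clearance = ndimage.map_coordinates(edt, coords.reshape(3, -1), order=1,
                                        mode="constant", cval=0.0)
    inside = clearance.reshape(len(pts), len(ts)) >= thresholds[:, None]
    # First step at which any voxel loses clearance bounds the feasible travel.
    fails = ~inside
    if not fails.any():
        feasible = norm
    else:
        first_fail = int(np.argmax(fails.any(axis=0)))
        feasible = max(0.0, float(ts[first_fail]) - step)
    if norm <= feasible:
        return shift.copy()
    return direction * feasible


class HarmonicPotential:
    """Scalar harmonic interpolant phi: 1 on the tumor, 0 at the lung wall.

    Solves the 7-point-stencil Laplace equation on ``lung & ~tumor`` with
    Dirichlet conditions (mirror/Neumann closure at grid faces) using a
    sparse direct solve.  Every displacement field of the phantom is
    ``shift x phi``.
    """

    def __init__(self, tumor_mask: np.ndarray, lung_mask: np.ndarray,
                 grid: VoxelGrid, tol: float = 1e-3, max_residual_check: bool = True):
        if (tumor_mask & ~lung_mask).any():
            raise GeometryError("tumor mask is not inside the lung mask")
        self.grid = grid
        self.tumor = tumor_mask
        self.lung = lung_mask
        self.tol = float(tol)
        self.phi = self._solve()
        if max_residual_check:
            res = self.residual()
            if res > tol:
                raise RuntimeError(
                    f"Laplace solve residual {res:.2e} exceeds tolerance {tol:.2e}")

    def _solve(self) -> np.ndarray:
        interior = self.lung & ~self.tumor
        shape = self.grid.shape
        n = int(interior.sum())
        phi = np.zeros(shape, dtype=float)
        phi[self.tumor] = 1.0
        if n == 0:
            return phi
        index = -np.ones(shape, dtype=np.int64)
        index[interior] = np.arange(n)

        rows, cols, vals = [], [], []
        rhs = np.zeros(n)
        diag = np.zeros(n)
        ivox = np.argwhere(interior)
        for off in _OFFSETS:
            nb = ivox + np.array(off)
            in_grid = ((nb >= 0) & (nb < np.array(shape))).all(axis=1)
            # Mirror closure at grid faces: out-of-grid neighbor drops out.
            diag[~in_grid] += 0.0
            sel = np.where(in_grid)[0]
            nbi = nb[sel]
            nb_flat = index[nbi[:, 0], nbi[:, 1], nbi[:, 2]]
            is_interior = nb_flat >= 0
            diag[sel] += 1.0
            rows.extend(index[ivox[sel[is_interior], 0], ivox[sel[is_interior], 1],
                              ivox[sel[is_interior], 2]])
            cols.extend(nb_flat[is_interior])
            vals.extend([-1.0] * int(is_interior.sum()))
            # Dirichlet neighbors: tumor contributes 1, outside-lung contributes 0.
            bd = sel[~is_interior]
            if len(bd):
                tb = self.tumor[nb[bd, 0], nb[bd, 1], nb[bd, 2]]
                r_idx = index[ivox[bd, 0], ivox[bd, 1], ivox[bd, 2]]
                np.add.at(rhs, r_idx, tb.astype(float))
        rows.extend(range(n))
        cols.extend(range(n))
        vals.extend(diag)
        A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        sol = spsolve(A, rhs)
        phi[interior] = sol
        return phi

    def residual(self) -> float:
        """Max-norm of the discrete Laplacian of phi over the interior."""
        interior = self.lung & ~self.tumor
        if not interior.any():
            return 0.0
        lap = np.zeros(self.grid.shape)
        count = np.zeros(self.grid.shape)
        for off in _OFFSETS:
            shifted = np.roll(self.phi, shift=[-o for o in off], axis=(0, 1, 2))
            valid = np.ones(self.grid.shape, dtype=bool)
            for a, o in enumerate(off):
                if o == 1:
                    sl = [slice(None)] * 3
                    sl[a] = slice(-1, None)
                    valid[tuple(sl)] = False
                elif o == -1:
                    sl = [slice(None)] * 3
                    sl[a] = slice(0, 1)
                    valid[tuple(sl)] = False
            lap += np.where(valid, shifted - self.phi, 0.0)
            count += valid
        return float(np.abs(lap[interior]).max())


def solve_laplacian_dvf(phantom: Phantom, spec: DeformationSpec,
                        tol: float = 1e-3,
                        potential: HarmonicPotential | None = None) -> DisplacementField:
    """Solve the harmonic displacement field for a (clamped) tumor shift.

    ``potential`` may carry a precomputed :class:`HarmonicPotential` for the
    same masks; otherwise one is solved here.
    """
    shift = np.asarray(spec.tumor_shift, dtype=float)
    if potential is None:
        potential = HarmonicPotential(spec.tumor_mask, spec.lung_mask,
                                      phantom.grid, tol=tol)
    vectors = potential.phi[..., None] * shift[None, None, None, :]
    return DisplacementField(grid=phantom.grid, vectors=vectors,
                             domain=spec.lung_mask,
                             meta={"tumor_shift": tuple(shift),
                                   "residual": potential.residual() * float(np.abs(shift).max(initial=0.0))})


def invert_dvf(field: DisplacementField, iters: int = 20) -> DisplacementField:
    """Populate the fixed-point inverse: v <- -u(x + v(x)).

    Emits a warning (with the measured residual) if the composition residual
    RMS inside the domain exceeds 0.25 x the smallest voxel spacing.
    """
    u = field.vectors
    if field.is_zero:
        field.inverse_vectors = np.zeros_like(u)
        field.meta["inverse_residual_rms_mm"] = 0.0
        return field
    bbox = _field_bbox(u, field.grid)
    v = -u.copy()
    for _ in range(iters):
        u_at = np.stack([_sample_displaced(u[..., a], v, field.grid, order=1,
                                           bbox=bbox) for a in range(3)], axis=-1)
        v_new = -u_at
        step = float(np.abs(v_new - v).max())
        v = v_new
        if step < 1e-3:  # converged well below the 0.25-voxel criterion
            break
    u_at = np.stack([_sample_displaced(u[..., a], v, field.grid, order=1, bbox=bbox)
                     for a in range(3)], axis=-1)
    res = u_at + v
    inside = field.domain
    rms = float(np.sqrt((res[inside] ** 2).sum(axis=-1).mean())) if inside.any() else 0.0
    field.inverse_vectors = v
    field.meta["inverse_residual_rms_mm"] = rms
    limit = 0.25 * float(min(field.grid.spacing))
    if rms > limit:
        warnings.warn(f"DVF inverse composition residual RMS {rms:.3f} mm exceeds "
                      f"{limit:.3f} mm after {iters} iterations")
    return field


def warp_image(volume: np.ndarray, field: DisplacementField,
               mode: str = "linear") -> np.ndarray:
    """Warp a reference-geometry volume into the deformed geometry.

    Pull-back resampling with the inverse displacement (computed lazily), so
    image content — e.g. the tumor — moves by +tumor_shift.  ``mode`` is
    ``"linear"`` for HU/dose and ``"nearest"`` for masks.
    """
    order = {"linear": 1, "nearest": 0}[mode]
    if field.is_zero:
        return volume.copy()
    inv = field.ensure_inverse()
    out = _sample_displaced(volume, inv, field.grid, order=order,
                            bbox=_field_bbox(inv, field.grid))
    if volume.dtype == bool:
        return out > 0.5
    return out.astype(volume.dtype, copy=False)


def accumulate_dose_on_reference(dose_in_deformed: np.ndarray,
                                 field: DisplacementField) -> np.ndarray:
    """Map a dose computed on the deformed geometry back to the reference.

    The dose received by the tissue element at reference position x is the
    deformed-geometry dose at its displaced position x + u(x), sampled with
    linear interpolation.
    """
    if field.is_zero:
        return dose_in_deformed.copy()
    return _sample_displaced(dose_in_deformed, field.vectors, field.grid, order=1,
                             bbox=_field_bbox(field.vectors, field.grid))


class BreathHoldDeformer:
    """Convenience wrapper: clamp, solve, warp and invert for one phantom.

    The scalar harmonic potential is solved once at construction; individual
    breath-hold geometries for arbitrary (clamped) tumor shifts then cost one
    field inversion and the image/mask warps.
    """

    def __init__(self, phantom: Phantom, tol: float = 1e-3):
        self.phantom = phantom
        self.tol = tol
        self.tumor = phantom.structures["CTV"]
        self.lung = phantom.lung_union | self.tumor
        self.potential = HarmonicPotential(self.tumor, self.lung, phantom.grid, tol=tol)

    def clamp(self, shift) -> np.ndarray:
        return clamp_shift_to_lung_wall(shift, self.tumor, self.lung, self.phantom.grid)

    def field_for(self, shift) -> DisplacementField:
        clamped = self.clamp(shift)
        spec = DeformationSpec(tuple(clamped), self.tumor, self.lung)
        return solve_laplacian_dvf(self.phantom, spec, tol=self.tol,
                                   potential=self.potential)

    def deform(self, shift,
               warp_structures: tuple[str, ...] | None = ("CTV", "lung_ipsi")
               ) -> tuple[Phantom, DisplacementField]:
        """Deformed phantom (warped HU + masks) and the displacement field.

        Only the masks named in ``warp_structures`` are resampled (``None``
        warps all).  Structures outside the deformation domain — body, chest
        wall, mediastinal organs — are unchanged by a lung-interior field, so
        copying their reference masks is exact and much cheaper.
        """
        fld = self.field_for(shift)
        if fld.is_zero:
            return self.phantom, fld
        hu = warp_image(self.phantom.hu, fld, mode="linear")
        if warp_structures is None:
            warp_structures = tuple(self.phantom.structures)
        structures = {name: (warp_image(mask, fld, mode="nearest")
                             if name in warp_structures else mask)
                      for name, mask in self.phantom.structures.items()}
        deformed = Phantom(grid=self.phantom.grid, hu=hu, structures=structures,
                           config=self.phantom.config,
                           meta={**self.phantom.meta,
                                 "tumor_shift_mm": tuple(float(v) for v in fld.meta.get("tumor_shift", (0, 0, 0)))})
        return deformed, fld
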