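"""Harmonic displacement fields: clamping, harmonicity, inversion, warping."""

import numpy as np
import pytest
from scipy import ndimage

from bhrobust.deformation import (BreathHoldDeformer, DeformationSpec,
                                  DisplacementField, HarmonicPotential,
                                  accumulate_dose_on_reference,
                                  clamp_shift_to_lung_wall, invert_dvf,
                                  solve_laplacian_dvf, warp_image)
from bhrobust.grid import GeometryError, VoxelGrid


def binary_search_clamp_oracle(shift, tumor, lung, grid, clearance_vox=1.0):
    """Independent feasibility oracle: bisection on the scale factor, testing
    the voxel-shifted tumor mask against the per-voxel clearance floor
    min(target clearance, initial clearance)."""
    spacing = np.asarray(grid.spacing)
    edt = ndimage.distance_transform_edt(lung, sampling=grid.spacing)
    pts = np.argwhere(tumor)
    h = spacing.min()
    floor = np.clip(np.minimum((clearance_vox + 0.5) * h,
                               edt[tuple(pts.T)] - 0.5 * h), h, None)

    def feasible(alpha):
        disp = np.asarray(shift) * alpha / spacing
        moved = np.round(pts + disp).astype(int)
        if (moved < 0).any() or (moved >= np.asarray(grid.shape)).any():
            return False
        return bool((edt[tuple(moved.T)] >= floor - h).all())

    if feasible(1.0):
        return np.asarray(shift, float)
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = (lo + hi) / 2
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return np.asarray(shift) * lo


class TestClamp:
    def test_zero_shift_identity(self, deformer3):
        assert np.allclose(deformer3.clamp((0.0, 0.0, 0.0)), 0.0)

    def test_feasible_shift_unchanged(self, deformer3):
        gap = deformer3.phantom.meta["tumor_wall_gap_mm"]
        small = np.array([0.0, 0.0, min(2.0, gap / 4)])
        assert np.allclose(deformer3.clamp(small), small)

    @pytest.mark.parametrize("shift", [(-25.0, 0.0, 0.0), (18.0, 10.0, 0.0),
                                       (0.0, 0.0, 40.0), (-12.0, -12.0, -12.0),
                                       (25.0, 0.0, 0.0), (0.0, -30.0, 8.0)])
    def test_clamped_tumor_never_escapes_lung(self, deformer3, shift):
        grid = deformer3.phantom.grid
        clamped = deformer3.clamp(shift)
        # direction preserved, magnitude <= requested
        n_req = np.linalg.norm(shift)
        assert np.linalg.norm(clamped) <= n_req + 1e-9
        if np.linalg.norm(clamped) > 0:
            assert np.allclose(np.cross(clamped, shift), 0.0, atol=1e-6 * n_req ** 2)
        # the clamped tumor must stay inside the lung (voxelized check) and be
        # feasible for the independent bisection oracle
        pts = np.argwhere(deformer3.tumor)
        moved = np.round(pts + clamped / np.asarray(grid.spacing)).astype(int)
        moved = np.clip(moved, 0, np.asarray(grid.shape) - 1)
        assert deformer3.lung[tuple(moved.T)].all()
        oracle = binary_search_clamp_oracle(clamped if np.linalg.norm(clamped) > 0
                                            else shift, deformer3.tumor,
                                            deformer3.lung, grid)
        assert np.linalg.norm(oracle) >= np.linalg.norm(clamped) - 1e-9

    def test_head_on_wall_shift_matches_bisection_oracle(self, deformer3):
        # straight toward the nearest (lateral) lung wall the clearance
        # gradient is steep and the bisection oracle pins the feasible travel
        grid = deformer3.phantom.grid
        lat = -1.0 if deformer3.phantom.config.laterality == "left" else 1.0
        shift = (lat * 25.0, 0.0, 0.0)
        clamped = deformer3.clamp(shift)
        oracle = binary_search_clamp_oracle(shift, deformer3.tumor, deformer3.lung, grid)
        assert abs(np.linalg.norm(clamped) - np.linalg.norm(oracle)) \
            <= 1.5 * max(grid.spacing)
        assert np.linalg.norm(clamped) < np.linalg.norm(shift)  # actually clamped

    def test_tumor_outside_lung_rejected(self, phantom3):
        bad_tumor = ~phantom3.structures["body"]
        with pytest.raises(GeometryError):
            clamp_shift_to_lung_wall((1.0, 0.0, 0.0), bad_tumor,
                                     phantom3.lung_union, phantom3.grid)


class TestLaplacianField:
    def test_zero_shift_gives_zero_field(self, phantom3, deformer3):
        spec = DeformationSpec((0.0, 0.0, 0.0), deformer3.tumor, deformer3.lung)
        fld = solve_laplacian_dvf(phantom3, spec, potential=deformer3.potential)
        assert fld.is_zero

    def test_dirichlet_boundary_exactness(self, phantom3, deformer3):
        shift = (2.0, -3.0, 1.5)
        spec = DeformationSpec(shift, deformer3.tumor, deformer3.lung)
        fld = solve_laplacian_dvf(phantom3, spec, potential=deformer3.potential)
        # exact shift on tumor voxels, exact zero outside the lung
        assert np.allclose(fld.vectors[deformer3.tumor], shift)
        assert np.all(fld.vectors[~deformer3.lung] == 0.0)

    def test_interior_harmonicity(self, deformer3):
        # discrete mean-value property: residual below solver tolerance
        assert deformer3.potential.residual() < deformer3.tol

    def test_linearity_in_shift(self, phantom3, deformer3):
        s = np.array([1.0, 2.0, -1.0])
        f1 = solve_laplacian_dvf(phantom3, DeformationSpec(tuple(s), deformer3.tumor,
                                                           deformer3.lung),
                                 potential=deformer3.potential)
        f2 = solve_laplacian_dvf(phantom3, DeformationSpec(tuple(2.5 * s),
                                                           deformer3.tumor,
                                                           deformer3.lung),
                                 potential=deformer3.potential)
        assert np.allclose(2.5 * f1.vectors, f2.vectors, atol=1e-9)

    def test_1d_slab_matches_linear_closed_form(self):
        # lung slab spanning the full cross-section: the potential between the
        # tumor plane and the wall is exactly linear (1D Laplace solution)
        grid = VoxelGrid(shape=(16, 16, 40), spacing=(3.0, 3.0, 3.0))
        lung = np.zeros(grid.shape, dtype=bool)
        tumor = np.zeros(grid.shape, dtype=bool)
        lung[:, :, 4:36] = True     # wall voxels at k=3 and k=36
        tumor[:, :, 4:8] = True     # tumor occupies the proximal slab
        pot = HarmonicPotential(tumor, lung, grid, tol=1e-6)
        ks = np.arange(8, 36)
        profile = pot.phi[8, 8, ks]
        # linear decay from 1 at the last tumor plane (k=7) to 0 at the wall (k=36)
        expected = (36 - ks) / (36 - 7)
        s = 6.0  # a 6 mm shift: agreement within 1% of the shift magnitude
        assert np.max(np.abs(profile - expected)) * s < 0.01 * s


class TestInverseAndWarp:
    def test_zero_field_inverse_and_warp(self, phantom3):
        fld = DisplacementField(grid=phantom3.grid,
                                vectors=np.zeros((*phantom3.grid.shape, 3)),
                                domain=phantom3.lung_union)
        invert_dvf(fld)
        assert not fld.inverse_vectors.any()
        out = warp_image(phantom3.hu, fld)
        assert np.array_equal(out, phantom3.hu)
        assert np.array_equal(accumulate_dose_on_reference(phantom3.hu, fld),
                              phantom3.hu)

    def test_translation_field_inverse_is_negation(self):
        grid = VoxelGrid(shape=(24, 24, 24), spacing=(3.0, 3.0, 3.0))
        t = np.array([4.0, -2.0, 3.0])
        vectors = np.broadcast_to(t, (*grid.shape, 3)).copy()
        domain = np.ones(grid.shape, dtype=bool)
        fld = DisplacementField(grid=grid, vectors=vectors, domain=domain)
        invert_dvf(fld)
        interior = (slice(6, 18),) * 3
        assert np.allclose(fld.inverse_vectors[interior], -t, atol=1e-6)

    def test_composition_residual_below_quarter_voxel(self, deformer3):
        clamped = deformer3.clamp((0.0, 0.0, 4.0))
        fld = deformer3.field_for(clamped)
        invert_dvf(fld)
        rms = fld.meta["inverse_residual_rms_mm"]
        assert rms < 0.25 * min(deformer3.phantom.grid.spacing)

    def test_warp_moves_tumor_centroid_by_shift(self, deformer3):
        shift = deformer3.clamp((0.0, 0.0, 4.0))
        img, fld = deformer3.deform(shift)
        spacing = np.asarray(deformer3.phantom.grid.spacing)
        c0 = np.array(ndimage.center_of_mass(deformer3.phantom.structures["CTV"])) * spacing
        c1 = np.array(ndimage.center_of_mass(img.structures["CTV"])) * spacing
        assert np.all(np.abs((c1 - c0) - shift) <= 0.5 * spacing + 1e-9)

    def test_warp_roundtrip_error_small(self, deformer3):
        fld = deformer3.field_for(deformer3.clamp((3.0, 0.0, 3.0)))
        smooth = np.sin(np.indices(fld.grid.shape)[2] / 4.0) * 100.0
        warped = warp_image(smooth, fld)
        back = accumulate_dose_on_reference(warped, fld)
        lung = deformer3.lung
        rms = np.sqrt(np.mean((back - smooth)[lung] ** 2))
        assert rms < 0.05 * np.ptp(smooth)  # interpolation bound, measured

    def test_accumulation_preserves_integral_dose(self, deformer3, engine):
        from bhrobust.dose import build_plan

        shift = deformer3.clamp((0.0, 0.0, 4.0))
        img, fld = deformer3.deform(shift)
        plan = build_plan(deformer3.phantom, "photon", 6.0, engine=engine)
        dose = engine.plan_dose(plan, img, "deformed-z4")
        acc = accumulate_dose_on_reference(dose, fld)
        body = deformer3.phantom.structures["body"]
        assert acc[body].sum() == pytest.approx(dose[body].sum(), rel=0.02)

    def test_accumulation_maps_peak_back_by_minus_shift(self, deformer3):
        # a dose spike at the deformed tumor position returns to the reference
        # tumor position under accumulation
        shift = deformer3.clamp((0.0, 0.0, 6.0))
        img, fld = deformer3.deform(shift)
        spacing = np.asarray(fld.grid.spacing)
        dose = ndimage.gaussian_filter(img.structures["CTV"].astype(float), 1.5)
        acc = accumulate_dose_on_reference(dose, fld)
        p_def = np.array(np.unravel_index(np.argmax(dose), dose.shape)) * spacing
        p_ref = np.array(np.unravel_index(np.argmax(acc), acc.shape)) * spacing
        assert np.all(np.abs((p_ref - p_def) + np.asarray(shift)) <= spacing + 1e-9)
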