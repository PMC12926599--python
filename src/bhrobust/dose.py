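"""Simplified analytic photon and proton dose engines.

These engines replace a clinical treatment-planning system with transparent
analytic models whose purpose is a correct *sensitivity structure* — response
to setup shifts, deformed anatomy and stopping-power perturbations — not
clinical dosimetric accuracy:

* photon: parallel beams with a build-up x exponential-attenuation depth dose
  of radiological depth, and an error-function penumbra around a static
  aperture conformed to the target projection plus a margin;
* proton: pencil-beam-scanning-like beams; per energy layer an analytic
  Bragg curve (proximal plateau + Gaussian peak) of water-equivalent path
  length (WEPL), a Gaussian lateral spot profile, NNLS-flattened layer
  weights forming a spread-out Bragg peak, and a constant RBE of 1.1.

All beams lie in the axial plane.  Dose is computed in beam's-eye-view (BEV)
coordinates — the volume rotated so the beam travels along the +AP array
axis — and rotated back.  In this parallel-beam geometry a rigid patient
setup shift is exactly equivalent to the opposite lateral offset of the
aperture/spot pattern in BEV (the along-beam component has no effect), which
is how setup scenarios are applied.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls
from scipy.special import erfc

from .grid import VoxelGrid
from .phantom import Phantom, hu_to_density, hu_to_spr


@dataclass(frozen=True)
class EngineParams:
    """Tunable constants of the analytic dose models (mm unless noted)."""

    photon_mu_per_mm: float = 0.0046  # exponential attenuation coefficient
    photon_buildup_mm: float = 10.0   # build-up depth constant
    penumbra_sigma_mm: float = 3.0    # photon aperture penumbra
    proton_plateau: float = 0.4       # Bragg entrance plateau relative to peak
    bragg_sigma_mm: float = 5.0       # Bragg peak Gaussian width
    distal_sigma_mm: float = 3.0      # distal fall-off width of the plateau term
    lateral_sigma_mm: float = 5.0     # proton spot lateral sigma
    layer_spacing_mm: float = 4.0     # WEPL spacing between energy layers
    range_margin_mm: float = 6.0      # proximal/distal layer margin around the CTV
    max_layers_per_subbeam: int = 10  # beams with more layers are split
    rbe_proton: float = 1.1
    mc_noise_sd: float = 0.0          # optional relative Gaussian dose noise


@dataclass
class EnergyLayer:
    """One PBS energy layer: nominal range (mm WEPL) and its lateral fluence."""

    nominal_range: float
    layer_weight: float
    lateral_sigma: float
    spots: np.ndarray          # (n, 3): BEV lateral x, z (mm) and spot weight
    lateral_fluence: np.ndarray  # 2D BEV (x, z) map: blurred, weighted spots


@dataclass
class Beam:
    """A treatment beam in the axial plane.

    ``angle_deg`` is the azimuth of the travel direction
    d = (sin a, cos a, 0) on the (LR, AP, CC) axes.  Photon beams carry a
    signed-distance map to the nominal target projection edge (negative
    inside) from which aperture segments at different margins are formed;
    proton beams carry energy layers.
    """

    modality: str
    angle_deg: float
    aperture_dist: np.ndarray | None = None  # photon: 2D BEV (x, z) signed distance, mm
    segment_margins: tuple[float, ...] = ()  # photon aperture margins, mm
    layers: list[EnergyLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.modality == "proton" and self.layers is not None and len(self.layers) == 0:
            # populated later by make_proton_beams
            pass


@dataclass(frozen=True)
class PlanVariable:
    """One nonnegative optimization weight: a photon aperture segment or a
    proton sub-beam (contiguous block of energy layers)."""

    unit_index: int
    beam_index: int
    segment_margin: float | None = None     # photon
    layer_indices: tuple[int, ...] = ()     # proton


@dataclass(frozen=True)
class PlanUnit:
    """One breath-hold delivery unit: a photon beam or a proton sub-beam."""

    beam_index: int
    var_indices: tuple[int, ...]
    label: str


@dataclass
class Plan:
    """A treatment plan: beams, delivery units, nonnegative variable weights."""

    modality: str
    beams: list[Beam]
    units: list[PlanUnit]
    variables: list[PlanVariable]
    weights: np.ndarray
    n_fractions: int = 3
    prescription_gy: float = 54.0
    normalization_scale: float = 1.0
    strategy_name: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("plan weights must be nonnegative")
        if self.normalization_scale <= 0:
            raise ValueError("normalization scale must be positive")

    @property
    def rbe(self) -> float:
        return 1.1 if self.modality == "proton" else 1.0

    def scaled(self, scale: float) -> "Plan":
        p = replace(self)
        p.weights = self.weights * scale
        p.normalization_scale = self.normalization_scale * scale
        return p


@dataclass
class DoseGrid:
    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid.validate_volume(self.values)
        if not np.isfinite(self.values).all() or (self.values < -1e-9).any():
            raise ValueError("dose must be finite and nonnegative")


# ---------------------------------------------------------------------------
# depth-dose primitives

def photon_pdd(depth_mm: np.ndarray, params: EngineParams) -> np.ndarray:
    """Normalized photon depth dose: build-up then exponential attenuation."""
    d = np.maximum(np.asarray(depth_mm, dtype=float), 0.0)
    raw = (1.0 - np.exp(-d / params.photon_buildup_mm)) * np.exp(-params.photon_mu_per_mm * d)
    dd = np.linspace(0, 5 * params.photon_buildup_mm, 400)
    peak = ((1.0 - np.exp(-dd / params.photon_buildup_mm))
            * np.exp(-params.photon_mu_per_mm * dd)).max()
    return raw / peak


def bragg_curve(u_mm: np.ndarray, params: EngineParams) -> np.ndarray:
    """Analytic Bragg curve vs. (WEPL - nominal range); peak normalized to 1."""
    u = np.asarray(u_mm, dtype=float)
    from scipy.special import ndtr
    raw = (params.proton_plateau * ndtr(-u / params.distal_sigma_mm)
           + np.exp(-0.5 * (u / params.bragg_sigma_mm) ** 2))
    uu = np.linspace(-5 * params.bragg_sigma_mm, 5 * params.bragg_sigma_mm, 800)
    peak = (params.proton_plateau * ndtr(-uu / params.distal_sigma_mm)
            + np.exp(-0.5 * (uu / params.bragg_sigma_mm) ** 2)).max()
    return raw / peak


# ---------------------------------------------------------------------------
# BEV machinery

def _bev_rotate(volume: np.ndarray, angle_deg: float, inverse: bool = False,
                order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Rotate a volume about the CC axis so the beam travels along +AP.

    ``ndimage.rotate(v, a, axes=(0, 1))`` maps the +LR direction onto +AP for
    a = 90; rotating by the beam azimuth therefore aligns the travel
    direction d = (sin a, cos a) with the +AP array axis.
    """
    a = -angle_deg if inverse else angle_deg
    return ndimage.rotate(volume, a, axes=(0, 1), reshape=False, order=order,
                          mode="constant", cval=cval)


def bev_lateral_offset(setup_shift, angle_deg: float) -> tuple[float, float]:
    """BEV (x, z) aperture offset equivalent to a rigid patient shift.

    A patient displaced by t sees the beam pattern displaced by -t; projected
    on the BEV lateral axes ex' = (cos a, -sin a, 0) and ez' = (0, 0, 1).
    """
    t = np.asarray(setup_shift, dtype=float)
    a = np.deg2rad(angle_deg)
    ox = -(t[0] * np.cos(a) - t[1] * np.sin(a))
    oz = -t[2]
    return float(ox), float(oz)


class AnalyticDoseEngine:
    """Computes per-variable/unit/plan doses with per-image BEV caching.

    Images are identified by a caller-supplied string key; rotated density,
    SPR, WEPL and body masks are memoized per (key, angle) with a bounded
    LRU cache.  The SPR perturbation enters as an exact linear scaling of the
    cached WEPL, so photon doses are invariant to it by construction.
    """

    def __init__(self, params: EngineParams | None = None, cache_entries: int = 512):
        self.params = params or EngineParams()
        self._cache: OrderedDict[tuple, np.ndarray] = OrderedDict()
        self._cache_entries = cache_entries

    def _memo(self, key: tuple, fn):
        if key in self._cache:
            self._cache.move_to_end(key)
            return self._cache[key]
        val = fn()
        self._cache[key] = val
        if len(self._cache) > self._cache_entries:
            self._cache.popitem(last=False)
        return val

    def clear_cache(self) -> None:
        self._cache.clear()

    # cached per-image BEV quantities -------------------------------------
    def _density_bev(self, image: Phantom, key: str, angle: float) -> np.ndarray:
        return self._memo(("rho", key, round(angle, 3)),
                          lambda: _bev_rotate(hu_to_density(image.hu), angle).astype(np.float32))

    def _body_bev(self, image: Phantom, key: str, angle: float) -> np.ndarray:
        return self._memo(("body", key, round(angle, 3)),
                          lambda: _bev_rotate(image.structures["body"].astype(np.float32),
                                              angle) > 0.5)

    def _radiological_depth_bev(self, image: Phantom, key: str, angle: float) -> np.ndarray:
        def build():
            rho = self._density_bev(image, key, angle)
            dy = image.grid.spacing[1]
            return ((np.cumsum(rho, axis=1) - 0.5 * rho) * dy).astype(np.float32)
        return self._memo(("rdepth", key, round(angle, 3)), build)

    def _pdd_bev(self, image: Phantom, key: str, angle: float) -> np.ndarray:
        return self._memo(("pdd", key, round(angle, 3)),
                          lambda: photon_pdd(self._radiological_depth_bev(image, key, angle),
                                             self.params).astype(np.float32))

    def _wepl_bev(self, image: Phantom, key: str, angle: float) -> np.ndarray:
        def build():
            spr = _bev_rotate(hu_to_spr(image.hu), angle).astype(np.float32)
            spr = np.clip(spr, 0.0, None)
            dy = image.grid.spacing[1]
            return ((np.cumsum(spr, axis=1) - 0.5 * spr) * dy).astype(np.float32)
        return self._memo(("wepl", key, round(angle, 3)), build)

    # dose computation -----------------------------------------------------
    def _shift_map(self, m: np.ndarray, ox: float, oz: float, grid: VoxelGrid) -> np.ndarray:
        if ox == 0.0 and oz == 0.0:
            return m
        return ndimage.shift(m, (ox / grid.spacing[0], oz / grid.spacing[2]),
                             order=1, mode="nearest")

    def variable_dose(self, plan: Plan, var: PlanVariable, image: Phantom,
                      image_key: str, setup_shift=(0.0, 0.0, 0.0),
                      spr_perturbation: float = 0.0) -> np.ndarray:
        """Unit-weight dose (Gy, RBE-weighted for protons) of one variable."""
        beam = plan.beams[var.beam_index]
        ox, oz = bev_lateral_offset(setup_shift, beam.angle_deg)
        if plan.modality == "photon":
            pdd = self._pdd_bev(image, image_key, beam.angle_deg)
            dist = self._shift_map(beam.aperture_dist, ox, oz, image.grid)
            trans = 0.5 * erfc((dist - var.segment_margin)
                               / (np.sqrt(2.0) * self.params.penumbra_sigma_mm))
            dose_bev = pdd * trans[:, None, :]
        else:
            wepl = self._wepl_bev(image, image_key, beam.angle_deg)
            wepl = wepl * (1.0 + spr_perturbation / 100.0)
            dose_bev = np.zeros_like(wepl, dtype=float)
            for li in var.layer_indices:
                layer = beam.layers[li]
                lat = self._shift_map(layer.lateral_fluence, ox, oz, image.grid)
                dose_bev += bragg_curve(wepl - layer.nominal_range, self.params) \
                    * lat[:, None, :]
            dose_bev *= self.params.rbe_proton
        dose = _bev_rotate(dose_bev, beam.angle_deg, inverse=True)
        dose *= image.structures["body"]
        return np.clip(dose, 0.0, None)

    def unit_dose(self, plan: Plan, unit: PlanUnit, image: Phantom, image_key: str,
                  setup_shift=(0.0, 0.0, 0.0), spr_perturbation: float = 0.0,
                  weights: np.ndarray | None = None) -> np.ndarray:
        """Weighted dose of one delivery unit (single BEV->reference rotation)."""
        w = plan.weights if weights is None else weights
        if all(w[vi] == 0.0 for vi in unit.var_indices):
            return np.zeros(image.grid.shape)
        beam = plan.beams[unit.beam_index]
        ox, oz = bev_lateral_offset(setup_shift, beam.angle_deg)
        if plan.modality == "photon":
            pdd = self._pdd_bev(image, image_key, beam.angle_deg)
            dist = self._shift_map(beam.aperture_dist, ox, oz, image.grid)
            trans = np.zeros_like(dist)
            for vi in unit.var_indices:
                if w[vi] == 0.0:
                    continue
                m = plan.variables[vi].segment_margin
                trans += w[vi] * 0.5 * erfc((dist - m)
                                            / (np.sqrt(2.0) * self.params.penumbra_sigma_mm))
            dose_bev = pdd * trans[:, None, :]
        else:
            wepl = self._wepl_bev(image, image_key, beam.angle_deg) \
                * (1.0 + spr_perturbation / 100.0)
            dose_bev = np.zeros(image.grid.shape, dtype=np.float32)
            for vi in unit.var_indices:
                if w[vi] == 0.0:
                    continue
                for li in plan.variables[vi].layer_indices:
                    layer = beam.layers[li]
                    lat = self._shift_map(layer.lateral_fluence, ox, oz, image.grid)
                    dose_bev += w[vi] * bragg_curve(wepl - layer.nominal_range,
                                                    self.params) * lat[:, None, :]
            dose_bev *= self.params.rbe_proton
        dose = _bev_rotate(dose_bev, beam.angle_deg, inverse=True)
        dose *= image.structures["body"]
        return np.clip(dose, 0.0, None)

    def plan_dose(self, plan: Plan, image: Phantom, image_key: str,
                  setup_shift=(0.0, 0.0, 0.0), spr_perturbation: float = 0.0) -> np.ndarray:
        dose = np.zeros(image.grid.shape)
        for unit in plan.units:
            dose += self.unit_dose(plan, unit, image, image_key, setup_shift,
                                   spr_perturbation)
        return dose


def compute_scenario_dose(plan: Plan, image: Phantom, engine: AnalyticDoseEngine,
                          setup_shift=(0.0, 0.0, 0.0), spr_perturbation: float = 0.0,
                          image_key: str = "nominal") -> DoseGrid:
    """Full plan dose for one scenario, on the (possibly deformed) image grid.

    The setup shift is applied as a rigid isocenter translation (lateral
    aperture offset in BEV, exact for parallel beams); accumulation back to
    the reference geometry is the caller's responsibility via the image's
    displacement field.
    """
    if plan.modality == "photon" and spr_perturbation != 0.0:
        raise ValueError("photon plans take no SPR perturbation scenarios")
    values = engine.plan_dose(plan, image, image_key, setup_shift, spr_perturbation)
    return DoseGrid(grid=image.grid, values=values)


def add_mc_noise(dose: np.ndarray, sd_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Optional seeded Gaussian dose noise mimicking Monte-Carlo uncertainty."""
    if sd_fraction <= 0:
        return dose
    return np.clip(dose * (1.0 + rng.normal(0.0, sd_fraction, size=dose.shape)), 0.0, None)


# ---------------------------------------------------------------------------
# beam construction

def radiological_path(phantom: Phantom, entry_mm, direction, quantity: str = "spr",
                      step_mm: float = 1.0, n_steps: int | None = None):
    """Cumulative water-equivalent depth along a ray (mm), sampled at ``step_mm``.

    Returns (distances, cumulative WEPL); both empty if the ray misses the body.
    """
    vol = hu_to_spr(phantom.hu) if quantity == "spr" else hu_to_density(phantom.hu)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if n_steps is None:
        n_steps = int(np.ceil(np.linalg.norm(phantom.grid.extent_mm) / step_mm))
    ts = (np.arange(n_steps) + 0.5) * step_mm
    pts = np.asarray(entry_mm, dtype=float)[None, :] + ts[:, None] * d[None, :]
    idx = phantom.grid.world_to_index(pts).T
    vals = ndimage.map_coordinates(vol, idx, order=1, mode="constant", cval=0.0)
    body = ndimage.map_coordinates(phantom.structures["body"].astype(np.float32),
                                   idx, order=0, mode="constant", cval=0.0)
    if not (body > 0).any():
        return np.array([]), np.array([])
    return ts, np.cumsum(vals * step_mm)


def default_beam_angles(phantom: Phantom, modality: str) -> list[float]:
    """Geometric default gantry azimuths entering from the tumor-bearing side."""
    c = phantom.grid.center_mm
    t = np.asarray(phantom.meta.get("tumor_center_mm", c))
    radial = c[:2] - t[:2]
    if np.linalg.norm(radial) < 1e-6:
        radial = np.array([0.0, 1.0])
    base = float(np.rad2deg(np.arctan2(radial[0], radial[1])))
    if modality == "photon":
        return [base + o for o in (-120.0, -75.0, -30.0, 30.0, 75.0, 120.0)]
    return [base + o for o in (-50.0, 0.0, 50.0)]


def _ctv_projection_dist(phantom: Phantom, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """(projection mask, signed distance mm to its edge) of the CTV in BEV (x, z)."""
    ctv_bev = _bev_rotate(phantom.structures["CTV"].astype(np.float32), angle) > 0.5
    proj = ctv_bev.any(axis=1)
    sampling = (phantom.grid.spacing[0], phantom.grid.spacing[2])
    outside = ndimage.distance_transform_edt(~proj, sampling=sampling)
    inside = ndimage.distance_transform_edt(proj, sampling=sampling)
    return proj, (outside - inside)


def make_photon_beams(phantom: Phantom, lateral_margin_mm: float,
                      params: EngineParams,
                      angles: Sequence[float] | None = None) -> list[Beam]:
    """Photon beams with static apertures: CTV projection + concentric margins."""
    angles = list(angles) if angles is not None else default_beam_angles(phantom, "photon")
    margins = tuple(max(2.0, lateral_margin_mm + o) for o in (-4.0, 0.0, 4.0))
    beams = []
    for a in angles:
        _, dist = _ctv_projection_dist(phantom, a)
        beams.append(Beam(modality="photon", angle_deg=a, aperture_dist=dist,
                          segment_margins=margins))
    return beams


def _sobp_layer_weights(ranges: np.ndarray, w_lo: float, w_hi: float,
                        params: EngineParams) -> np.ndarray:
    """NNLS layer weights flattening the summed Bragg curves over [w_lo, w_hi]."""
    depths = np.linspace(w_lo - 30.0, w_hi + 15.0, 240)
    M = bragg_curve(depths[:, None] - ranges[None, :], params)
    sel = (depths >= w_lo + 2.0) & (depths <= w_hi - 2.0)
    if sel.sum() < 2:
        sel = (depths >= w_lo) & (depths <= w_hi)
    sol, _ = nnls(M[sel], np.ones(int(sel.sum())))
    if sol.max() > 0:
        sol = sol / sol.max()
    else:
        sol = np.ones_like(sol)
    return sol


def make_proton_beams(phantom: Phantom, lateral_margin_mm: float,
                      params: EngineParams,
                      angles: Sequence[float] | None = None,
                      engine: AnalyticDoseEngine | None = None) -> list[Beam]:
    """Proton PBS beams: energy layers spanning the CTV WEPL extent (deepest
    first), spots on the voxel lattice covering the CTV projection + margin."""
    angles = list(angles) if angles is not None else default_beam_angles(phantom, "proton")
    engine = engine or AnalyticDoseEngine(params)
    grid = phantom.grid
    beams = []
    for a in angles:
        proj, dist = _ctv_projection_dist(phantom, a)
        wepl = engine._wepl_bev(phantom, "nominal", a)
        ctv_bev = _bev_rotate(phantom.structures["CTV"].astype(np.float32), a) > 0.5
        w_ctv = wepl[ctv_bev]
        w_lo = float(w_ctv.min()) - params.range_margin_mm
        w_hi = float(w_ctv.max()) + params.range_margin_mm
        ranges = np.arange(w_hi, w_lo - 1e-9, -params.layer_spacing_mm)
        layer_w = _sobp_layer_weights(ranges, w_lo, w_hi, params)

        spot_region = dist <= lateral_margin_mm
        raster = spot_region.astype(float)
        sig_vox = (params.lateral_sigma_mm / grid.spacing[0],
                   params.lateral_sigma_mm / grid.spacing[2])
        xs = grid.coords(0)
        zs = grid.coords(2)
        ii, kk = np.nonzero(spot_region)
        spot_pos = np.column_stack([xs[ii], zs[kk]])
        layers = []
        for R, lw in zip(ranges, layer_w):
            fluence = ndimage.gaussian_filter(raster * lw, sig_vox)
            spots = np.column_stack([spot_pos, np.full(len(spot_pos), lw)])
            layers.append(EnergyLayer(nominal_range=float(R), layer_weight=float(lw),
                                      lateral_sigma=params.lateral_sigma_mm,
                                      spots=spots, lateral_fluence=fluence))
        beams.append(Beam(modality="proton", angle_deg=a, layers=layers))
    return beams


def split_energy_layers(beam: Beam, max_layers: int = 10) -> list[tuple[int, ...]]:
    """Indices of successive energy layers per sub-beam.

    Beams with more than ``max_layers`` layers are split into two sub-beams:
    the first ceil(n/2) successive (deepest-first) layers and the remaining
    floor(n/2) — so each fits in a single breath-hold.
    """
    if beam.modality != "proton":
        raise ValueError("only proton beams have energy layers")
    n = len(beam.layers)
    if n <= max_layers:
        return [tuple(range(n))]
    first = int(np.ceil(n / 2))
    return [tuple(range(first)), tuple(range(first, n))]


def build_plan(phantom: Phantom, modality: str, lateral_margin_mm: float,
               params: EngineParams | None = None,
               angles: Sequence[float] | None = None,
               engine: AnalyticDoseEngine | None = None,
               strategy_name: str = "") -> Plan:
    """Assemble an (unoptimized, unit-weight) plan for the phantom."""
    params = params or EngineParams()
    if modality == "photon":
        beams = make_photon_beams(phantom, lateral_margin_mm, params, angles)
        variables, units = [], []
        for bi, beam in enumerate(beams):
            vis = []
            for m in beam.segment_margins:
                vis.append(len(variables))
                variables.append(PlanVariable(unit_index=bi, beam_index=bi,
                                              segment_margin=m))
            units.append(PlanUnit(beam_index=bi, var_indices=tuple(vis),
                                  label=f"beam{bi}"))
    elif modality == "proton":
        beams = make_proton_beams(phantom, lateral_margin_mm, params, angles, engine)
        variables, units = [], []
        for bi, beam in enumerate(beams):
            for si, layer_idx in enumerate(split_energy_layers(
                    beam, params.max_layers_per_subbeam)):
                ui = len(units)
                variables.append(PlanVariable(unit_index=ui, beam_index=bi,
                                              layer_indices=layer_idx))
                units.append(PlanUnit(beam_index=bi, var_indices=(len(variables) - 1,),
                                      label=f"beam{bi}.sub{si}"))
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return Plan(modality=modality, beams=beams, units=units, variables=variables,
                weights=np.ones(len(variables)), strategy_name=strategy_name)
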