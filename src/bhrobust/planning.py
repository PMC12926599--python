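"""Scenario-based (minimax) robust treatment planning.

Implements the three planning strategies per modality:

* ``*3D-PS``   — single image, isotropic patient shifts at the 90% radius of
  the patient-setup errors (5.7 mm with the default error model);
* ``*3D-BH``   — single image, enlarged shifts at the 90% radius of setup and
  breath-hold errors combined (7.0 mm);
* ``*4D-BH``   — 7 deformed planning images (tumor shifted on-axis at the
  breath-hold 90% radius, 4.1 mm) with 5.7 mm patient shifts.

Setup shifts are sampled at 15 positions (center + 6 faces + 8 vertices),
proton strategies add 3 SPR perturbations, giving 15 / 45 / 105 / 315 robust
scenarios.  Nonnegative segment/sub-beam weights minimize a softmax-smoothed
worst case over scenarios of a composite objective: a CTV D50% target of
54 Gy, a quadratic penalty on dose outside the CTV beyond an exponential
fall-off envelope, and a chest-wall hot-spot penalty.  Organs of interest are
not objectives (their sparing comes from the beam arrangement); they are only
reported.  After optimization, plans are normalized so the worst robust
scenario has CTV D50% = 54 Gy exactly (linear in the weights, hence exact up
to dose-grid interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize
from scipy.special import logsumexp

from .deformation import BreathHoldDeformer, DisplacementField
from .dose import AnalyticDoseEngine, EngineParams, Plan, build_plan
from .grid import GeometryError
from .metrics import dose_at_volume
from .phantom import Phantom
from .scenarios import (UncertaintyModel, ci90_radius, ci90_radius_combined,
                        planning_axis_samples, setup_shift_samples, spr_scenarios)

STRATEGY_NAMES = ("proton3D-PS", "proton3D-BH", "proton4D-BH",
                  "photon3D-PS", "photon3D-BH", "photon4D-BH")


@dataclass(frozen=True)
class PlanningStrategy:
    """One row of the strategy table."""

    name: str
    modality: str
    setup_radius_mm: float
    planning_images: int  # 1 or 7
    tumor_shift_radius_mm: float
    spr_set: tuple[float, ...]

    @property
    def scenario_count(self) -> int:
        return self.planning_images * 15 * len(self.spr_set)


@dataclass(frozen=True)
class RobustScenario:
    index: int
    image_id: int
    setup_id: int
    spr_id: int
    setup_shift: tuple[float, float, float]
    spr_perturbation: float


def build_strategy(name: str, model: UncertaintyModel | None = None,
                   spr_set: tuple[float, ...] | None = None
                   ) -> tuple[PlanningStrategy, list[RobustScenario]]:
    """Strategy definition plus its full robust-scenario list."""
    if name not in STRATEGY_NAMES:
        raise ValueError(f"unknown strategy {name!r}; choose from {STRATEGY_NAMES}")
    model = model or UncertaintyModel()
    modality = "proton" if name.startswith("proton") else "photon"
    r_ps = ci90_radius(max(model.Sigma_PS), max(model.sigma_PS))
    r_comb = ci90_radius_combined((max(model.Sigma_PS), max(model.sigma_PS)),
                                  (max(model.Sigma_BH_A), max(model.sigma_BH_A)))
    r_bh = ci90_radius(max(model.Sigma_BH_A), max(model.sigma_BH_A))
    kind = name.split("-")[0][-2:] + "-" + name.split("-")[1]  # '3D-PS' etc.
    if kind == "3D-PS":
        setup_r, images, tumor_r = r_ps, 1, 0.0
    elif kind == "3D-BH":
        setup_r, images, tumor_r = r_comb, 1, 0.0
    elif kind == "4D-BH":
        setup_r, images, tumor_r = r_ps, 7, r_bh
    else:  # pragma: no cover
        raise ValueError(name)
    sprs = spr_scenarios(modality, custom=spr_set)
    strat = PlanningStrategy(name=name, modality=modality, setup_radius_mm=setup_r,
                             planning_images=images, tumor_shift_radius_mm=tumor_r,
                             spr_set=sprs)
    setup = setup_shift_samples(setup_r)
    scenarios = []
    idx = 0
    for img in range(images):
        for si, s in enumerate(setup.samples):
            for di, d in enumerate(sprs):
                scenarios.append(RobustScenario(index=idx, image_id=img, setup_id=si,
                                                spr_id=di,
                                                setup_shift=s.systematic_shift,
                                                spr_perturbation=float(d)))
                idx += 1
    assert len(scenarios) == strat.scenario_count
    return strat, scenarios


@dataclass(frozen=True)
class ObjectiveConfig:
    """Composite-objective weights and shapes (defaults tuned once on the
    default phantom and frozen)."""

    ctv_weight: float = 1.0
    shell_weight: float = 0.02
    chestwall_weight: float = 0.02
    falloff_mm: float = 10.0       # e-folding distance of the fall-off envelope
    shell_radius_mm: float = 18.0  # sampled shell thickness around the CTV
    chestwall_limit_gy: float = 30.0
    softmax_tau: float = 2.0       # worst-case smoothing temperature (Gy^2)
    max_shell_voxels: int = 800
    max_chestwall_voxels: int = 400
    soft_quantile_sigma: float = 2.0  # rank smoothing (voxels) of soft-D50%


def soft_d50(dose_values: np.ndarray, sigma_ranks: float = 2.0) -> float:
    """Differentiable-in-practice median: Gaussian rank-weighted average
    around the interpolated D50% rank (exact for uniform dose)."""
    d = np.sort(np.asarray(dose_values, float))[::-1]
    n = d.size
    r = np.arange(n)
    w = np.exp(-0.5 * ((r - (n / 2.0 - 0.5)) / max(sigma_ranks, 1e-6)) ** 2)
    return float((w * d).sum() / w.sum())


class RobustPlanner:
    """Builds planning images and scenario influence data for one strategy,
    then optimizes, robust-evaluates and normalizes a plan."""

    def __init__(self, phantom: Phantom, strategy_name: str,
                 model: UncertaintyModel | None = None,
                 engine: AnalyticDoseEngine | None = None,
                 deformer: BreathHoldDeformer | None = None,
                 objectives: ObjectiveConfig | None = None,
                 engine_params: EngineParams | None = None,
                 seed: int = 0):
        self.phantom = phantom
        self.model = model or UncertaintyModel()
        self.strategy, self.scenarios = build_strategy(strategy_name, self.model)
        self.engine = engine or AnalyticDoseEngine(engine_params)
        self.deformer = deformer or BreathHoldDeformer(phantom)
        self.objectives = objectives or ObjectiveConfig()
        self.seed = seed
        self.log: list[dict] = []
        self._images: list[tuple[Phantom, DisplacementField | None, str]] | None = None
        self._plan_template: Plan | None = None
        self._influence = None

    # ------------------------------------------------------------------
    def planning_images(self):
        """The 1 (3D) or 7 (4D: zero + on-axis tumor shifts) planning images."""
        if self._images is not None:
            return self._images
        images = [(self.phantom, None, "plan/0")]
        if self.strategy.planning_images > 1:
            shift_set = planning_axis_samples(self.strategy.tumor_shift_radius_mm)
            for i, s in enumerate(shift_set.samples[1:], start=1):
                img, fld = self.deformer.deform(np.asarray(s.combined_shift))
                images.append((img, fld, f"plan/{i}"))
        if len(images) != self.strategy.planning_images:
            raise GeometryError("planning image count mismatch")
        self._images = images
        return images

    def plan_template(self) -> Plan:
        if self._plan_template is None:
            margin = self.strategy.setup_radius_mm + self.strategy.tumor_shift_radius_mm + 2.0
            self._plan_template = build_plan(
                self.phantom, self.strategy.modality, lateral_margin_mm=margin,
                params=self.engine.params, engine=self.engine,
                strategy_name=self.strategy.name)
        return self._plan_template

    # ------------------------------------------------------------------
    def _sample_voxels(self):
        """Per planning image: CTV voxel indices, shell indices + envelope,
        and a deterministic chest-wall subsample."""
        rng = np.random.default_rng(self.seed)
        obj = self.objectives
        grid = self.phantom.grid
        cw = np.argwhere(self.phantom.structures["chest_wall"])
        if len(cw) > obj.max_chestwall_voxels:
            cw = cw[rng.choice(len(cw), obj.max_chestwall_voxels, replace=False)]
        per_image = []
        for img, _, _ in self.planning_images():
            ctv = img.structures["CTV"]
            dist = ndimage.distance_transform_edt(~ctv, sampling=grid.spacing)
            shell_mask = (dist > 0) & (dist <= obj.shell_radius_mm) & img.structures["body"]
            shell = np.argwhere(shell_mask)
            if len(shell) > obj.max_shell_voxels:
                shell = shell[rng.choice(len(shell), obj.max_shell_voxels, replace=False)]
            envelope = self.phantom.meta.get("prescription", 54.0) * np.exp(
                -dist[tuple(shell.T)] / obj.falloff_mm)
            per_image.append({"ctv": np.argwhere(ctv), "shell": shell,
                              "envelope": envelope, "cw": cw})
        return per_image

    def influence(self):
        """Per-scenario dose-influence matrices at the sampled voxels."""
        if self._influence is not None:
            return self._influence
        plan = self.plan_template()
        per_image = self._sample_voxels()
        images = self.planning_images()
        nvar = len(plan.variables)
        infl = []
        for sc in self.scenarios:
            img, _, key = images[sc.image_id]
            vox = per_image[sc.image_id]
            pts = np.vstack([vox["ctv"], vox["shell"], vox["cw"]])
            flat = np.ravel_multi_index(pts.T, self.phantom.grid.shape)
            A = np.empty((len(flat), nvar), dtype=np.float32)
            for vi, var in enumerate(plan.variables):
                d = self.engine.variable_dose(plan, var, img, key,
                                              setup_shift=sc.setup_shift,
                                              spr_perturbation=sc.spr_perturbation)
                A[:, vi] = d.ravel()[flat]
            n_ctv, n_shell = len(vox["ctv"]), len(vox["shell"])
            infl.append({"A": A, "n_ctv": n_ctv, "n_shell": n_shell,
                         "envelope": vox["envelope"], "scenario": sc})
        self._influence = infl
        return infl

    # ------------------------------------------------------------------
    def _scenario_objectives(self, w: np.ndarray) -> np.ndarray:
        obj = self.objectives
        rx = 54.0
        out = np.empty(len(self.scenarios))
        for i, rec in enumerate(self.influence()):
            d = rec["A"] @ w
            nc, ns = rec["n_ctv"], rec["n_shell"]
            d_ctv, d_shell, d_cw = d[:nc], d[nc:nc + ns], d[nc + ns:]
            # Uniform-dose CTV objective: drives the whole target (edges
            # included) to the prescription in every scenario, which is what
            # keeps coverage from collapsing under fraction-wise mixing.
            f = obj.ctv_weight * float(np.mean((d_ctv - rx) ** 2))
            if ns:
                f += obj.shell_weight * float(
                    np.mean(np.clip(d_shell - rec["envelope"], 0.0, None) ** 2))
            if d_cw.size:
                f += obj.chestwall_weight * float(
                    np.mean(np.clip(d_cw - obj.chestwall_limit_gy, 0.0, None) ** 2))
            out[i] = f
        return out

    def composite_objective(self, w: np.ndarray) -> float:
        """Softmax-smoothed worst case over robust scenarios."""
        f = self._scenario_objectives(np.asarray(w, float))
        tau = self.objectives.softmax_tau
        return float(tau * logsumexp(f / tau))

    def initial_weights(self) -> np.ndarray:
        plan = self.plan_template()
        w = np.ones(len(plan.variables))
        nom = self.influence()[self._nominal_index()]
        d50 = soft_d50((nom["A"] @ w)[:nom["n_ctv"]])
        if d50 <= 0:
            raise GeometryError("infeasible plan: no positive CTV dose at unit weights")
        return w * (54.0 / d50)

    def _nominal_index(self) -> int:
        for i, sc in enumerate(self.scenarios):
            if sc.image_id == 0 and sc.setup_id == 0 and sc.spr_perturbation == 0.0:
                return i
        return 0

    def optimize(self, maxiter: int = 120) -> Plan:
        """Minimize the smoothed worst case with nonnegative weights."""
        x0 = self.initial_weights()
        self.log.clear()

        def cb(xk):
            self.log.append({"iter": len(self.log),
                             "objective": self.composite_objective(xk)})

        res = minimize(self.composite_objective, x0, method="L-BFGS-B",
                       bounds=[(0.0, None)] * len(x0),
                       options={"maxiter": maxiter}, callback=cb)
        w = np.clip(res.x, 0.0, None)
        if self.composite_objective(w) > self.composite_objective(x0):
            w = x0  # descent guarantee: never worse than the scaled uniform start
        plan = self.plan_template()
        plan = Plan(modality=plan.modality, beams=plan.beams, units=plan.units,
                    variables=plan.variables, weights=w,
                    n_fractions=plan.n_fractions,
                    strategy_name=self.strategy.name)
        return plan

    # ------------------------------------------------------------------
    def robust_evaluate(self, plan: Plan) -> pd.DataFrame:
        """Exact CTV D50% for every robust scenario of the strategy."""
        rows = []
        for rec in self.influence():
            d_ctv = (rec["A"] @ plan.weights)[:rec["n_ctv"]]
            sc = rec["scenario"]
            rows.append({"scenario": sc.index, "image_id": sc.image_id,
                         "setup_id": sc.setup_id, "spr_id": sc.spr_id,
                         "ctv_d50": dose_at_volume(d_ctv, 50.0)})
        return pd.DataFrame(rows)

    def normalize(self, plan: Plan, evaluation: pd.DataFrame | None = None) -> Plan:
        if evaluation is None:
            evaluation = self.robust_evaluate(plan)
        return normalize_plan(plan, evaluation)


def normalize_plan(plan: Plan, robust_evaluation: pd.DataFrame,
                   prescription_gy: float = 54.0) -> Plan:
    """Scale weights so the worst robust scenario meets the prescription.

    Dose is linear in the weights, so the rescaled minimum is exact up to
    dose-grid interpolation.
    """
    dmin = float(robust_evaluation["ctv_d50"].min())
    if dmin <= 0:
        raise ValueError(f"cannot normalize: minimum scenario CTV D50% = {dmin}")
    return plan.scaled(prescription_gy / dmin)
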