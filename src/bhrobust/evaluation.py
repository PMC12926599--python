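"""Probabilistic treatment evaluation.

Simulates whole treatments from the hierarchical error model — systematic
SPR perturbation, patient-setup and breath-hold position errors, plus
fraction-wise setup and per-breath-hold position errors — and accumulates
dose on the reference geometry from a cache of precomputed scenario doses.

Each sampled treatment consists of 3 fractions; within a fraction every
delivery unit (photon beam or proton sub-beam) is delivered in its own
breath-hold with its own sampled tumor position.  Continuous draws are mapped
to the discrete scenario grids (nearest neighbor in per-axis Mahalanobis
distance), the corresponding reference-geometry unit doses are summed, and
DVH metrics of the accumulated dose are recorded.  Summaries report Avg, SD,
Med, IQR, min, max and p90% — the 10th percentile for CTV dose levels
(coverage with 90% certainty) and the 90th percentile for CTV HI and organs
of interest (avoidance with 90% certainty).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deformation import BreathHoldDeformer, DisplacementField, accumulate_dose_on_reference
from .dose import AnalyticDoseEngine, Plan
from .metrics import DEFAULT_METRICS, dvh_metrics, summarize
from .phantom import Phantom
from .scenarios import (ScenarioSet, UncertaintyModel, ci90_radius,
                        evaluation_shift_grid, setup_shift_samples, spr_scenarios)


@dataclass
class FractionSample:
    patient_shift: np.ndarray          # per-fraction setup error, mm
    bh_shifts: np.ndarray              # (n_units, 3) per-breath-hold tumor shifts, mm


@dataclass
class TreatmentSample:
    """One simulated treatment course (3 fractions)."""

    spr_delta: float
    systematic_patient: np.ndarray
    systematic_bh: np.ndarray
    fractions: list[FractionSample]


def sample_treatment(model: UncertaintyModel, eval_set: str, n_units: int,
                     rng: np.random.Generator, modality: str = "proton",
                     spr_set: tuple[float, ...] | None = None,
                     n_fractions: int = 3) -> TreatmentSample:
    """Draw one treatment from the hierarchical Gaussian error model.

    The systematic SPR perturbation is drawn from the discrete scenario set
    weighted by the N(0, Sigma_SPR) density at each member (always 0 for
    photons).
    """
    Sigma_BH, sigma_BH = model.bh(eval_set)
    if modality == "photon":
        delta = 0.0
    else:
        deltas = np.asarray(spr_set if spr_set is not None else spr_scenarios("proton"))
        if model.Sigma_SPR == 0:
            w = (deltas == 0.0).astype(float)
        else:
            w = np.exp(-0.5 * (deltas / model.Sigma_SPR) ** 2)
        delta = float(rng.choice(deltas, p=w / w.sum()))
    sys_ps = rng.normal(0.0, model.Sigma_PS)
    sys_bh = rng.normal(0.0, Sigma_BH)
    fractions = [FractionSample(patient_shift=rng.normal(0.0, model.sigma_PS),
                                bh_shifts=rng.normal(0.0, sigma_BH, size=(n_units, 3)))
                 for _ in range(n_fractions)]
    return TreatmentSample(spr_delta=delta, systematic_patient=sys_ps,
                           systematic_bh=sys_bh, fractions=fractions)


def _nearest(point: np.ndarray, grid_points: np.ndarray, sds) -> int:
    """Nearest grid point in per-axis Mahalanobis distance; ties break to the
    lowest index (np.argmin convention)."""
    s = np.asarray(sds, dtype=float)
    s = np.where(s > 0, s, 1.0)
    d2 = (((grid_points - point[None, :]) / s[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def map_to_discrete(systematic_shift, per_bh_shift, eval_grid: ScenarioSet,
                    Sigma_BH, sigma_BH) -> int:
    """Map a continuous (systematic, per-BH) shift pair to an evaluation-grid
    image id (grid ordering: 15 systematic x 7 per-BH, systematic outer)."""
    sys_pts = np.array([eval_grid.samples[i * 7].systematic_shift for i in range(15)])
    bh_pts = np.array([eval_grid.samples[i].per_bh_shift for i in range(7)])
    si = _nearest(np.asarray(systematic_shift, float), sys_pts, Sigma_BH)
    bi = _nearest(np.asarray(per_bh_shift, float), bh_pts, sigma_BH)
    return si * 7 + bi


class EvaluationImageProvider:
    """Lazily deformed breath-hold images for one 105-shift evaluation grid."""

    def __init__(self, deformer: BreathHoldDeformer, eval_grid: ScenarioSet,
                 label: str):
        self.deformer = deformer
        self.grid_set = eval_grid
        self.label = label
        self._cache: dict[int, tuple[Phantom, DisplacementField | None, str]] = {}

    def get(self, img_id: int) -> tuple[Phantom, DisplacementField | None, str]:
        if img_id not in self._cache:
            shift = np.asarray(self.grid_set.samples[img_id].combined_shift)
            key = f"{self.label}/{img_id}"
            if np.allclose(shift, 0.0):
                self._cache[img_id] = (self.deformer.phantom, None, key)
            else:
                img, fld = self.deformer.deform(shift)
                self._cache[img_id] = (img, fld, key)
        return self._cache[img_id]


class ScenarioDoseCache:
    """Reference-geometry unit doses keyed by (unit, image, setup, SPR) with a
    bounded LRU; entries are recomputed on demand from the dose engine."""

    def __init__(self, plan: Plan, engine: AnalyticDoseEngine,
                 provider: EvaluationImageProvider, setup_set: ScenarioSet,
                 spr_set: tuple[float, ...], max_entries: int = 1500):
        self.plan = plan
        self.engine = engine
        self.provider = provider
        self.setup_set = setup_set
        self.spr_set = tuple(spr_set)
        self.max_entries = max_entries
        self._cache: OrderedDict[tuple, np.ndarray] = OrderedDict()
        self.misses = 0
        self.hits = 0

    @property
    def n_scenario_combinations(self) -> int:
        """Distinct (evaluation image, setup shift, SPR) dose distributions."""
        return len(self.provider.grid_set) * len(self.setup_set) * len(self.spr_set)

    def spr_index(self, delta: float) -> int:
        try:
            return self.spr_set.index(float(delta))
        except ValueError:
            raise KeyError(f"SPR perturbation {delta} not in cache set {self.spr_set}")

    def get(self, unit_idx: int, img_id: int, setup_id: int, spr_id: int) -> np.ndarray:
        key = (unit_idx, img_id, setup_id, spr_id)
        if key in self._cache:
            self._cache.move_to_end(key)
            self.hits += 1
            return self._cache[key]
        self.misses += 1
        image, fld, ikey = self.provider.get(img_id)
        shift = self.setup_set.samples[setup_id].combined_shift
        dose = self.engine.unit_dose(self.plan, self.plan.units[unit_idx], image,
                                     ikey, setup_shift=shift,
                                     spr_perturbation=self.spr_set[spr_id])
        if fld is not None:
            dose = accumulate_dose_on_reference(dose, fld)
        dose = dose.astype(np.float32)
        self._cache[key] = dose
        if len(self._cache) > self.max_entries:
            self._cache.popitem(last=False)
        return dose


def accumulate_treatment_dose(sample: TreatmentSample, cache: ScenarioDoseCache,
                              plan: Plan, model: UncertaintyModel,
                              eval_set: str) -> np.ndarray:
    """Total reference-geometry dose of one sampled treatment.

    Each fraction delivers every unit once (one breath-hold per unit); the
    combined fraction setup error and per-breath-hold tumor positions are
    mapped to the discrete cache grids.
    """
    Sigma_BH, sigma_BH = model.bh(eval_set)
    setup_pts = np.array([s.systematic_shift for s in cache.setup_set.samples])
    setup_sds = np.sqrt(np.asarray(model.Sigma_PS) ** 2 + np.asarray(model.sigma_PS) ** 2)
    spr_id = cache.spr_index(sample.spr_delta)
    total = np.zeros(cache.provider.deformer.phantom.grid.shape)
    nf = len(sample.fractions)
    for frac in sample.fractions:
        setup_id = _nearest(sample.systematic_patient + frac.patient_shift,
                            setup_pts, setup_sds)
        for u in range(len(plan.units)):
            img_id = map_to_discrete(sample.systematic_bh, frac.bh_shifts[u],
                                     cache.provider.grid_set, Sigma_BH, sigma_BH)
            total += cache.get(u, img_id, setup_id, spr_id)
    return total / nf


@dataclass
class EvaluationResult:
    """Per-sample DVH metrics and their summary for one plan and eval set."""

    strategy: str
    eval_set: str
    n_samples: int
    samples: pd.DataFrame
    summary: pd.DataFrame
    nominal: dict[str, float] = field(default_factory=dict)
    cache_stats: dict[str, int] = field(default_factory=dict)


def evaluate_plan(plan: Plan, phantom: Phantom, deformer: BreathHoldDeformer,
                  engine: AnalyticDoseEngine, model: UncertaintyModel,
                  eval_set: str, n_samples: int = 10000, seed: int = 0,
                  metric_specs=DEFAULT_METRICS,
                  cache: ScenarioDoseCache | None = None,
                  provider: EvaluationImageProvider | None = None) -> EvaluationResult:
    """Probabilistic evaluation: ``n_samples`` simulated treatments."""
    Sigma_BH, sigma_BH = model.bh(eval_set)
    eval_grid = evaluation_shift_grid(Sigma_BH, sigma_BH, label=f"eval{eval_set}_105")
    setup_set = setup_shift_samples(ci90_radius(max(model.Sigma_PS), max(model.sigma_PS)))
    spr_set = spr_scenarios(plan.modality)
    if cache is None:
        if provider is None:
            provider = EvaluationImageProvider(deformer, eval_grid, f"eval{eval_set}")
        cache = ScenarioDoseCache(plan, engine, provider, setup_set, spr_set)
    rng = np.random.default_rng(seed)
    vv = phantom.grid.voxel_volume_mm3
    rows = []
    for _ in range(n_samples):
        s = sample_treatment(model, eval_set, n_units=len(plan.units), rng=rng,
                             modality=plan.modality, spr_set=spr_set,
                             n_fractions=plan.n_fractions)
        dose = accumulate_treatment_dose(s, cache, plan, model, eval_set)
        rows.append(dvh_metrics(dose, phantom.structures, metric_specs, vv))
    samples = pd.DataFrame(rows)
    nominal_dose = engine.plan_dose(plan, phantom, "nominal")
    nominal = dvh_metrics(nominal_dose, phantom.structures, metric_specs, vv)
    return EvaluationResult(strategy=plan.strategy_name, eval_set=eval_set,
                            n_samples=n_samples, samples=samples,
                            summary=summarize(samples), nominal=nominal,
                            cache_stats={"hits": cache.hits, "misses": cache.misses,
                                         "combinations": cache.n_scenario_combinations})
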