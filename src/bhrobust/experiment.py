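"""End-to-end experiment orchestration.

``run_experiment`` loops phantoms x planning strategies x evaluation sets:
generate the phantom, robust-optimize and normalize the six plans, then
probabilistically evaluate each plan against breath-hold reproducibility
sets A and B, writing per-sample tables and summaries.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ExperimentConfig
from .deformation import BreathHoldDeformer
from .dose import AnalyticDoseEngine, Plan
from .evaluation import EvaluationImageProvider, EvaluationResult, evaluate_plan
from .grid import GeometryError
from .io import config_hash, save_plan_json
from .phantom import PhantomConfig, generate_phantom
from .planning import RobustPlanner
from .scenarios import evaluation_shift_grid


def planned_treatment_count(config: ExperimentConfig) -> int:
    """Total simulated treatments the configuration prescribes."""
    return (config.n_phantoms * len(config.strategies)
            * len(config.eval_sets) * config.n_samples)


def phantom_variant(base: PhantomConfig, index: int, seed: int) -> PhantomConfig:
    """Deterministic per-phantom variation of tumor size and position.

    Phantom 0 is the base configuration; further phantoms jitter the tumor
    diameter (15-35 mm) and its in-lung position, emulating a cohort with
    varying lesions.
    """
    if index == 0:
        return base
    rng = np.random.default_rng(np.random.SeedSequence([seed, index, 777]))
    diameter = float(rng.uniform(15.0, 35.0))
    # Jitter relative to the auto-placed center by letting generate_phantom
    # recompute it, then nudging within the lung via a trial loop.
    for attempt in range(8):
        offset = rng.normal(0.0, 6.0, size=3) * (0.8 ** attempt)
        probe = PhantomConfig(shape=base.shape, spacing=base.spacing,
                              tumor_diameter_mm=diameter, tumor_center_mm=None,
                              laterality=base.laterality,
                              noise_hu_sd=base.noise_hu_sd)
        auto = generate_phantom(probe, seed=0)
        center = tuple(np.asarray(auto.meta["tumor_center_mm"]) + offset)
        cand = PhantomConfig(shape=base.shape, spacing=base.spacing,
                             tumor_diameter_mm=diameter, tumor_center_mm=center,
                             laterality=base.laterality, noise_hu_sd=base.noise_hu_sd)
        try:
            generate_phantom(cand, seed=0)
            return cand
        except GeometryError:
            continue
    return PhantomConfig(shape=base.shape, spacing=base.spacing,
                         tumor_diameter_mm=diameter, tumor_center_mm=None,
                         laterality=base.laterality, noise_hu_sd=base.noise_hu_sd)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    results: dict[tuple[int, str, str], EvaluationResult]
    plans: dict[tuple[int, str], Plan]
    robust_tables: dict[tuple[int, str], "object"]
    total_treatments: int
    runtime_s: float = 0.0
    log: list[str] = field(default_factory=list)


def run_experiment(config: ExperimentConfig, progress=print) -> ExperimentResult:
    """Execute the full pipeline; deterministic for a given config/seed."""
    t_start = time.time()
    model = config.uncertainty.to_model()
    params = config.engine.to_params()
    results: dict[tuple[int, str, str], EvaluationResult] = {}
    plans: dict[tuple[int, str], Plan] = {}
    robust_tables: dict[tuple[int, str], object] = {}
    log: list[str] = []
    total = planned_treatment_count(config)
    msg = (f"simulating {config.n_samples}x{config.n_phantoms}x"
           f"{len(config.strategies)}x{len(config.eval_sets)}={total} treatments")
    log.append(msg)
    if progress:
        progress(msg)

    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    base_phantom_cfg = config.phantom.to_phantom_config()
    for pi in range(config.n_phantoms):
        ph_cfg = phantom_variant(base_phantom_cfg, pi, config.seed)
        phantom = generate_phantom(ph_cfg, seed=config.seed + pi)
        deformer = BreathHoldDeformer(phantom)
        engine = AnalyticDoseEngine(params)
        providers = {
            es: EvaluationImageProvider(
                deformer, evaluation_shift_grid(*model.bh(es), label=f"eval{es}_105"),
                f"eval{es}")
            for es in config.eval_sets}
        for si, strat in enumerate(config.strategies):
            planner = RobustPlanner(phantom, strat, model=model, engine=engine,
                                    deformer=deformer, seed=config.seed)
            plan = planner.optimize()
            table = planner.robust_evaluate(plan)
            plan = planner.normalize(plan, table)
            table_post = planner.robust_evaluate(plan)
            plans[(pi, strat)] = plan
            robust_tables[(pi, strat)] = table_post
            m = (f"phantom {pi} {strat}: {len(planner.scenarios)} scenarios, "
                 f"normalization scale {plan.normalization_scale:.3f}, "
                 f"min robust CTV D50% {table_post.ctv_d50.min():.2f} Gy")
            log.append(m)
            if progress:
                progress(m)
            for ei, es in enumerate(config.eval_sets):
                seed_seq = np.random.SeedSequence([config.seed, pi, si, ei])
                res = evaluate_plan(plan, phantom, deformer, engine, model, es,
                                    n_samples=config.n_samples, seed=seed_seq,
                                    provider=providers[es])
                results[(pi, strat, es)] = res
                p90 = res.summary.loc["CTV D50%", "p90%"]
                m = (f"phantom {pi} {strat} eval {es}: n={res.n_samples}, "
                     f"p90% CTV D50% {p90:.2f} Gy")
                log.append(m)
                if progress:
                    progress(m)
                if out:
                    tag = f"p{pi}_{strat}_{es}"
                    res.samples.to_csv(out / f"samples_{tag}.csv", index=False)
                    res.summary.to_csv(out / f"summary_{tag}.csv")
            if out:
                save_plan_json(plan, out / f"plan_p{pi}_{strat}.json")
                robust_tables[(pi, strat)].to_csv(out / f"robust_p{pi}_{strat}.csv",
                                                  index=False)

    result = ExperimentResult(config=config, results=results, plans=plans,
                              robust_tables=robust_tables,
                              total_treatments=total,
                              runtime_s=time.time() - t_start, log=log)
    if out:
        summary_all = {
            f"p{pi}|{st}|{es}": res.summary.to_dict()
            for (pi, st, es), res in results.items()}
        (out / "summaries.json").write_text(json.dumps(summary_all, indent=2))
        (out / "run.json").write_text(json.dumps({
            "config_hash": config_hash(config.model_dump(mode="json")),
            "seed": config.seed,
            "total_treatments": total,
            "runtime_s": result.runtime_s,
            "log": log}, indent=2))
    return result
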