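"""Serialization helpers: NIfTI dose export, plan JSON audit records, and an
HDF5 scenario-dose cache dump."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .dose import DoseGrid, Plan
from .grid import VoxelGrid


def config_hash(payload) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    s = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(s.encode()).hexdigest()[:12]


def save_dose_nifti(dose: DoseGrid | np.ndarray, path: str | Path,
                    grid: VoxelGrid | None = None) -> Path:
    import nibabel as nib

    if isinstance(dose, DoseGrid):
        values, grid = dose.values, dose.grid
    else:
        if grid is None:
            raise ValueError("grid required when passing a bare array")
        values = dose
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(values.astype(np.float32), grid.affine()), path)
    return path


def plan_to_dict(plan: Plan) -> dict:
    """Audit record of a plan: geometry summary, weights, scale, strategy."""
    beams = []
    for b in plan.beams:
        rec = {"modality": b.modality, "angle_deg": b.angle_deg}
        if b.modality == "photon":
            rec["segment_margins_mm"] = list(b.segment_margins)
        else:
            rec["layers"] = [{"nominal_range_mm": l.nominal_range,
                              "layer_weight": l.layer_weight,
                              "n_spots": int(len(l.spots))} for l in b.layers]
        beams.append(rec)
    return {
        "strategy": plan.strategy_name,
        "modality": plan.modality,
        "n_fractions": plan.n_fractions,
        "rbe": plan.rbe,
        "prescription_gy": plan.prescription_gy,
        "normalization_scale": plan.normalization_scale,
        "weights": [float(w) for w in plan.weights],
        "units": [{"beam_index": u.beam_index, "label": u.label,
                   "var_indices": list(u.var_indices)} for u in plan.units],
        "beams": beams,
    }


def save_plan_json(plan: Plan, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(plan_to_dict(plan), indent=2))
    return path


def save_scenario_cache_h5(cache, path: str | Path) -> Path:
    """Dump the currently cached reference-geometry unit doses to HDF5,
    keyed ``unit/image/setup/spr`` with grid metadata."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid = cache.provider.deformer.phantom.grid
    with h5py.File(path, "w") as f:
        f.attrs["shape"] = grid.shape
        f.attrs["spacing"] = grid.spacing
        f.attrs["origin"] = grid.origin
        f.attrs["spr_set"] = list(cache.spr_set)
        f.attrs["n_scenario_combinations"] = cache.n_scenario_combinations
        for (u, i, s, d), dose in cache._cache.items():
            f.create_dataset(f"unit{u}/img{i}/setup{s}/spr{d}", data=dose,
                             compression="gzip", compression_opts=1)
    return path
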