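"""Dose-volume-histogram metrics and summary statistics.

Conventions (documented, used consistently everywhere):

* ``Dx%`` is the dose exceeded by the hottest x% of a structure's voxels,
  computed as the interpolated descending-order statistic at rank
  ``x * n / 100 - 0.5`` (so ``D0%`` is the voxel-wise maximum and, e.g.,
  100 voxels of 1..100 Gy give D50% = 50.5 Gy, D2% = 98.5 Gy).
* ``VxGy`` is the absolute volume (cm^3) receiving at least x Gy.
* ``HI = (D2% - D98%) / D50%`` (0 for a perfectly uniform target dose).
* Percentile summaries (median, IQR, p90%) use the linear-interpolation
  percentile convention; min/max are raw sample extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DVHMetricSpec:
    """One requested metric: structure name, metric kind and its parameter."""

    structure: str
    metric: str  # 'D' (Dx%), 'Dmean', 'V' (VxGy), 'HI'
    param: float = 0.0

    def __post_init__(self) -> None:
        if self.metric == "D" and not (0.0 <= self.param <= 100.0):
            raise ValueError("Dx% requires x in [0, 100]")
        if self.metric == "V" and self.param <= 0:
            raise ValueError("VxGy requires a positive dose threshold")

    @property
    def name(self) -> str:
        if self.metric == "D":
            return f"{self.structure} D{self.param:g}%"
        if self.metric == "V":
            return f"{self.structure} V{self.param:g}Gy"
        if self.metric == "Dmean":
            return f"{self.structure} Dmean"
        return f"{self.structure} HI"


def dose_at_volume(dose_values: np.ndarray, x_percent: float) -> float:
    """Dx%: interpolated descending order statistic (D0% = voxel max)."""
    d = np.asarray(dose_values, dtype=float)
    if d.size == 0:
        raise ValueError("empty structure: Dx% undefined")
    d = np.sort(d)[::-1]
    r = x_percent * d.size / 100.0 - 0.5
    if r <= 0:
        return float(d[0])
    if r >= d.size - 1:
        return float(d[-1])
    lo = int(np.floor(r))
    frac = r - lo
    return float(d[lo] * (1.0 - frac) + d[lo + 1] * frac)


def volume_at_dose(dose_values: np.ndarray, threshold_gy: float,
                   voxel_volume_mm3: float) -> float:
    """VxGy in cm^3: voxels at or above threshold times the voxel volume."""
    d = np.asarray(dose_values, dtype=float)
    return float((d >= threshold_gy).sum()) * voxel_volume_mm3 / 1000.0


def homogeneity_index(dose_values: np.ndarray) -> float:
    """HI = (D2% - D98%) / D50%."""
    d50 = dose_at_volume(dose_values, 50.0)
    if d50 == 0:
        return float("nan")
    return (dose_at_volume(dose_values, 2.0) - dose_at_volume(dose_values, 98.0)) / d50


DEFAULT_METRICS: tuple[DVHMetricSpec, ...] = (
    DVHMetricSpec("CTV", "D", 50.0),
    DVHMetricSpec("CTV", "D", 2.0),
    DVHMetricSpec("CTV", "D", 98.0),
    DVHMetricSpec("CTV", "D", 0.0),
    DVHMetricSpec("CTV", "HI"),
    DVHMetricSpec("lung_ipsi", "V", 5.0),
    DVHMetricSpec("lung_ipsi", "V", 20.0),
    DVHMetricSpec("heart", "D", 0.0),
    DVHMetricSpec("heart", "Dmean"),
    DVHMetricSpec("esophagus", "D", 0.0),
    DVHMetricSpec("aorta", "D", 0.0),
    DVHMetricSpec("spinal_cord", "D", 0.0),
)


def dvh_metrics(dose: np.ndarray, structures: dict[str, np.ndarray],
                specs=DEFAULT_METRICS, voxel_volume_mm3: float = 27.0) -> dict[str, float]:
    """Evaluate the requested metrics; empty masks yield NaN (flagged, excluded
    from summaries)."""
    out: dict[str, float] = {}
    for spec in specs:
        mask = structures.get(spec.structure)
        if mask is None or not mask.any():
            out[spec.name] = float("nan")
            continue
        vals = dose[mask]
        if spec.metric == "D":
            out[spec.name] = dose_at_volume(vals, spec.param)
        elif spec.metric == "Dmean":
            out[spec.name] = float(vals.mean())
        elif spec.metric == "V":
            out[spec.name] = volume_at_dose(vals, spec.param, voxel_volume_mm3)
        elif spec.metric == "HI":
            out[spec.name] = homogeneity_index(vals)
        else:
            raise ValueError(f"unknown metric {spec.metric!r}")
    return out


def is_target_dose_metric(metric_name: str) -> bool:
    """CTV dose levels get the 10th-percentile p90% (coverage with 90%
    certainty); CTV HI and every organ-of-interest metric get the 90th
    (avoidance with 90% certainty)."""
    return metric_name.startswith("CTV D")


def summarize(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-metric summary: Avg, SD, Med, IQR, Min, Max, p90%."""
    if len(samples) < 2:
        raise ValueError("summaries require at least 2 samples")
    rows = {}
    for col in samples.columns:
        v = samples[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        q = 10.0 if is_target_dose_metric(col) else 90.0
        rows[col] = {
            "Avg": v.mean(), "SD": v.std(ddof=1),
            "Med": float(np.percentile(v, 50.0)),
            "IQR": float(np.percentile(v, 75.0) - np.percentile(v, 25.0)),
            "Min": v.min(), "Max": v.max(),
            "p90%": float(np.percentile(v, q)),
        }
    return pd.DataFrame(rows).T[["Avg", "SD", "Med", "IQR", "Min", "Max", "p90%"]]
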