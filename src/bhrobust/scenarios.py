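"""Error model and discrete shift-scenario construction.

Houses the systematic/random standard deviations of the study's uncertainty
model (patient setup, breath-hold reproducibility sets A and B, proton
stopping-power-ratio) and builds every discrete shift set used downstream:

* 90% confidence-interval radii of combined 3D Gaussian errors,
* the 7-image axis-sampled planning set,
* the 15-position setup-shift set (center + 6 faces + 8 vertices),
* the 105-shift probability-weighted evaluation grids A and B
  (15 systematic x 7 per-breath-hold positions).

Conventions: shifts are 3-vectors in mm on the (LR, AP, CC) axes; "systematic"
(Sigma) errors persist for a whole treatment course, "random" (sigma) errors
are redrawn per fraction or per breath-hold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

#: sqrt of the 0.90 quantile of chi-squared with 3 dof: the radius (in units
#: of the per-axis SD) enclosing 90% of an isotropic 3D Gaussian.
CHI3_Q90 = float(np.sqrt(stats.chi2.ppf(0.90, df=3)))

#: Default SPR perturbation set for protons (percent).
DEFAULT_SPR_SET = (-4.7, 0.0, 4.7)


@dataclass(frozen=True)
class UncertaintyModel:
    """Per-axis (LR, AP, CC) standard deviations of the error model, mm.

    ``Sigma_*`` are systematic SDs, ``sigma_*`` random (per-fraction or
    per-breath-hold) SDs.  ``Sigma_SPR`` is the systematic stopping-power-ratio
    SD in percent.  Defaults are the study's planning/evaluation values:
    breath-hold set A is used for planning and a first evaluation, the larger
    set B for a second evaluation only.
    """

    Sigma_PS: tuple[float, float, float] = (1.1, 1.5, 1.4)
    sigma_PS: tuple[float, float, float] = (1.4, 1.7, 1.7)
    Sigma_BH_A: tuple[float, float, float] = (1.3, 1.2, 1.1)
    sigma_BH_A: tuple[float, float, float] = (0.9, 1.0, 1.0)
    Sigma_BH_B: tuple[float, float, float] = (1.0, 1.2, 2.2)
    sigma_BH_B: tuple[float, float, float] = (1.1, 1.6, 2.7)
    Sigma_SPR: float = 3.8

    def __post_init__(self) -> None:
        for name in ("Sigma_PS", "sigma_PS", "Sigma_BH_A", "sigma_BH_A",
                     "Sigma_BH_B", "sigma_BH_B"):
            v = getattr(self, name)
            if len(v) != 3 or any(x < 0 for x in v):
                raise ValueError(f"{name} must be 3 nonnegative SDs, got {v}")
        if self.Sigma_SPR < 0:
            raise ValueError("Sigma_SPR must be >= 0")

    def bh(self, eval_set: str) -> tuple[tuple[float, ...], tuple[float, ...]]:
        """(Sigma, sigma) breath-hold SD pair for evaluation set 'A' or 'B'."""
        if eval_set == "A":
            return self.Sigma_BH_A, self.sigma_BH_A
        if eval_set == "B":
            return self.Sigma_BH_B, self.sigma_BH_B
        raise ValueError(f"unknown evaluation set {eval_set!r}")


@dataclass(frozen=True)
class ShiftSample:
    """One discrete scenario shift: systematic + per-BH parts (mm) and weight."""

    systematic_shift: tuple[float, float, float]
    per_bh_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    weight: float = 1.0

    @property
    def combined_shift(self) -> tuple[float, float, float]:
        return tuple(s + b for s, b in zip(self.systematic_shift, self.per_bh_shift))


@dataclass
class ScenarioSet:
    """A labeled collection of discrete shifts with normalized weights."""

    label: str
    samples: list[ShiftSample] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def combined_shifts(self) -> np.ndarray:
        return np.array([s.combined_shift for s in self.samples])

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.samples])

    def to_json(self, path: str | Path) -> None:
        payload = {"label": self.label,
                   "samples": [{"systematic_shift": list(s.systematic_shift),
                                "per_bh_shift": list(s.per_bh_shift),
                                "weight": s.weight} for s in self.samples]}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioSet":
        d = json.loads(Path(path).read_text())
        return cls(label=d["label"],
                   samples=[ShiftSample(tuple(s["systematic_shift"]),
                                        tuple(s["per_bh_shift"]), s["weight"])
                            for s in d["samples"]])


def ci90_radius(systematic_sd_max: float, random_sd_max: float) -> float:
    """Radius enclosing 90% of an isotropic 3D Gaussian error.

    The per-axis SD is the quadrature combination sqrt(Sigma^2 + sigma^2) of
    the maximum systematic and random SDs; the 90% radius follows from the
    chi-squared(3) 0.90 quantile.
    """
    if systematic_sd_max < 0 or random_sd_max < 0:
        raise ValueError("standard deviations must be >= 0")
    return float(np.hypot(systematic_sd_max, random_sd_max) * CHI3_Q90)


def ci90_radius_combined(ps: tuple[float, float], bh: tuple[float, float]) -> float:
    """90% radius for patient-setup and breath-hold errors combined in quadrature."""
    if any(v < 0 for v in (*ps, *bh)):
        raise ValueError("standard deviations must be >= 0")
    sd = float(np.sqrt(ps[0] ** 2 + ps[1] ** 2 + bh[0] ** 2 + bh[1] ** 2))
    return sd * CHI3_Q90


def _axis_pattern(radius: float) -> np.ndarray:
    """Zero + the 6 on-axis unit shifts scaled to ``radius`` (7 points)."""
    pts = [np.zeros(3)]
    for ax in range(3):
        for sgn in (+1.0, -1.0):
            e = np.zeros(3)
            e[ax] = sgn * radius
            pts.append(e)
    return np.array(pts)


def _face_vertex_pattern(radius: float) -> np.ndarray:
    """Zero + 6 face + 8 vertex directions of a sphere, all at ``radius`` (15)."""
    pts = list(_axis_pattern(radius))
    for sx in (+1.0, -1.0):
        for sy in (+1.0, -1.0):
            for sz in (+1.0, -1.0):
                pts.append(radius * np.array([sx, sy, sz]) / np.sqrt(3.0))
    return np.array(pts)


def planning_axis_samples(radius: float) -> ScenarioSet:
    """The 7-member planning shift set: zero plus +-radius along each axis."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        warnings.warn("planning radius 0: the 7 axis samples collapse to the zero shift")
        return ScenarioSet("planning_7", [ShiftSample((0.0, 0.0, 0.0), weight=1.0)])
    pts = _axis_pattern(radius)
    return ScenarioSet("planning_7",
                       [ShiftSample(tuple(p), weight=1.0 / len(pts)) for p in pts])


def setup_shift_samples(radius: float) -> ScenarioSet:
    """The 15-member setup set: center, 6 sphere faces and 8 vertices at ``radius``."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    pts = _face_vertex_pattern(radius)
    return ScenarioSet("setup_15",
                       [ShiftSample(tuple(p), weight=1.0 / len(pts)) for p in pts])


def _gauss_density(v: np.ndarray, sds: np.ndarray) -> float:
    """Unnormalized anisotropic Gaussian density at shift v; degenerate axes
    (SD 0) contribute only when the component is 0."""
    out = 1.0
    for x, s in zip(v, sds):
        if s == 0:
            out *= 1.0 if x == 0 else 0.0
        else:
            out *= float(np.exp(-0.5 * (x / s) ** 2))
    return out


def evaluation_shift_grid(Sigma_BH, sigma_BH, label: str = "evalA_105") -> ScenarioSet:
    """The 105-member probability-weighted evaluation grid.

    15 discrete systematic positions (face/vertex pattern at the 90% radius of
    the systematic SDs alone) crossed with 7 per-breath-hold axis positions
    (at the 90% radius of the per-BH SDs alone).  Each combination is weighted
    by the product of the anisotropic per-axis Gaussian densities of its
    systematic and per-BH components, normalized to sum 1.
    """
    Sigma_BH = np.asarray(Sigma_BH, float)
    sigma_BH = np.asarray(sigma_BH, float)
    if (Sigma_BH < 0).any() or (sigma_BH < 0).any():
        raise ValueError("standard deviations must be >= 0")
    r_sys = ci90_radius(float(Sigma_BH.max()), 0.0)
    r_bh = ci90_radius(float(sigma_BH.max()), 0.0)
    sys_pts = _face_vertex_pattern(r_sys)
    bh_pts = _axis_pattern(r_bh)
    samples = []
    for s in sys_pts:
        ws = _gauss_density(s, Sigma_BH)
        for b in bh_pts:
            samples.append(ShiftSample(tuple(s), tuple(b),
                                       weight=ws * _gauss_density(b, sigma_BH)))
    total = sum(s.weight for s in samples)
    if total <= 0:
        raise ValueError("degenerate evaluation grid: all weights zero")
    samples = [ShiftSample(s.systematic_shift, s.per_bh_shift, s.weight / total)
               for s in samples]
    return ScenarioSet(label, samples)


def spr_scenarios(modality: str = "proton",
                  custom: tuple[float, ...] | None = None) -> tuple[float, ...]:
    """SPR perturbation set in percent: (-4.7, 0, +4.7) for protons, (0,) for photons."""
    if custom is not None:
        return tuple(float(v) for v in custom)
    if modality == "photon":
        return (0.0,)
    if modality == "proton":
        return DEFAULT_SPR_SET
    raise ValueError(f"unknown modality {modality!r}")
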