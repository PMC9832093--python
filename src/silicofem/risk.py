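"""Per-subject fracture probability and the ARF0 estimator.

The side-fall load a subject experiences is modelled by a patient-specific
lognormal peak-force distribution whose median comes from a single-mass
impact energy balance,

    F0 = sqrt(2 · K_eff · m_eff · g · h_hip),

with effective mass ``m_eff = mass_fraction · weight`` and drop height
``h_hip = hip_height_fraction · height``.  This is a deliberately simple
surrogate for a full multiscale fall-dynamics model; every constant is
configurable and the distribution sits behind a small interface
(`exceedance`) so an alternative model can be plugged in.

For each fall orientation the fracture probability is the probability that
the fall load exceeds the failure load at that orientation; the per-fall
probability P is the mean over the orientation grid (the discrete version
of the double integral over the two fall angles on a uniform grid).  The
absolute risk of fracture in the following year, with λ falls per year, is

    ARF0 = 1 − (1 − P)^λ,        λ = 0.65 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .strength import FailureLoadGrid

__all__ = [
    "FallConstants",
    "FallLoadModel",
    "RiskResult",
    "fall_load_distribution",
    "fracture_probability",
    "arf0",
    "evaluate_subject",
]


@dataclass(frozen=True)
class FallConstants:
    mass_fraction: float = 1.0 / 3.0  # effective mass / body mass
    hip_height_fraction: float = 0.51  # hip height / body height
    k_eff: float = 71000.0  # N/m, effective pelvis-trochanter stiffness
    g: float = 9.81  # m/s²
    sigma: float = 0.25  # lognormal log-scale of the peak force


@dataclass
class FallLoadModel:
    """Lognormal peak side-fall force distribution for one subject."""

    f0: float  # N, median peak force
    sigma: float

    @property
    def dist(self):
        return sps.lognorm(s=self.sigma, scale=self.f0)

    def exceedance(self, load) -> np.ndarray:
        """P(fall force > load) — the survival function."""
        return self.dist.sf(load)


def fall_load_distribution(
    height_cm: float, weight_kg: float, constants: FallConstants | None = None
) -> FallLoadModel:
    """Patient-specific fall-load distribution from height and weight."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    c = constants or FallConstants()
    m_eff = weight_kg * c.mass_fraction
    h_hip = (height_cm / 100.0) * c.hip_height_fraction
    f0 = float(np.sqrt(2.0 * c.k_eff * m_eff * c.g * h_hip))
    return FallLoadModel(f0=f0, sigma=c.sigma)


def fracture_probability(grid: FailureLoadGrid, fall_model) -> float:
    """Per-fall fracture probability P: mean exceedance over the grid.

    ``fall_model`` only needs an ``exceedance(load)`` method, so any
    distribution can stand in for the lognormal surrogate.
    """
    loads = np.asarray(grid.loads, dtype=float)
    if np.any(~np.isfinite(loads) & ~np.isposinf(loads)):
        raise ValueError("failure-load grid has missing entries")
    p_angle = np.where(np.isposinf(loads), 0.0, fall_model.exceedance(loads))
    return float(np.mean(p_angle))


def arf0(P: float, fall_rate: float = 0.65) -> float:
    """Absolute risk of fracture at time 0: ``1 − (1 − P)^fall_rate``."""
    if not (0.0 <= P <= 1.0):
        raise ValueError("P must lie in [0, 1]")
    return float(1.0 - (1.0 - P) ** fall_rate)


@dataclass
class RiskResult:
    P: float
    arf0: float
    msf: float
    predicted_label: str = "unknown"


def evaluate_subject(
    grid: FailureLoadGrid,
    height_cm: float,
    weight_kg: float,
    constants: FallConstants | None = None,
    fall_rate: float = 0.65,
) -> RiskResult:
    """Failure-load grid + anthropometrics → (P, ARF0, MSF)."""
    model = fall_load_distribution(height_cm, weight_kg, constants)
    P = fracture_probability(grid, model)
    return RiskResult(P=P, arf0=arf0(P, fall_rate), msf=grid.msf)
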