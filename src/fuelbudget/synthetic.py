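"""Synthetic oxidation curves and athlete-profile grids.

Exogenous carbohydrate oxidation starts near zero (no ingested carbohydrate
has reached the blood yet) and rises toward a plateau as gut delivery
saturates, so the canonical synthetic family is the saturating exponential

    r(t) = r_max · (1 − exp(−t/τ)) + noise,

whose closed-form integral ``r_max · (T − τ(1 − exp(−T/τ)))`` provides a
free analytic oracle for the bin-averaged integration in
:mod:`fuelbudget.kinetics`.  Gaussian noise (standard deviation ``noise_sd``,
clipped so rates stay non-negative) is generated from a single integer seed
via :func:`numpy.random.default_rng`, so fixtures are reproducible across
platforms.

Profile grids scale a base profile's rates and stores linearly with body
mass, supporting mass-sweep analyses without re-deriving the underlying
energetics model.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .kinetics import OxidationCurve
from .profiles import AthleteFuelProfile, load_profile

__all__ = [
    "RampCurveSpec",
    "make_ramp_curve",
    "ramp_integral",
    "make_profile_grid",
]


class RampCurveSpec(BaseModel):
    """Parameters of a saturating-exponential oxidation-rate ramp."""

    model_config = ConfigDict(frozen=True)

    r_max: float = Field(gt=0, description="g/min plateau rate")
    tau: float = Field(gt=0, description="min time constant of the rise")
    noise_sd: float = Field(default=0.0, ge=0, description="g/min noise s.d.")
    seed: int = 0
    duration: float = Field(default=120.0, gt=0)
    step: float = Field(default=5.0, gt=0, description="min tabulation step")


def make_ramp_curve(spec: RampCurveSpec) -> OxidationCurve:
    """Generate a tabulated ramp curve; deterministic for a fixed seed."""
    n = int(round(spec.duration / spec.step))
    times = np.linspace(0.0, n * spec.step, n + 1)
    rates = spec.r_max * (1.0 - np.exp(-times / spec.tau))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        rates = rates + rng.normal(0.0, spec.noise_sd, size=rates.shape)
    rates = np.clip(rates, 0.0, None)
    label = f"ramp(r_max={spec.r_max},tau={spec.tau},seed={spec.seed})"
    return OxidationCurve(times=tuple(times), rates=tuple(rates), label=label)


def ramp_integral(r_max: float, tau: float, duration: float) -> float:
    """Closed-form integral of the noiseless ramp over [0, duration] (g)."""
    return r_max * (duration - tau * (1.0 - np.exp(-duration / tau)))


def make_profile_grid(
    masses: Sequence[float],
    base_profile: AthleteFuelProfile | str = "male",
    base_mass: float = 58.0,
) -> list[AthleteFuelProfile]:
    """Deterministic grid of profiles scaled linearly with body mass.

    Energy expenditure, substrate oxidation rates, glycogen capacity and
    liver glucose all scale by ``mass / base_mass``; a single-point grid at
    ``base_mass`` reproduces the base profile exactly.
    """
    if len(masses) == 0:
        raise ValueError("mass grid must be non-empty")
    if any(m <= 0 for m in masses):
        raise ValueError("masses must be positive")
    if base_mass <= 0:
        raise ValueError("base_mass must be positive")
    if isinstance(base_profile, str):
        base_profile = load_profile(base_profile)
    grid = []
    for mass in masses:
        s = mass / base_mass
        label = (
            base_profile.label if s == 1 else f"{base_profile.label}@{mass:g}kg"
        )
        grid.append(
            AthleteFuelProfile(
                label=label,
                total_energy_rate=base_profile.total_energy_rate * s,
                cho_ox_rate=base_profile.cho_ox_rate * s,
                fat_ox_rate=base_profile.fat_ox_rate * s,
                glycogen_capacity=base_profile.glycogen_capacity * s,
                liver_glucose_total=base_profile.liver_glucose_total * s,
                duration=base_profile.duration,
            )
        )
    return grid
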