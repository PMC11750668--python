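"""Exogenous carbohydrate requirements and oxidation-ceiling shortfalls.

Given an athlete profile and a glycogen depletion threshold, the budget is:

* total carbohydrate demand = carbohydrate oxidation rate × duration;
* the deficit beyond usable muscle glycogen must come from blood glucose and
  ingested (exogenous) carbohydrate;
* a liver-glucose correction: under the *printed* accounting the liver's
  contribution is added to the deficit on the grounds that high ingestion
  rates suppress hepatic glucose output, so exogenous carbohydrate must
  cover the liver's share as well; under *strict* accounting the liver pool
  is simply reassigned and the exogenous requirement equals the deficit.

The *printed* mode is the default because it is what the headline published
requirements (211 g and 238 g per 2 h) use, even though adding the liver
term to a deficit already net of it double-counts under strict bookkeeping.
"""

from __future__ import annotations

from typing import Literal, NamedTuple

from pydantic import BaseModel, ConfigDict, Field

from .glycogen import usable_glycogen
from .profiles import AthleteFuelProfile

__all__ = [
    "LiverMode",
    "Deficit",
    "ExogenousRequirement",
    "total_cho_required",
    "cho_deficit",
    "corrected_exogenous",
    "rate_per_hour",
    "oxidation_shortfall",
    "exogenous_requirement",
]

LiverMode = Literal["printed", "strict"]


class Deficit(NamedTuple):
    """A non-negative carbohydrate deficit with a clamping flag."""

    grams: float
    #: True when glycogen covered the whole demand and the raw difference
    #: was negative (clamped to zero).
    surplus: bool


class ExogenousRequirement(BaseModel):
    """Full exogenous-carbohydrate accounting for one profile and threshold."""

    model_config = ConfigDict(frozen=True)

    total_cho_required: float = Field(ge=0, description="g over the bout")
    glycogen_supplied: float = Field(ge=0, description="g of usable glycogen")
    deficit: float = Field(ge=0, description="g beyond muscle glycogen")
    surplus: bool = False
    liver_contribution: float = Field(ge=0, description="g from liver glucose")
    liver_mode: LiverMode
    exogenous_total: float = Field(ge=0, description="g required over the bout")
    exogenous_rate: float = Field(ge=0, description="g/hr required")


def total_cho_required(cho_ox_rate: float, duration: float) -> float:
    """Total grams of carbohydrate oxidized: rate (g/min) × duration (min)."""
    if cho_ox_rate < 0 or duration < 0:
        raise ValueError("cho_ox_rate and duration must be non-negative")
    return cho_ox_rate * duration

def cho_deficit(total_required: float, glycogen_supplied: float) -> Deficit:
    """Demand not covered by muscle glycogen, clamped at zero.

    A negative exogenous requirement is physiologically meaningless; the
    ``surplus`` flag preserves the information that clamping occurred.
    """
    if total_required < 0 or glycogen_supplied < 0:
        raise ValueError("inputs must be non-negative")
    raw = total_required - glycogen_supplied
    return Deficit(grams=max(raw, 0.0), surplus=raw < 0)

def corrected_exogenous(
    deficit: float, liver_contribution: float, mode: LiverMode = "printed"
) -> float:
    """Exogenous carbohydrate required after the liver-glucose correction."""
    if deficit < 0 or liver_contribution < 0:
        raise ValueError("inputs must be non-negative")
    if mode == "printed":
        return deficit + liver_contribution
    if mode == "strict":
        return deficit
    raise ValueError(f"unknown liver mode {mode!r}: expected 'printed' or 'strict'")

def rate_per_hour(total: float, duration: float) -> float:
    """Convert a bout total (g) into a g/hr rate over ``duration`` minutes."""
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    return total / (duration / 60.0)

def oxidation_shortfall(
    required_rate: float, ceiling_total: float, duration: float
) -> float:
    """Signed gap between required and achievable exogenous oxidation.

    ``required_rate`` (g/hr) over ``duration`` minutes versus a ``ceiling_total``
    (g) of achievable exogenous oxidation.  Positive means the requirement
    exceeds the ceiling (a shortfall); negative means surplus capacity.
    """
    if required_rate < 0 or ceiling_total < 0 or duration < 0:
        raise ValueError("inputs must be non-negative")
    return required_rate * (duration / 60.0) - ceiling_total


def exogenous_requirement(
    profile: AthleteFuelProfile,
    threshold_fraction: float,
    liver_mode: LiverMode = "printed",
) -> ExogenousRequirement:
    """Run the whole budget pipeline for one profile and one threshold."""
    total = total_cho_required(profile.cho_ox_rate, profile.duration)
    supplied = usable_glycogen(profile.glycogen_capacity, threshold_fraction)
    deficit = cho_deficit(total, supplied)
    exo_total = corrected_exogenous(
        deficit.grams, profile.liver_glucose_total, liver_mode
    )
    return ExogenousRequirement(
        total_cho_required=total,
        glycogen_supplied=supplied,
        deficit=deficit.grams,
        surplus=deficit.surplus,
        liver_contribution=profile.liver_glucose_total,
        liver_mode=liver_mode,
        exogenous_total=exo_total,
        exogenous_rate=rate_per_hour(exo_total, profile.duration),
    )
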