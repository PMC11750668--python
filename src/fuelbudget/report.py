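"""Assembled fuel-budget reports and reference constants.

:func:`run_table1` recomputes, from a profile and a set of depletion
thresholds, every derived row of the published budget table: total
carbohydrate demand, glycogen remnant and use at each threshold, the
windfall from lowering the threshold, the residual deficit, the
liver-corrected exogenous requirement, and per-hour rates.  Nothing is
cached: report values are the module-level recomputation.

Two published quantities are *inputs*, not recomputations, and live here as
reference constants: the per-hour exogenous oxidation requirement from the
original model's own figures (90 g/hr male, 106 g/hr female) and its
mass-specific requirement table.  They come from the upstream differential
model, which is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .fat import scenario_sweep, zero_exogenous_fat_rate
from .glycogen import glycogen_budget, threshold_windfall
from .profiles import AthleteFuelProfile, EnergyConstants
from .requirement import LiverMode, exogenous_requirement, rate_per_hour

__all__ = [
    "REFERENCE_REQUIRED_RATE_G_PER_HR",
    "REFERENCE_MASS_SPECIFIC_RATES",
    "Table1Report",
    "run_table1",
    "run_scenarios",
    "write_report",
    "read_report",
]

#: Original model's required exogenous oxidation rates (g/hr), read from its
#: published figures; used as the baseline of scenario and shortfall analyses.
REFERENCE_REQUIRED_RATE_G_PER_HR: Mapping[str, float] = {"male": 90.0, "female": 106.0}

#: Original model's mass-specific requirements (g/hr by body mass in kg),
#: kept as a reference fixture only.
REFERENCE_MASS_SPECIFIC_RATES: Mapping[str, Mapping[float, float]] = {
    "male": {50.0: 70.0, 54.0: 82.0, 58.0: 105.0, 62.0: 120.0},
    "female": {42.0: 90.0, 46.0: 103.0, 50.0: 114.0, 54.0: 128.0},
}


class ThresholdRows(BaseModel):
    """Derived budget rows at one depletion threshold."""

    model_config = ConfigDict(frozen=True)

    threshold_fraction: float
    remnant_g: int
    usable_g: int
    deficit_g: float
    surplus: bool
    exogenous_total_g: float
    exogenous_rate_g_per_hr: float


class Table1Report(BaseModel):
    """Full budget report for one profile at one or more thresholds."""

    model_config = ConfigDict(frozen=True)

    label: str
    duration_min: float
    liver_mode: LiverMode
    e_cho: float
    e_fat: float
    total_energy_rate_kj_per_min: float
    cho_ox_rate_g_per_min: float
    fat_ox_rate_g_per_min: float
    glycogen_capacity_g: float
    liver_glucose_g: float
    total_cho_required_g: float
    thresholds: tuple[ThresholdRows, ...]
    windfall_g: int | None

    def to_flat_dict(self) -> dict:
        """One flat record, one field per derived row (CSV/JSON friendly)."""
        out: dict = {
            "label": self.label,
            "duration_min": self.duration_min,
            "liver_mode": self.liver_mode,
            "e_cho": self.e_cho,
            "e_fat": self.e_fat,
            "total_energy_rate_kj_per_min": self.total_energy_rate_kj_per_min,
            "cho_ox_rate_g_per_min": self.cho_ox_rate_g_per_min,
            "fat_ox_rate_g_per_min": self.fat_ox_rate_g_per_min,
            "glycogen_capacity_g": self.glycogen_capacity_g,
            "liver_glucose_g": self.liver_glucose_g,
            "total_cho_required_g": self.total_cho_required_g,
        }
        for row in self.thresholds:
            pct = f"{row.threshold_fraction * 100:g}pct"
            out[f"remnant_g_at_{pct}"] = row.remnant_g
            out[f"usable_g_at_{pct}"] = row.usable_g
            out[f"deficit_g_at_{pct}"] = row.deficit_g
            out[f"exogenous_g_at_{pct}"] = row.exogenous_total_g
            out[f"exogenous_g_per_hr_at_{pct}"] = row.exogenous_rate_g_per_hr
        if self.windfall_g is not None:
            out["windfall_g"] = self.windfall_g
        return out


def run_table1(
    profile: AthleteFuelProfile,
    thresholds: Sequence[float] = (0.32, 0.20),
    liver_mode: LiverMode = "printed",
    constants: EnergyConstants | None = None,
) -> Table1Report:
    """Recompute every derived budget row for one profile.

    ``thresholds`` are depletion fractions in [0, 1]; when exactly two are
    given the report includes the remnant windfall between the higher and
    lower threshold.
    """
    k = constants or EnergyConstants()
    rows = []
    total = None
    for fraction in thresholds:
        req = exogenous_requirement(profile, fraction, liver_mode)
        total = req.total_cho_required
        budget = glycogen_budget(profile.glycogen_capacity, fraction)
        rows.append(
            ThresholdRows(
                threshold_fraction=fraction,
                remnant_g=budget.remnant,
                usable_g=budget.usable,
                deficit_g=req.deficit,
                surplus=req.surplus,
                exogenous_total_g=req.exogenous_total,
                exogenous_rate_g_per_hr=req.exogenous_rate,
            )
        )
    windfall = None
    if len(thresholds) == 2:
        f_high, f_low = max(thresholds), min(thresholds)
        windfall = threshold_windfall(profile.glycogen_capacity, f_high, f_low)
    return Table1Report(
        label=profile.label,
        duration_min=profile.duration,
        liver_mode=liver_mode,
        e_cho=k.e_cho,
        e_fat=k.e_fat,
        total_energy_rate_kj_per_min=profile.total_energy_rate,
        cho_ox_rate_g_per_min=profile.cho_ox_rate,
        fat_ox_rate_g_per_min=profile.fat_ox_rate,
        glycogen_capacity_g=profile.glycogen_capacity,
        liver_glucose_g=profile.liver_glucose_total,
        total_cho_required_g=total if total is not None else profile.cho_ox_rate * profile.duration,
        thresholds=tuple(rows),
        windfall_g=windfall,
    )


def run_scenarios(
    base_required_rate: float,
    baseline_fat: float,
    fat_grid: Sequence[float],
    constants: EnergyConstants | None = None,
) -> tuple[pd.DataFrame, float]:
    """Fat-oxidation sweep plus the closed-form zero-crossing fat rate."""
    frame = scenario_sweep(base_required_rate, baseline_fat, fat_grid, constants)
    crossing = zero_exogenous_fat_rate(base_required_rate, baseline_fat, constants)
    return frame, crossing


def write_report(
    report: Table1Report, path: Union[str, Path], fmt: str = "json"
) -> None:
    """Serialize a report as a one-object JSON file or a one-row CSV."""
    flat = report.to_flat_dict()
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(flat, indent=2) + "\n")
    elif fmt == "csv":
        pd.DataFrame([flat]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}: expected 'json' or 'csv'")


def read_report(path: Union[str, Path]) -> dict:
    """Read back a flat report record written by :func:`write_report`."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path)
        return frame.iloc[0].to_dict()
    return json.loads(path.read_text())
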