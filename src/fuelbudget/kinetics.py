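"""Exogenous carbohydrate oxidation kinetics.

Instantaneous exogenous-oxidation-rate curves (g/min versus time) are
integrated in fixed-width bins — 30 min by default, matching how published
cumulative-oxidation figures are constructed from average rates in each
30-min period — and compared with cumulative ingestion to yield the
unoxidized residual and the oxidation efficiency (fraction of ingested
carbohydrate actually oxidized during the bout).

Curves are tabulated at arbitrary time points and linearly interpolated
between them; the per-bin "average rate × bin width" is computed as the
exact integral of that piecewise-linear interpolant over the bin, so
refining the bin width leaves the total at the trapezoidal integral of the
tabulated curve.

Drink arithmetic: a drink of concentration c% weight/volume (g per 100 ml)
ingested at v ml/hr supplies ``c/100 × v`` g/hr of carbohydrate.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "OxidationCurve",
    "CumulativeOxidation",
    "DrinkSpec",
    "ingestion_rate",
    "cumulative_oxidized",
    "oxidation_summary",
    "unoxidized_residual",
    "oxidation_efficiency",
    "average_rate",
    "curve_from_bin_averages",
]

CURVE_CSV_COLUMNS = ("time_min", "rate_g_per_min")


class OxidationCurve(BaseModel):
    """Tabulated instantaneous exogenous-oxidation rates.

    ``times`` (min) must be strictly increasing and start at 0; ``rates``
    (g/min) are non-negative and aligned with ``times``.
    """

    model_config = ConfigDict(frozen=True)

    times: tuple[float, ...]
    rates: tuple[float, ...]
    label: str = ""

    @model_validator(mode="after")
    def _well_formed(self) -> "OxidationCurve":
        if len(self.times) != len(self.rates):
            raise ValueError("times and rates must have equal length")
        if len(self.times) < 2:
            raise ValueError("a curve needs at least two points")
        if self.times[0] != 0:
            raise ValueError(f"times must start at 0, got {self.times[0]}")
        t = np.asarray(self.times)
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be non-negative")
        return self

    @property
    def duration(self) -> float:
        return self.times[-1]

    def rate_at(self, t: Union[float, np.ndarray]) -> np.ndarray:
        """Linearly interpolated rate(s) at time(s) ``t`` (min)."""
        return np.interp(t, self.times, self.rates)

    @classmethod
    def from_csv(cls, path: Union[str, Path], label: str | None = None) -> "OxidationCurve":
        """Read a two-column curve CSV (header ``time_min,rate_g_per_min``)."""
        path = Path(path)
        frame = pd.read_csv(path)
        missing = [c for c in CURVE_CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(
                f"curve CSV {path} lacks required column(s) {missing}; "
                f"expected header {','.join(CURVE_CSV_COLUMNS)}"
            )
        return cls(
            times=tuple(frame["time_min"].astype(float)),
            rates=tuple(frame["rate_g_per_min"].astype(float)),
            label=label if label is not None else path.stem,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"time_min": self.times, "rate_g_per_min": self.rates}
        ).to_csv(path, index=False)


class CumulativeOxidation(BaseModel):
    """Binned cumulative oxidation, optionally paired with ingestion."""

    model_config = ConfigDict(frozen=True)

    bin_edges: tuple[float, ...]
    oxidized_per_bin: tuple[float, ...]
    cumulative_oxidized: tuple[float, ...]
    cumulative_ingested: tuple[float, ...] | None = None
    unoxidized: tuple[float, ...] | None = None
    efficiency: float | None = None

    @model_validator(mode="after")
    def _consistent(self) -> "CumulativeOxidation":
        if np.any(np.diff(self.cumulative_oxidized) < 0):
            raise ValueError("cumulative oxidized series must be non-decreasing")
        if self.efficiency is not None and not 0 <= self.efficiency <= 1:
            raise ValueError(f"efficiency must lie in [0, 1], got {self.efficiency}")
        return self

    @property
    def total_oxidized(self) -> float:
        return self.cumulative_oxidized[-1]


class DrinkSpec(BaseModel):
    """A carbohydrate drink: concentration in % w/v and fluid rate in ml/hr."""

    model_config = ConfigDict(frozen=True)

    concentration: float = Field(ge=0, le=100, description="g per 100 ml")
    fluid_rate: float = Field(ge=0, description="ml/hr")


def ingestion_rate(drink: DrinkSpec) -> float:
    """Carbohydrate ingestion rate in g/hr: concentration/100 × fluid rate."""
    return drink.concentration / 100.0 * drink.fluid_rate


def _bin_integral(curve: OxidationCurve, a: float, b: float) -> float:
    """Exact integral of the piecewise-linear interpolant over [a, b]."""
    t = np.asarray(curve.times)
    inner = t[(t > a) & (t < b)]
    grid = np.concatenate(([a], inner, [b]))
    return float(np.trapezoid(curve.rate_at(grid), grid))


def cumulative_oxidized(
    curve: OxidationCurve, duration: float = 120.0, bin_width: float = 30.0
) -> CumulativeOxidation:
    """Bin-averaged cumulative oxidation of a rate curve.

    Per bin the mean interpolated rate × bin width (the exact integral of the
    interpolant); cumulative sums are reported at every bin edge starting
    from 0.  ``bin_width`` must divide ``duration`` and the curve must cover
    the whole bout.
    """
    if duration <= 0 or bin_width <= 0:
        raise ValueError("duration and bin_width must be positive")
    n_bins = duration / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin_width {bin_width} must divide duration {duration} evenly"
        )
    if curve.duration < duration - 1e-9:
        raise ValueError(
            f"curve '{curve.label}' covers only {curve.duration} min but "
            f"{duration} min were requested"
        )
    edges = np.linspace(0.0, duration, int(round(n_bins)) + 1)
    per_bin = [_bin_integral(curve, a, b) for a, b in zip(edges[:-1], edges[1:])]
    return CumulativeOxidation(
        bin_edges=tuple(edges),
        oxidized_per_bin=tuple(per_bin),
        cumulative_oxidized=tuple(np.concatenate(([0.0], np.cumsum(per_bin)))),
    )


def oxidation_summary(
    curve: OxidationCurve,
    ingestion_g_per_hr: float,
    duration: float = 120.0,
    bin_width: float = 30.0,
) -> CumulativeOxidation:
    """Full oxidized-versus-ingested accounting for a constant ingestion rate."""
    if ingestion_g_per_hr < 0:
        raise ValueError("ingestion rate must be non-negative")
    partial = cumulative_oxidized(curve, duration, bin_width)
    edges = np.asarray(partial.bin_edges)
    ingested = ingestion_g_per_hr * edges / 60.0
    oxidized = np.asarray(partial.cumulative_oxidized)
    residual = unoxidized_residual(float(ingested[-1]), float(oxidized[-1]))
    return CumulativeOxidation(
        bin_edges=partial.bin_edges,
        oxidized_per_bin=partial.oxidized_per_bin,
        cumulative_oxidized=partial.cumulative_oxidized,
        cumulative_ingested=tuple(ingested),
        unoxidized=tuple(ingested - oxidized),
        efficiency=oxidation_efficiency(float(oxidized[-1]), float(ingested[-1])),
    )

def unoxidized_residual(ingested_total: float, oxidized_total: float) -> float:
    """Grams ingested but not oxidized over the full bout."""
    if ingested_total < 0 or oxidized_total < 0:
        raise ValueError("inputs must be non-negative")
    residual = ingested_total - oxidized_total
    if residual < 0:
        raise ValueError(
            f"oxidized total ({oxidized_total} g) exceeds ingested total "
            f"({ingested_total} g) over the bout"
        )
    return residual

def oxidation_efficiency(oxidized_total: float, ingested_total: float) -> float:
    """Fraction of ingested carbohydrate oxidized (0–1)."""
    if ingested_total <= 0:
        raise ValueError("efficiency is undefined for zero ingestion")
    if not 0 <= oxidized_total <= ingested_total:
        raise ValueError(
            f"oxidized total {oxidized_total} g must lie in [0, {ingested_total}]"
        )
    return oxidized_total / ingested_total

def average_rate(total: float, duration: float) -> float:
    """Average rate in g/hr of a bout total (g) over ``duration`` minutes."""
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    return total / (duration / 60.0)


def curve_from_bin_averages(
    bin_means: Sequence[float],
    bin_width: float = 30.0,
    label: str = "bin-averages",
    eps: float = 1e-9,
) -> OxidationCurve:
    """Step-shaped curve whose bin means equal ``bin_means``.

    Each bin is held constant at its mean; the steps are joined by ``eps``-
    wide linear transitions so the tabulation stays strictly increasing.
    Useful for replaying published per-30-min average rates as a curve.
    """
    if not bin_means:
        raise ValueError("bin_means must be non-empty")
    times: list[float] = [0.0]
    rates: list[float] = [float(bin_means[0])]
    for i, mean in enumerate(bin_means):
        end = (i + 1) * bin_width
        times.append(end if i == len(bin_means) - 1 else end - eps)
        rates.append(float(mean))
        if i < len(bin_means) - 1:
            times.append(end)
            rates.append(float(bin_means[i + 1]))
    return OxidationCurve(times=tuple(times), rates=tuple(rates), label=label)
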