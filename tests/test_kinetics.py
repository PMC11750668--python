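"""Oxidation-curve integration, drink arithmetic, residuals and efficiency."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from fuelbudget import (
    DrinkSpec,
    OxidationCurve,
    average_rate,
    cumulative_oxidized,
    curve_from_bin_averages,
    ingestion_rate,
    oxidation_efficiency,
    oxidation_summary,
    unoxidized_residual,
)
from fuelbudget.synthetic import ramp_integral


@pytest.mark.parametrize(
    "concentration, fluid_rate, expected",
    [(22.5, 400, 90), (15, 800, 120), (0, 750, 0), (11, 1000, 110)],
)
def test_ingestion_rate_from_drink_spec(concentration, fluid_rate, expected):
    drink = DrinkSpec(concentration=concentration, fluid_rate=fluid_rate)
    assert ingestion_rate(drink) == pytest.approx(expected)


def test_constant_curve_integrates_to_rectangle():
    curve = OxidationCurve(times=(0.0, 120.0), rates=(1.0, 1.0))
    result = cumulative_oxidized(curve, 120, 30)
    assert result.total_oxidized == pytest.approx(120.0)
    assert result.oxidized_per_bin == pytest.approx((30.0,) * 4)


def test_bin_average_fixture_reproduces_total():
    """Per-30-min averages (0.30, 0.95, 1.30, 2.02 g/min) sum to 137.1 g."""
    curve = curve_from_bin_averages([0.30, 0.95, 1.30, 2.02], 30.0)
    result = cumulative_oxidized(curve, 120, 30)
    assert result.total_oxidized == pytest.approx(137.1, abs=1e-5)
    assert result.cumulative_oxidized[-1] == result.total_oxidized


@pytest.mark.parametrize("bin_width", [5, 10])
def test_ramp_integration_matches_analytic(bin_width):
    """Bin-averaged total within 1% of the closed-form ramp integral."""
    r_max, tau, duration = 1.5, 30.0, 120.0
    times = np.arange(0, duration + 1, 1.0)
    rates = r_max * (1 - np.exp(-times / tau))
    curve = OxidationCurve(times=tuple(times), rates=tuple(rates))
    total = cumulative_oxidized(curve, duration, bin_width).total_oxidized
    assert total == pytest.approx(ramp_integral(r_max, tau, duration), rel=0.01)


def test_refining_bins_converges_to_trapezoid():
    times = tuple(np.arange(0, 121, 5.0))
    rates = tuple(1.5 * (1 - np.exp(-np.asarray(times) / 30)))
    curve = OxidationCurve(times=times, rates=rates)
    trapezoid = float(np.trapezoid(rates, times))
    totals = [
        cumulative_oxidized(curve, 120, w).total_oxidized for w in (60, 30, 10, 5)
    ]
    errors = [abs(t - trapezoid) for t in totals]
    assert all(e <= errors[0] + 1e-9 for e in errors)
    assert errors[-1] < 1e-9


def test_curve_must_cover_duration():
    curve = OxidationCurve(times=(0.0, 60.0), rates=(0.5, 1.0))
    with pytest.raises(ValueError, match="covers only"):
        cumulative_oxidized(curve, 120, 30)


def test_bin_width_must_divide_duration():
    curve = OxidationCurve(times=(0.0, 120.0), rates=(1.0, 1.0))
    with pytest.raises(ValueError, match="divide"):
        cumulative_oxidized(curve, 120, 45)


@pytest.mark.parametrize(
    "times, rates",
    [
        ((5.0, 120.0), (0.5, 1.0)),        # must start at 0
        ((0.0, 50.0, 50.0), (0, 1, 1)),    # strictly increasing
        ((0.0, 120.0), (-0.1, 1.0)),       # non-negative rates
        ((0.0,), (1.0,)),                  # at least two points
    ],
)
def test_curve_validation(times, rates):
    with pytest.raises((ValidationError, ValueError)):
        OxidationCurve(times=times, rates=rates)


def test_curve_csv_roundtrip(tmp_path):
    curve = OxidationCurve(times=(0.0, 30.0, 120.0), rates=(0.0, 1.0, 1.4),
                           label="demo")
    path = tmp_path / "demo.csv"
    curve.to_csv(path)
    back = OxidationCurve.from_csv(path)
    assert back.times == curve.times
    assert back.rates == curve.rates
    assert back.label == "demo"


def test_curve_csv_requires_dialect_header(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("minutes,grams\n0,0\n30,1\n")
    with pytest.raises(ValueError, match="time_min"):
        OxidationCurve.from_csv(path)


@pytest.mark.parametrize(
    "ingested, oxidized, expected",
    [(288, 137, 151), (240, 90, 150), (137, 137, 0)],
)
def test_unoxidized_residual(ingested, oxidized, expected):
    assert unoxidized_residual(ingested, oxidized) == expected


def test_residual_rejects_oxidized_above_ingested():
    with pytest.raises(ValueError, match="exceeds"):
        unoxidized_residual(100, 120)


@pytest.mark.parametrize(
    "oxidized, ingested, fraction, percent",
    [(137, 288, 137 / 288, 48), (132, 180, 132 / 180, 73), (0, 200, 0.0, 0)],
)
def test_oxidation_efficiency(oxidized, ingested, fraction, percent):
    eff = oxidation_efficiency(oxidized, ingested)
    assert eff == pytest.approx(fraction)
    assert round(eff * 100) == percent


def test_efficiency_zero_ingestion_rejected():
    with pytest.raises(ValueError, match="zero ingestion"):
        oxidation_efficiency(0, 0)


@pytest.mark.parametrize(
    "total, duration, expected", [(137, 120, 68.5), (132, 120, 66), (0, 120, 0)]
)
def test_average_rate(total, duration, expected):
    assert average_rate(total, duration) == pytest.approx(expected)


def test_summary_consistency_and_bounds():
    """unoxidized = ingested − oxidized at every edge; efficiency in [0,1]."""
    curve = curve_from_bin_averages([0.30, 0.95, 1.30, 2.02], 30.0)
    summary = oxidation_summary(curve, ingestion_g_per_hr=144, duration=120,
                                bin_width=30)
    ingested = np.asarray(summary.cumulative_ingested)
    oxidized = np.asarray(summary.cumulative_oxidized)
    assert np.all(np.diff(oxidized) >= 0)
    assert np.all(np.asarray(summary.unoxidized) == ingested - oxidized)
    assert np.all(np.asarray(summary.unoxidized) >= 0)
    assert summary.efficiency == pytest.approx(oxidized[-1] / ingested[-1])
    residual = summary.unoxidized[-1]
    assert residual / ingested[-1] == pytest.approx(1 - summary.efficiency)


@given(
    rate=st.floats(min_value=0.0, max_value=2.0),
    ingest=st.floats(min_value=120.0, max_value=200.0),
)
def test_oxidation_never_exceeds_ingestion_when_rate_below_supply(rate, ingest):
    """If the oxidation rate never exceeds the ingestion rate, cumulative
    oxidized stays below cumulative ingested at every bin edge."""
    rate = min(rate, ingest / 60.0)
    curve = OxidationCurve(times=(0.0, 120.0), rates=(rate, rate))
    summary = oxidation_summary(curve, ingest, 120, 30)
    assert all(
        ox <= ing + 1e-9
        for ox, ing in zip(summary.cumulative_oxidized, summary.cumulative_ingested)
    )
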