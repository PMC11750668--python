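# Methods

## The model

`fuelbudget` implements a deterministic bookkeeping model of substrate use
during two hours of running at sub-2-hour-marathon intensity. It is an
accounting identity, not a differential model: given a constant total
energy expenditure and constant substrate oxidation rates, it partitions
the carbohydrate (CHO) demand across muscle glycogen, liver glucose and
ingested (exogenous) carbohydrate, and asks whether the exogenous share is
achievable given observed gut/oxidation ceilings.

Assumptions, all inherited from the analysis the package reproduces:

* oxidation rates are constant over the bout (no drift, no pacing effects);
* performance fails once muscle glycogen falls to a fixed fraction of its
  starting value (the depletion threshold), regardless of which fibers hold
  the remaining glycogen;
* substrate energies add: `total ≈ cho_ox_rate·e_cho + fat_ox_rate·e_fat`
  (the packaged profiles close this identity to within 3–4%, checked by
  `audit_energy_closure`);
* amino-acid and ketone contributions are ignored.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| `duration` | min | 120 | a two-hour marathon; a profile field so scenarios generalize |
| depletion threshold | fraction | 0.32 and 0.20 | 32% is the threshold of the model under scrutiny; 20% matches the classical depletion studies in which subjects stopped at 10–20% of starting glycogen |
| `e_cho` | kJ/g | 17.3 | back-computed from the male profile (88.3 kJ/min ÷ 5.1 g/min); the source analysis never states its densities |
| `e_fat` | kJ/g | 38.0 | back-computed from "1.5 g/min ↔ 57 kJ/min"; elsewhere the same source equates 0.5 g/min with 18 kJ/min (implying 36), so both densities are config-overridable |
| `liver_mode` | enum | `printed` | see below |
| `bin_width` | min | 30 | cumulative-oxidation figures in the feeding literature are built from average rates per 30-min period; a parameter because finer curves deserve finer integration |

The packaged profiles carry the published per-sex model parameters: male
(88.3 kJ/min, 5.1 g CHO/min, 0.07 g fat/min, 690 g glycogen, 68 g liver
glucose) and female (75.7, 4.4, 0.06, 499, 49).

## Numerical choices

**Rounding.** Glycogen remnants are rounded half-away-from-zero to whole
grams at the remnant step, and every downstream row consumes the rounded
remnant. This is the package's single rounding site and exactly reproduces
the published bookkeeping (220.8 → 221; 612 − 469 = 143). Per-hour rates
keep one decimal at reporting; grams are reported as integers.

**Liver accounting.** The published requirement adds the liver-glucose
contribution to a deficit that is already net of it ("deficit + liver"),
on the argument that high ingestion rates suppress hepatic output so
exogenous CHO must also cover the liver's share. Under strict bookkeeping
this double-counts: if the liver supplies nothing, the requirement should
equal the deficit. Both modes are implemented; `printed` is the default
because it is what the headline 211 g / 238 g requirements use, and the two
modes differ by exactly the liver contribution (a tested invariant).

**Clamping.** Carbohydrate deficits and counterfactual requirements clamp
at zero — negative requirements are physiologically meaningless — with a
`surplus` flag (deficits) or an exposed zero-crossing fat rate (scenarios)
preserving the lost information.

**Integration.** Oxidation curves are tabulated points joined by linear
interpolation (no interpolation rule is published; linear is the least
structured choice). The per-bin "average rate × bin width" is computed as
the exact integral of the piecewise-linear interpolant over the bin, so
bin totals are conservative and refining the bin width leaves the full-bout
total at the trapezoidal integral of the tabulation. Step-shaped curves
built from published per-bin averages use 1 ns joining ramps to keep the
time axis strictly increasing; the induced integration error is below
10⁻⁶ g.

**Counterfactual basis.** Fat scenarios operate on the per-hour exogenous
requirement (the level at which the published scenario figure is drawn)
rather than re-running the whole budget, keeping the fat knob orthogonal to
the threshold and liver-mode choices. Before clamping, the requirement is
affine in the scenario fat rate with slope `−60·e_fat/e_cho` (tested
against a grid scan).

## Synthetic data

The generator emulates the rising-then-plateau shape of measured exogenous
oxidation: `r(t) = r_max(1 − e^(−t/τ))` plus optional Gaussian noise
(clipped at zero), tabulated every `step` minutes, seeded through
`numpy.random.default_rng` so fixtures are identical across platforms. The
closed-form integral `r_max(T − τ(1 − e^(−T/τ)))` serves as an independent
oracle: bin-averaged integration of a noiseless ramp agrees with it to
within 1% at bin widths of 10 min or less. Profile grids scale a base
profile linearly with body mass.

What the generator does **not** emulate: inter-subject variability of real
oxidation data, gut-absorption saturation dynamics, or any time-dependence
of the budget's constant rates. Passing tests therefore demonstrate the
arithmetic and its invariants, not the physiological accuracy of the
underlying assumptions.

## Known limitations and irreproducible reference values

Three published quantities are carried as reference constants, never
recomputed, because they are outputs of the upstream differential model or
are internally inconsistent:

* the 90 g/hr (male) and 106 g/hr (female) required exogenous oxidation
  rates, and the mass-specific requirement table, both read from the
  upstream model's figures;
* the intermediate scenario values "25 g/hr (male) / 46 g/min (female)" at
  0.5 g/min fat: no single (e_cho, e_fat) pair reproduces them (the
  consistent defaults give ≈33.3 g/hr for males), and the female unit is
  presumably a g/hr typo;
* the "43.6 g/2hr" male shortfall, which implies an unprinted 90.3 g/hr
  requirement; against the referenced 90 g/hr the computed shortfall is
  43 g. (The 11%-at-1-L/hr ingestion example likewise implies 110 g/hr,
  not the published 112.5.)

The acceptance script reports only quantities the package computes at run
time; the constants above appear only as inputs.
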