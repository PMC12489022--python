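# Methods

## The indicator

Estimated Modern Use (EMU) is a coverage proxy built from routine service
statistics: estimated modern contraceptive users divided by women of
reproductive age (WRA, 15–49). Unlike couple-years of protection (CYP),
which credits the full multi-year impact of a long-acting method to the
year of provision, EMU *annualizes* that impact — each insertion cohort is
carried forward along a continuation curve until its users discontinue,
the method expires, or (for sterilization) the woman ages out of
reproductive age. This smooths trends in long-acting use and makes the
indicator comparable to survey-based modern contraceptive prevalence.

## User decomposition

For each method × service-statistic type × year, estimated users split
into current, continuing and historic components; the total is their exact
sum and all quantities stay real-valued until presentation.

**Short-term methods** convert through CYP factors: users = count /
units-per-CYP, with the standard factors (15 pill cycles, 120 condoms,
4 DMPA-IM doses per CYP). Short-term methods have no carryover.

**Long-acting and permanent methods** use the continuation curve Con(x) —
the proportion of adopters still using the method in their x-th year of
use, with Con(1) applying to the calendar year of insertion (100 Copper-T
insertions yield 92 current-year users, not 92 on the first anniversary).
Continuing users sum the surviving fractions of every cohort observed
since the first data year t0. The first data year is determined **per
method and statistic type**, because methods enter reporting systems at
different times; gap years inside the window contribute zero current users
but do not trigger historic estimation.

**Historic users** address provision before t0. The program's maturity at
t0 is a *declared* input per method — never inferred from the data,
because it rests on program knowledge:

- `no_historic`: provision began with the data; back-cast is zero.
- `at_scale`: pre-window provision resembled the first observed year;
  back-cast C(t0) · Σ_{x=t−t0}^{L_max} Con(x+2).
- `scaling_up`: half the at-scale value, splitting the difference between
  the two extremes.

The summation's upper bound is written as L_max even though terms beyond
the curve's support are zero; they are harmless and kept for fidelity to
the published form. Consequently the historic component vanishes exactly
once t − t0 ≥ L_max − 1: with ten years of data no method carries a
historic component.

The `users` statistic type represents true longitudinal user counts and
bypasses all conversion: counts pass through as current users.

## Parameters and their defaults

The registry is a versioned YAML document; everything in it is a program
parameter, editable per country.

- **Copper-T IUD**: duration 10 years, 4.6 CYP per insertion. The first
  three continuation values (0.92, 0.77, 0.65) are the published anchors
  of the curve underlying the CYP factor; later years extend them at the
  anchors' observed year-over-year retention ratio (≈0.84). The resulting
  expected use is 4.75 person-years per insertion, within 15% of the CYP
  credit (the factor embeds additional effectiveness scaling, so equality
  is not expected).
- **Implant**: duration 5 years, 3.8 CYP, curve set to the CYP
  continuation literature's levonorgestrel-implant profile.
- **Female sterilization**: permanent; its 10-year curve declines slowly
  from 1.0, representing aging out of reproductive age rather than
  discontinuation.
- **Covered shares**: covered_share_m = public_share_m + capture_fraction
  × (1 − public_share_m), with public shares from survey source-of-supply
  data and the capture fraction (how much private provision reports into
  the HMIS) defaulting to 0. Shares are held constant between surveys —
  source-of-supply structure changes slowly — so no temporal interpolation
  is applied. The adjustment multiplies each method by 1/covered_share
  *before* aggregation, matching the method-by-method definition.
- **Completeness threshold**: 80% facility reporting, the standard
  recommendation; years below it are excluded from the trend but still
  computed — the gate never rescales a numerator.
- **Quality-review thresholds** (all keyword-configurable): 10% relative
  difference for the clients-vs-visits similarity check on single-dose
  methods; outliers flagged when a year deviates from the method-series
  median by more than 3 median absolute deviations or changes by more than
  50% year-over-year (robust rules in the WHO data-quality style, since
  only the requirement to flag outliers is standardized, not the rule);
  growth divergence flagged beyond 1 percentage point per year between
  annualized survey mCP change and annualized adjusted-EMU change.

## Synthetic data and what it shows

The generator emulates a country's inputs from a declarative scenario:
true provision trajectories per method (flat, linear scale-up, or a
one-year impulse), a covered share, optional pre-window cohorts, a WRA
trajectory (default 1,000,000 growing 2%/year), reporting rates, and
multiplicative lognormal noise on observed counts (σ default 0.05 —
positive counts with errors that scale with volume). Observed counts are
`true volume × covered_share × noise`; synthetic survey mCP is true users
/ WRA.

Ground truth comes from a per-cohort ledger that follows every insertion
cohort through its curve by explicit enumeration. This is deliberately a
second, independent implementation of the carryover arithmetic, kept free
of the estimator's summation formulas so it can catch algebra errors.

Passing the recovery tests shows the estimator inverts its own generative
assumptions: with no noise and full coverage the pipeline reproduces the
ledger EMU to numerical precision, an at-scale back-cast lands within 10%
of truth when pre-window provision really was constant, and rank ordering
of EMU across years is preserved under linear scale-up. It does **not**
show robustness to what real HMIS data contains — reporting heterogeneity
across facilities, method misclassification, double counting between
statistic streams, or continuation behaviour that differs from the global
curves. The quality review exists precisely because those features are
outside the generative model.

Problem sizes in the test and acceptance runs are small by design —
single-country bundles of roughly 5–10 years and a handful of methods —
since every identity being checked is scale-free (the estimator is exactly
linear in counts).

## Numerical choices and degenerate inputs

- Users are floats end to end; printed integers (92/77/65) emerge exactly
  from count × rate.
- Missing population years are linearly interpolated inside the known
  range; extrapolation raises, naming the year.
- Monthly records aggregate to annual totals by summation before
  estimation. Sub-annual EMU, where wanted, is computed by annualizing
  counts (a quarter × 4) and is flagged as provisional.
- Readers reject invariant violations (negative counts, rates outside
  0–100, non-monotone curves) with errors naming the offending row or
  index; they never coerce.
- An EMU above 1.0 (more estimated users than WRA) is produced but carries
  a hard validation flag.
- Result files are written at 6 decimal places with a deterministic column
  order, so write-then-read round-trips exactly at that precision.

## Known limitations

- Continuation curves are global per method; country- or region-specific
  curves, and level-shifted curve adjustments, are config hooks only.
- The implant curve beyond its published anchors, like all non-anchored
  curve values, is a documented editorial choice in the default config,
  not an estimate.
- No modelling of method switching between years: a switcher appears as a
  discontinuation in one method and an adoption in another.
- The scaling-up back-cast's ½ factor is a convention, not an estimate;
  the 10% recovery tolerance on back-cast scenarios reflects that.
- Survey sampling error is not modelled; synthetic "surveys" are exact
  functions of the truth.
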