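# Methods

## Model

The toolkit computes the *theoretical* nitrosamine build-up in a tablet
under three assumptions: (i) nitrite impurities in the excipients are the
only nitrosating source and are the rate-limiting reagent (the secondary
amine — usually the API — is in large excess); (ii) a fixed molar fraction
of the nitrite present converts into a single nitrosamine species, using
plateau values measured under accelerated storage rather than kinetics
over time; (iii) all nitrite in an excipient is equally available to
react. Under these assumptions the calculation is a two-step linear chain:
per excipient, `nitrosamine_ppm = nitrite_ppm · MW_na · f_conv /
MW_nitrite` (a mole-to-mass conversion: ppm w/w of nitrite, times the
molar conversion fraction, times the nitrosamine/nitrite molecular-weight
ratio), then `ng = tablet_mg · fraction_ww · nitrosamine_ppm`, exact
because ppm w/w is ng per mg. The tablet total is the sum over
nitrite-bearing ingredients; the API is excluded from the nitrite budget
by default (`counts_nitrite=False`), overridable per ingredient.

Assumption (iii) is a deliberate simplification: real excipients differ in
how much of their nitrite is mobile and able to reach the amine, so the
model is a screening estimate, generally conservative for a given nitrite
level and conversion.

## Parameters

- `nitrosamine_mw` (g/mol): the nitrosamine expected to form. NDSRIs span
  roughly 200–1000 g/mol with a median near 400, the default used in the
  bundled scenarios; NDEA is 102.
- `conversion_fraction` (dimensionless, molar, in [0, 1]): registry
  defaults 0.13 (direct compression, secondary-amine salt API, NDSRI),
  0.29 (wet granulation, same), 0.022 (low-level amine impurities, wet
  granulation). These are measured plateau values from nitrite-spiked
  tablets; the highest conversion ever measured in the solid state is
  about 38 %, which bounds the default conversion-sweep range. Unknown
  (amine type, form, process, class) combinations raise a lookup error —
  there is no silent default, because a wrong conversion silently scales
  every result.
- `nitrite_mw` (g/mol): 46.005, the NO₂⁻ ion. The molar bookkeeping is
  referenced to the ion rather than a salt; with this constant the
  documented scenario arithmetic is internally consistent (the
  6.5 → 0.42 ppm superdisintegrant swap at 5 % w/w of a 200 mg tablet
  removes 153.3 ng, 36.3 % of the 422 ng reference total, matching the
  reported −36 %), which a salt MW such as 69.0 (NaNO₂) would not give.
  Exposed as a parameter for users whose nitrite data are reported as a
  salt.
- `nitrite_statistic` plus per-ingredient `statistic_overrides`: supplier
  selection is modeled as choosing the min (best case), mean (average) or
  max (worst case) of an excipient's nitrite distribution, globally or for
  selected ingredients only (e.g. MCC→min with everything else at mean).
- ADI registry (ng/day): NDSRI default 18, EMA interim NDSRI 178, NDEA
  26.5, EMA potency categories 1500/400/100/18. `total ≤ limit` counts as
  compliant — the limit is an *acceptable* intake — with exact ties
  flagged.

## Numerical and design choices

- Compositions must close to 100 % w/w within 0.1 percentage point;
  rescaling is an explicit `normalize` opt-in, never silent. Ingredient
  and excipient keys are case-insensitive and whitespace-normalized.
- All computation carries full double precision; reports round ng to one
  decimal and percent changes to the nearest integer, and percent changes
  are computed on exact totals before display rounding. A zero-baseline
  comparison reports "n/a", never ±∞.
- Sweeps evaluate every grid point with a fresh full evaluation (no
  incremental shortcuts); linearity through the origin is asserted by
  tests, not assumed by the sweep. Threshold inversion uses `limit/slope`
  with the slope taken from one evaluation; the returned critical value
  may exceed the parameter's physical domain (e.g. conversion > 1), which
  means the ADI is unreachable within it — the caller decides how to
  present that, and re-evaluation at the returned value reproduces the
  limit to ~1e-9 relative.
- Database text serialization writes shortest round-tripping decimals so
  6.5 stays "6.5"; formulation files carry the human-convention percent
  plus the exact machine fraction, and the loader prefers the latter, so
  write→load is lossless.
- JSON reports sort keys and serialize floats at fixed precision: the same
  inputs give byte-identical reports, and every report embeds the nitrite
  database provenance and the nitrite MW used.

## Bundled data and the synthetic generators

The packaged nitrite database contains only individually documented
values: crospovidone mean 6.5 ppm and croscarmellose sodium mean 0.42 ppm
(stored as degenerate min=mean=max triples because their supplier ranges
are not individually documented) and a generic "low-nitrite filler" band
0.04/0.055/0.07 ppm representing the lowest filler levels on the market.
Absolute tablet totals for the bundled multi-excipient formulations
require the full excipient survey (min/mean/max for MCC, lactose,
povidone, magnesium stearate, ...), which is not redistributed here; the
template CSV names the excipients to fill in, and `import_toolkit_xlsx`
reads a survey sheet from an Excel workbook, matching header aliases
(lowest/average/highest etc.) and failing with the scanned sheet names
when no recognizable layout exists.

The synthetic generators exist so every pipeline stage is testable with no
external file. A `FixtureSpec` seed fully determines the output.
Formulations draw an API fraction from 5–30 % w/w, split the remainder
across excipients by normalized uniform draws, and close to exactly 100 %
by largest-remainder rounding in 0.01-point units; tablet weight is
uniform on 100–1000 mg. Nitrite records are three uniform draws on
0–10 ppm, sorted, so min ≤ mean ≤ max by construction. These ranges mirror
realistic immediate-release tablets and the spread of real excipient
nitrite levels, but the generator does not emulate supplier-level nitrite
distributions, correlations between excipients, or heavy-tailed
variability — passing tests demonstrate the arithmetic, validation and
invariants (linearity, additivity, monotonicity, mole conservation), not
distributional realism.

## Problem sizes

The property suites run the full model on 1000 seeded fixtures for
additivity and 200 for scenario monotonicity; each evaluation is a
handful of multiplications, so the entire suite completes in seconds.

## Known limitations

Single nitrosamine species per run; no kinetics (plateau conversions
only); no uncertainty propagation or Monte-Carlo over nitrite
distributions; no potency categorization from structure (only the numeric
category limits are registered); nitrite scavengers and process mitigation
enter only through the conversion parameter.
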