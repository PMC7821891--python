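# Methods

## Least-cost diet linear programs

For one market-month with item prices `p_i` (local currency per kg edible
matter) and a composition matrix `a_ij` (nutrient j per kg of item i,
`a_ie` = kcal per kg), the cost of nutrient adequacy (CoNA) is

    min Σ_i p_i q_i   over  q_i ≥ 0  (kg/day)

subject to, for each constrained nutrient: `Σ_i a_ij q_i ≥ EAR_j` and
`Σ_i a_ij q_i ≤ UL_j` where defined; for each macronutrient j with energy
density `e_j` (protein 4, carbohydrate 4, lipid 9 kcal/g): gram bounds
`AMDR_lo,j · E / e_j ≤ Σ_i a_ij q_i ≤ AMDR_hi,j · E / e_j`; and the energy
equality `Σ_i a_ie q_i = E`. Energy is an equality, not `≥`: this keeps the
caloric-subsistence problem closed-form and makes the nutrient premium
(CoNA − CoCA) a like-for-like comparison at identical energy. CoCA solves
the same program restricted to starchy staples with only the energy
constraint; its optimum is `E ×` the minimum staple price-per-kcal.

Solved with `scipy.optimize.linprog` (HiGHS). Infeasibility is declared
only on the solver's certificate, with one fast pre-check that produces a
better diagnostic: any nutrient with a positive lower bound that no priced
item contains is reported by name. Cost is the tested quantity; optimal
quantities are asserted only for feasibility because the basis can be
degenerate (ties in price-per-kcal, redundant constraints). Binding
constraints are reported at 1e-7 relative slack.

### Requirement set

The shipped default (`data/dri_women_19_30.yaml`, editable) is the IOM DRI
set for healthy non-pregnant women aged 19–30: EARs as lower bounds, ULs as
upper bounds, AMDR fractions for the three macronutrients, and the energy
target from the IOM adult-female EER equation
`354 − 6.91·age + PA·(9.36·weight + 726·height)` with PA ∈ {1.00 sedentary,
1.12 low-active, 1.27 active, 1.45 very-active}; the reference woman
(24.5 y, 57 kg, 1.63 m, low-active) needs 2107.6 kcal/day. Twenty-one
nutrients carry at least one constraint: protein, carbohydrate and lipid;
calcium, iron, magnesium, phosphorus, zinc, copper, selenium, sodium; and
vitamin C, thiamin, riboflavin, niacin, B6, folate, B12, vitamin A (RAE),
retinol and vitamin E. Choices worth flagging:

- **Sodium** has no lower bound; the upper bound is the 2019 CDRR
  (2300 mg/day) rather than a classical UL.
- **Vitamin A / retinol split**: the EAR applies to total vitamin A in
  retinol activity equivalents; the UL (3000 µg) applies to preformed
  retinol on its own constraint row. Both roles live in the YAML and can
  be reassigned without code changes.
- **Magnesium** carries no UL because the IOM UL covers supplemental
  magnesium only; other ULs are included wherever the IOM defines one.

Unit tests do not depend on these transcribed constants: they run on
synthetic requirement sets with known closed-form optima.

## Price-panel cleaning and conversion

- **Winsorization**: each record's ratio to its item's median price is
  pooled across items; ratios above the (1 − upper_tail) quantile
  (default top 1%) are capped at cutpoint × item median. The cutpoint is
  pooled rather than per-item because a per-item 99th percentile is
  ill-defined for items with few records; a per-item mode exists behind a
  flag, as does optional two-sided trimming. Fitting and transforming are
  separated so a frozen cutpoint can be re-applied idempotently.
- **LCU per 100 kcal**: `price_per_kg / (kcal_per_kg / 100)`; zero or
  missing energy density is an error naming the item.
- **PPP conversion** happens strictly after optimisation (the LPs reflect
  nominal choices at each place and time). Annual PPP factors are
  disaggregated to months by additive Denton benchmarking: minimise the
  sum of squared first differences of the monthly path subject to each
  calendar year's 12 months *averaging* to the annual factor
  (average-consistency is the right benchmark type for an index-like
  series; sum-consistency would be appropriate for flows). The
  equality-constrained quadratic program is solved exactly via its KKT
  system; the test suite checks it against an independent null-space
  least-squares solution. Monthly factors must stay positive — true for
  factors that drift gradually, as PPP series do; violent year-over-year
  swings would be rejected rather than silently producing negative rates.
- **Duplicate (market, year, month, item) rows are a hard error**, not
  averaged away: the source statistics offices already reduce to one
  observation per market-month, so duplicates signal a data defect.

## Harmonic seasonality

Log prices and log diet costs follow

    ln C_kt = β₀ + β_s sin(2πt/12) + β_c cos(2πt/12) + T(t) + Y_t + ε_kt

with `T(t)` a cubic polynomial in a centred, scaled month index (scaling
controls design conditioning; the trend is nuisance and unreported) and
`Y_t` crop-year fixed effects (first crop year as reference; the crop year
starts at a configurable month, default May, and the dummies are dropped
automatically when fewer than two crop years are observed, where they
would be collinear). The month index is anchored so that t = 1 falls in
January of the first observed year; the phase is therefore calendar-
interpretable. Level-scale series (kcal or cost components by food group)
use the same regressors on the untransformed response.

Multi-market panels are fitted with `statsmodels` MixedLM (REML): random
intercept plus independent random sin and cos coefficients by market
(independent variance components by default — with typical panel sizes a
free 3×3 random-effect covariance is weakly identified). If the mixed fit
fails to converge the estimator falls back to pooled OLS with
cluster-robust (by market) standard errors and the output row is flagged.
Single-market series use OLS.

### Amplitude, peak, intensity

With `(β_s, β_c)` and covariance `(σ_s², σ_c², σ_sc)`:

- `A = √(β_s² + β_c²)`,
  `Var(A) = (σ_s²β_s² + σ_c²β_c² + 2σ_sc β_sβ_c) / (β_s² + β_c²)`.
- `P = (12/2π)·atan2(β_s, β_c)` mapped to (0, 12], so the fitted seasonal
  component `A·cos(2π(t − P)/12)` peaks at calendar month `P`. atan2
  covers all four quadrants; a property test checks the closed form
  against a dense grid argmax to 1e-3 months.
- `Var(φ) = (σ_s²β_c² + σ_c²β_s² − 2σ_sc β_sβ_c) / (β_s² + β_c²)²` and
  `Var(P) = (12/2π)² Var(φ)`. The **minus** sign on the cross term is the
  analytic delta-method gradient of `φ = −arctan(β_s/β_c)`; a Monte-Carlo
  test drawing `(β_s, β_c)` from their fitted Gaussian confirms it (a
  `published_phase_var` flag flips the sign for comparison with
  conventions that print it positive).
- Intensity is `exp(2A) − 1` on the log scale (the peak-to-nadir excess of
  the multiplicative seasonal component as a fraction of the nadir,
  reported in percent; it must vanish at A = 0), and `2A` in the
  variable's own units on the level scale. 95% CIs transform the
  amplitude CI endpoints `A ∓ 1.96·SE(A)`. Seasonality is *significant*
  when the intensity CI excludes zero.

Two inference caveats are documented rather than hidden. First, at the
null (A* = 0) the amplitude-CI significance rule is a 2-dof chi-square
test: its false-positive rate is `exp(−1.96²/2) ≈ 14.6%`, not 5% — the
test suite asserts this known property. Second, `Â` carries a Rice-type
finite-sample bias of order `Var(β)/A`, negligible at multi-market panel
sizes (where CI coverage is verified at 93–97% over 500 replicates) but
visible for a single short series with small amplitude.

No multiple-testing correction is applied across items or locations by
default (a Benjamini–Hochberg helper could be layered on the results
table); missing months are simply absent rows — no imputation.

The monthly-indicator comparator regresses the same response on 11
calendar-month dummies (November base, so November's coefficient is zero
by construction) plus the cubic trend, and reports the implied peak month
for cross-checking the harmonic fit.

## Synthetic data

The generator emulates a statistics-office retail price panel: for item i
in market k, `ln p = β₀ᵢ + u_k0 + (β_sᵢ + u_ks)·sin + (β_cᵢ + u_kc)·cos +
trend + crop-year effect + ε`, with `(β_sᵢ, β_cᵢ)` derived from the
chosen amplitude/peak by the same convention the estimator inverts, market
random effects `u` with configurable SDs, `ε ~ N(0, σ_ε²)`, uniform
per-cell missingness, and explicit cell deletions for engineering
infeasible market-months (delete the designated sole source of a marker
nutrient — by default the complete staple can be made the only carrier of
vitamin B12). Reproducibility uses one root seed with child RNG streams
per market and per (market, item), so enlarging a scenario never perturbs
existing draws.

Default scenario (fixed once, as study conditions): 5 markets × 60 months,
4 items per food group plus a designed "complete" staple; item amplitudes
drawn from 2–25% scaled by group (fruits/vegetables ×1.8 strongest, animal
foods ×0.25 weakest, mirroring the stylised facts of East African retail
panels); log-price noise σ_ε = 0.08; market intercept SD 0.10 and sin/cos
SDs 0.01; 5% missing cells; mild upward trend and small crop-year shocks.
Group-level base prices keep staples the cheapest calories and animal
foods the dearest, and group-level micronutrient densities are richest in
fruits/vegetables and animal foods — under these defaults the CoNA/CoCA
ratio lands around 1.7–3.7 across seeds, in the range seen in real
low-income panels. The complete staple is priced high: it backstops
feasibility without being the routine optimum, keeping the nutrient
premium strictly positive in typical draws (a negative premium is
possible in principle and is flagged, never clipped).

What the generator does **not** emulate — and therefore what passing
tests cannot certify about real data: actual item lists or price
distributions of any country, heteroskedastic or autocorrelated noise,
item entry/exit, structured reporting gaps beyond the uniform and
engineered mechanisms, measurement error in food composition, and
within-month price dispersion.

## Numerical choices

- LP: HiGHS defaults; 1e-7 relative feasibility for the binding report;
  infeasibility only by certificate, never by iteration cap.
- Denton: exact dense KKT solve (panels are decades at most, so the
  system is tiny); annual-average consistency checked to 1e-9 relative.
- Harmonic fit requires ≥ 24 monthly observations; the indicator model
  additionally requires every calendar month to appear.
- Peak undefined (flagged None) when β_s = β_c = 0 exactly.
- Winsorization cutpoint uses the pandas linear-interpolation quantile.
- All tabular outputs are plain CSV with a stamped header comment
  (package version, config hash, seed); the run manifest records row
  accounting and infeasible-month counts, and infeasible market-months
  are excluded from every seasonality input.

## Limitations

Pure least-cost diets ignore palatability, variety, cultural rules and
portion discreteness; requirement sets cover one reference demographic
(no pregnancy/lactation or child sets); a single annual harmonic cannot
represent bimodal seasonal calendars; and the mixed model assumes
independent random effects across markets rather than spatial
correlation. The measured seasonality is the smooth harmonic component
only — anomalies (conflict, outbreaks) and higher harmonics are outside
its scope.
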