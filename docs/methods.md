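# Methods

## The analysis

`holcair` estimates how ambient air pollution levels and their long-run
trends differ across urban areas defined by historical HOLC redlining
grades, at the census-tract level, over a multi-year study window
(canonically 2000–2016). The chain is: score tracts by redlining exposure,
aggregate gridded daily pollutant estimates to tract-year annual means,
summarize tract demographics by score category, and fit a longitudinal
mixed model of annual means on category, year, and their interaction.

## Redlining score

HOLC polygons carry grades A–D, weighted 1–4. For tract *i* with land area
`L_i`, the grade-g fraction is `f_ig = area(tract_i ∩ union of grade-g
polygons) / L_i`, and the score is `s_i = Σ_g f_ig · w_g ∈ [0, 4]`.
Categories are left-open, right-closed bins — `(0,1] → A, (1,2] → B,
(2,3] → C, (3,4] → D` — so a tract fully covered by one grade lands exactly
in that grade (score 1.0 is category A), and a tract with no graded area
scores 0 and is *ungraded*.

Choices where the procedure is genuinely open:

- **Tract selection.** The study boundary is the convex hull of the graded
  polygons; "within or intersecting" is implemented as intersection area
  above a sliver tolerance (default 1 m², configurable), so tracts sharing
  only an edge with the hull are excluded.
- **Denominators.** Grade fractions divide by census *land* area (`ALAND`,
  which excludes water) when the attribute is present, else by polygon
  area. Exposure weights (below) divide by total polygon area. Both
  defaults are configurable.
- **Overlapping grade polygons** (digitization artifacts) can push the
  fraction sum above 1; fractions are then rescaled to sum to 1 and a
  data-quality warning is logged.
- No minimum graded-fraction threshold: any positive graded overlap above
  the sliver tolerance makes a tract graded.

## Exposure aggregation

Daily pollutant estimates arrive on a regular grid (nominally 1 km²). The
weight of cell *g* for tract *i* is `w_ig = area(tract_i ∩ cell_g) /
area(tract_i)`; the tract's daily value is the weight-renormalized average
over cells with data that day. Weights are renormalized when raw coverage
is at least `min_coverage` (default 0.8) and the tract-day is set missing
below that; annual means require at least `min_day_frac` (default 0.75) of
the year's days. Leap days are included. The data model assumes full grid
coverage in the source analysis; both thresholds exist for robustness and
are logged.

**Aberrant-value screening.** Modeled pollution surfaces occasionally
carry sustained multi-month dips in clusters of cells. The automated
screen works on *detrended* values: each cell's Theil–Sen slope over its
annual medians is removed first (the study period's own secular trend —
roughly −1 unit/yr over 17 years, i.e. ~15 units end to end — would
otherwise swamp any plausible threshold), then deviations from the cell's
month-of-year median are smoothed with a centered rolling median of width
`min_run_days` (default 14), and cell-days whose smoothed deviation
exceeds `threshold` (default 5) robust SDs (1.4826×MAD of the month
deviations) are removed. The rolling median is what makes the screen a
*cluster* detector: isolated noisy days are damped to near zero while a
sustained dip keeps its full magnitude. A manual exclusion list
(cells × date-range) is also supported, so an inspection-based removal of
a known bad window is exactly expressible in configuration. On synthetic
grids with a −15-unit two-year dip injected into half the cells, the
default screen recovers ≥ 90% of injected cell-days with < 1% false
positives (measured by the acceptance suite).

## Mixed-effects trend model

For tract *i* in category *c(i)* at year *t*:

    y_it = β₀ + β_c(i) + (β_t + γ_c(i)) · (t − t₀) + u_i + ε_it
    u_i ~ N(0, σ²_u),   ε_it ~ N(0, σ²_e)

with A as the reference (`β_A = γ_A = 0`) and year centered at the first
panel year, so `β₀` is the reference level at `t₀` and `β_t` its slope.
The tract random intercept absorbs the within-tract correlation of
repeated annual means. Each pollutant is fit separately.

- **Estimation** is REML via statsmodels `MixedLM` (lbfgs), with ML as a
  fallback on non-convergence. Two degenerate regimes are handled exactly:
  noise-free panels (zero least-squares residual) return the exact
  least-squares solution with zero variance components, and panels whose
  random-effect variance sits on the zero boundary (where the mixed
  likelihood information matrix is singular) fall back to OLS, which is
  the model's exact limit at σ²_u = 0.
- **Predicted levels** at year *y* are `β₀ + β_c + (β_t + γ_c)(y − t₀)`
  with SEs from the fixed-effect covariance; category slopes are
  `β_t + γ_c`.
- **Overall tests** of category differences in levels at a given year
  (`β_c + γ_c(y − t₀) = 0` jointly) and in slopes (`γ_c = 0` jointly) are
  Wald chi-square tests on the fitted covariance with df = number of
  non-reference categories. Denominator-df corrections
  (Kenward–Roger/Satterthwaite) are out of scope; with tract counts in the
  tens and 17 annual measures each, the normal approximation is adequate
  (type-I error calibrates to 3–7% at 500 replicates in the acceptance
  suite).
- **Pairwise contrasts** compare each non-reference category with A, at a
  Bonferroni threshold α/m where m is the number of non-reference
  categories actually present (4 when ungraded tracts exist, 3 when the
  hull contains none). By default contrasts are gated on the overall test:
  they are reported but flagged not-evaluated unless the overall test
  rejects at α.
- Random slopes are not fitted; the random-effects structure is a tract
  intercept only, matching the repeated-measures correlation the model is
  meant to absorb. Reparameterizing `t₀` changes `β₀/β_c` but not levels
  or slopes (tested).

One caveat on a tempting invariant: with σ²_u > 0, mixed-model SEs exceed
naive OLS SEs for the *level* terms but are *smaller* for slope terms,
because time contrasts are within-tract comparisons. The test suite
asserts the direction per block.

## Synthetic city generator

The generator emulates exactly the statistical structure the analysis
assumes, with known truth:

- **Tracts** are an `nx × ny` lattice of square cells (meter units);
  tiling is exact and land area equals polygon area (no water).
- **HOLC layout**: vertical grade bands with edges snapped to half-tract
  positions (so expected overlap fractions are analytic and some tracts
  straddle two grades), and the ungraded margin carved out as a *central*
  horizontal strip so the convex hull of the graded areas still contains
  ungraded tracts — as in cities whose HOLC maps left interior pockets
  unmapped. Realized per-grade areas land within 5 percentage points of
  targets (exact for half-tract-aligned layouts). A separate "hole city"
  builder yields an exact count of interior ungraded tracts for
  share-arithmetic checks.
- **Daily pollution**: cell value = category intercept of the cell's
  dominant tract + category slope × (year − y₀) + an annual sinusoid +
  a tract-level random intercept + iid daily noise. Defaults follow
  NO2-magnitude trends in redlined cities: intercepts 33.5 (A) to 36.0
  (ungraded) ppb, slopes −1.01 (A) to −0.87 (ungraded) ppb/yr. The
  within-year structure of real modeled surfaces is not published;
  seasonal amplitude 3 ppb, daily noise SD 2 ppb, and tract-RE SD 0.5 ppb
  are chosen for testability (small enough that a −15-unit injection is
  unambiguous, large enough that screening and renormalization paths are
  exercised), not realism.
- **Census/SVI tables**: Normal draws per category and period with
  big-city magnitudes (income and education highest in A, poverty and
  %Black highest in D; SVI means roughly twice as high in D as in A),
  SVI clamped to [0, 1], missingness injectable.
- **Annual-panel shortcut**: statistical simulations draw tract-year means
  directly from the trend model (`generate_annual_panel`), skipping the
  daily grid.

What passing tests therefore do **not** show about real data: the
generator has no spatial correlation between tracts, no autocorrelated
residuals, no realistic seasonality or meteorology, perfectly rectangular
geographies, and Normal census variables. It validates the *pipeline
arithmetic and inference machinery*, not the upstream exposure models or
real-city effect sizes.

## Problem sizes and numerics

- Calibration simulations (slope-CI coverage, overall-test type-I) run 500
  replicates at 20 tracts/category over 17 years with σ_e = 0.3,
  σ_u = 0.5 — coverage and size are properties of the model specification,
  not of n, so a moderate panel per replicate is the package's choice.
- The Monte-Carlo aggregation oracle samples 10⁵ uniform points per tract
  on a grid offset by half a cell from the tract lattice, agreeing with
  the area-weighted means within 3 Monte-Carlo SEs.
- Tolerances: sliver 1 m² for overlays; 1e−9 relative for analytic
  geometry identities; 1e−6 absolute for noise-free coefficient recovery.
- Determinism: one master seed derives independent substreams per
  generator component; the end-to-end report writes no timestamps and
  sorts JSON keys, so fixed-seed runs are byte-identical.

## Known limitations

- GeoJSON only; shapefiles must be converted upstream. No CRS handling —
  all layers must share a planar, equal-area, meter-unit frame.
- Area weighting ignores population distribution within tracts.
- The mixed model assumes linear trends and exchangeable tract effects; no
  spatial correlation, no AR residuals, no random slopes (flag reserved).
- Percent change operates on category-level means, not averaged
  tract-level changes; categories means are unweighted tract averages, so
  large and small tracts count equally.
- Published tables from real cities depend on the real exposure surfaces;
  synthetic recovery demonstrates correctness of the method, and printed
  worked examples (percent-change cells, ungraded shares) are reproduced
  exactly from printed inputs.
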