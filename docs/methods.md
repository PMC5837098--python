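# Methods

## Model

### Yield–density parabola

Stand yield is modelled as `Y(D) = A(D − Dm)² + Ym` with `A < 0`; the
expanded coefficients are `B = −2·A·Dm` and `C = A·Dm² + Ym`. Units are
fixed package-wide: model densities in plants/m², field densities in
plants/hm² (10⁴ m²/hm²), stand yields in t/hm², per-plant yields in t.
Recovering `Ym` from expanded coefficients involves the cancellation
`C − B²/4A`, so its round-trip accuracy is relative to the parabola's
magnitude (`max(Ym, |C|)`), not to `Ym` alone.

The *density sensitivity* of a variety is the angle θ (degrees, 0 < θ <
180) between the two tangents drawn at unit density offsets from the
optimum, whose slopes are ±2A; hence `A = −tan(θ/2)/2`. This reading makes
the conventional sensitivity values {16, 48, 80, 112}° dimensionally
sensible and monotone in |A|: θ = 90° gives A = −1/2, and θ → 0 the flat
parabola. No additional scaling of A by the yield level is applied:
sensitivity and maximum yield are independent knobs here, although in real
germplasm the two are correlated.

### Emergence grids

A field is `n_rows × n_cols` planting positions with fixed row and plant
spacings; each position emerges independently with probability ρ
(i.i.d. Bernoulli — no soil patchiness or spatially correlated failure).
Layouts built from a target density fix the row spacing and solve the
plant spacing from `density = 10⁴/(row_spacing · plant_spacing)`; row and
column counts are floors of the field dimensions, so the realized density
matches the target to within one row/column granule and the *planted
extent* (`n_cols·plant_spacing × n_rows·row_spacing`) is the field
rectangle used everywhere downstream.

Randomness is a single seedable stream per simulation; replicate `r` of an
experiment draws from a stream derived from `(base_seed, …, r)`, so every
experiment is bit-reproducible from one integer seed while replicates stay
independent.

### Missing spots

A seedling missing spot is a maximal connected component of zeros.
**8-connectivity is the default**: the replicate-averaged spot counts it
produces on a 60 × 120 grid (≈293 at ρ = 0.95, ≈466 at ρ = 0.9) agree with
the Euler-characteristic approximation `V − E + T` for the king-graph
lattice and with the reference statistics this package reproduces, whereas
4-connectivity gives ≈324/≈578. 4-connectivity remains selectable.

Per-rate statistics are replicate means; the *missing plants per spot*
column is the **ratio of means** (mean missing / mean spots), which is
defined even when single replicates have no spots, rather than the mean of
per-replicate ratios.

Curve fitting: spots-per-100-points vs rate is fitted by OLS on the
quadratic monomial basis; the per-spot missing count vs rate by
`y = α·e^(βx)`, either log-linear (OLS on ln y, the default; its R² is on
the log scale) or nonlinear least squares initialised from the log-linear
solution (R² on the original scale, floored at 0). The published
exponential coefficients for this law cannot be pinned to a unique point
set and fit method, so they are treated as indicative only.

### Voronoi nutrition areas

Each emerged plant sits at its cell centre (half-spacing margin from the
field edge). Cells are clipped to the field rectangle by reflecting plant
points across each of the four edges before tessellating (the bisector
between a point and its mirror is the edge itself), which makes a full
regular grid partition the field into exact `row_spacing × plant_spacing`
rectangles and forces the areas to sum to the field area exactly.

For speed, only points inside a boundary band are mirrored: a cell can
only reach an edge through a run of missing plants, so the band depth is
the deepest such run at that edge plus a safety margin; if the resulting
areas fail a 10⁻⁹ conservation check (or any kept cell is unbounded) the
computation silently redoes itself with every point mirrored. Qhull's
tessellation is deterministic for identical input, so identical grids give
bit-identical areas.

### Compensated yield and the zero clamp

With a full stand the field is priced directly at the planting density.
Otherwise per-plant yield is the parabola at the plant's equivalent
density `1/area`, converted to mass. Two pricing variants exist, and the
choice matters:

* `per_plant_yield` / `compensated_field_yield` clamp each plant at zero
  mass — a plant cannot produce negative grain — which is the right
  behaviour for pricing an individual stand (e.g. a lone survivor on a
  huge area).
* `run_method_comparison` defaults to the **raw, unclamped parabola**. In
  the extreme corners of the factorial grid (dense stands of low-yield,
  highly sensitive varieties) the parabola extrapolates below zero; the
  clamp then caps Method 1's losses and inverts the policy orderings the
  experiment exists to measure, while the unclamped model preserves them.
  The experiment is a comparison of policies under one response model, so
  the un-floored response is the default; `clamp=True` switches to the
  floored pricing.

One algebraic consequence: under unclamped pricing the Method 2 − Method 1
yield gap is exactly independent of `Ym` (the areas partition the plot, so
`Ym` adds identically to both methods); the widening of Method 2's
advantage at higher yield levels appears only under clamped pricing, and
is tested there.

## Study conditions and problem sizes

* Missing-spot experiments: 60 × 120 grid, row spacing twice the plant
  spacing (0.6 m / 0.3 m), rates {0.95, 0.925, 0.9, 0.85, 0.8, 0.75, 0.7},
  1000 replicates per rate, 8-connectivity.
* Method comparison: optimum densities {4.5, 6, 7.5, 9, 10.5, 12}
  plants/m², maximum yields {5.25, 7.5, 9.75, 12, 14.25} t/hm²,
  sensitivities {16, 48, 80, 112}°, emergence rates
  {0.75, 0.85, 0.9, 0.95}, both methods, 200 replicates per cell, row
  spacing 0.6 m. Method 2 reaches its inflated density by shrinking the
  plant spacing; fractional plants resolve through the layout's floor
  granularity.
* The comparison plot is **20 m × 20 m** (1 440–6 400 positions across the
  density range). Yields are normalised per hm², so plot size is purely a
  Monte-Carlo convergence knob: the chosen plot keeps replicate means
  tight enough for every ordering in the factorial summary while the full
  480-cell experiment (9 600 tessellations) completes in minutes. Since
  the same emergence geometry serves every (Ym, θ) combination, grids and
  Voronoi areas are simulated once per (density, rate, method, replicate)
  and re-priced under each parabola.

## Regression summaries

*Reduction vs rate* (at a fixed sensitivity, by default 112°): OLS of
`Ym − mean yield` on ρ per (optimum density, method), pooling yield
levels. *Reduction vs sensitivity*: OLS of the reduction on θ and θ·ρ
(intercept + two slopes) per (density, method), pooling yield levels and
rates. Coefficient magnitudes depend on unstated experiment details
(replicate count, plot size, compensation variant), so the meaningful
contract is signs and orderings: negative rate slopes with
|slope(Method 2)| < |slope(Method 1)|, positive sensitivity main effects,
negative interactions, and positive (negative) correlation of mean yield
(yield spread) with emergence rate.

## What the generator does and does not emulate

The simulator reproduces the stochastic geometry of stand establishment
under the stated model: independent emergence, equal-vigour plants, and
compensation mediated purely by ground area through a static parabola. It
does not model spatially correlated emergence (seedbed or moisture
patches), competition dynamics, light interception, temporal growth,
variety × environment interaction, or economics (seed cost vs yield).
Passing tests therefore validate the model's internal consistency and its
published summary statistics, not field-level predictions for any
particular variety.

## Numerical choices

* Bernoulli draws use numpy's PCG64 via `default_rng(seed tuple)`.
* Connected components via `scipy.ndimage.label` with the 4- or
  8-neighbourhood structuring element; the test suite cross-checks it
  against an independent BFS flood fill.
* Voronoi via `scipy.spatial.Voronoi` (Qhull); polygon areas by a
  vectorised shoelace over the kept regions.
* Quadratic fits via linear least squares on the monomial design (rank
  checked); exponential fits as described above.
* Seeds-per-hole uses `ceil(log(target)/log(1−ρ))` with a 10⁻¹²
  slack before the ceiling to absorb floating-point representation of
  exact integer bounds.
* Degenerate inputs: empty fields yield 0 with a warning; a single plant
  owns the whole field; rates outside [0, 1], non-positive areas/densities
  and malformed layouts raise `ValueError`.

## Known limitations

* The boundary-band mirror optimisation falls back to full mirroring by a
  conservation check rather than a formal worst-case bound; the fallback
  makes the result exact in all cases but costs a second tessellation when
  triggered.
* The exponential law's published coefficients are sensitive to the exact
  point set used; only the qualitative decay is asserted.
* Sensitivity angles near 180° produce |A| → ∞ and are accepted but
  numerically extreme; the conventional range tops out at 112°.
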