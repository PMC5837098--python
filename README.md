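# maizesim

Monte-Carlo simulation of **single-seed precise sowing** of maize.

Single-seed sowing places exactly one seed per planting position instead of
the traditional several-seeds-per-hole insurance, so any seed that fails to
emerge leaves a gap in the stand. `maizesim` answers the planning questions
that raises, for agronomists and breeders who want simulated rather than
season-long field answers:

* How do gaps (**seedling missing spots**) distribute across a field at a
  given field seedling emergence rate ρ?
* How much of a gap's lost yield do the surrounding plants recover
  (**yield compensation**)?
* Which sowing policy is better: sowing at the optimum stand density D\*
  (**Method 1**), or inflating the sowing rate to D\*/ρ so the *emerged*
  stand averages D\* (**Method 2**)?

## The model

Stand yield is a downward parabola in planting density (vertex form)

```
Y(D) = A (D − Dm)² + Ym ,   A < 0
```

with optimum density `Dm` (plants/m²) and maximum yield `Ym` (t/hm²).
Varieties are parameterised by a *density sensitivity* angle θ: the angle
between the two tangents of slope `dY/dD = ±2A` at unit density offsets
from the optimum, giving `A = −tan(θ/2)/2`.

A field is a rectangular lattice of planting positions; each position
emerges independently with probability ρ (i.i.d. Bernoulli), giving a 0/1
emergence grid. Missing-spot statistics are connected components of the
zeros (8-adjacency by default, 4-adjacency selectable). For yield, each
emerged plant receives its **nutrition area** `x` — its Voronoi cell
clipped to the field rectangle — and is priced by the same parabola at its
equivalent density `1/x`:

```
Yd = F(1/x) · x / 10⁴   (t per plant)
```

so survivors bordering a gap inherit its ground and partially compensate
the loss. Policy comparisons run a factorial grid over
(Dm, Ym, θ, ρ, method) with replicate fields and summarise means, standard
deviations and regression slopes of the yield reduction.

## Worked example

```python
from maizesim import (FieldLayout, fit_quadratic, seeds_per_hole,
                      spot_rate_sweep, sweep_to_frame)

# how many seeds per hole would traditional sowing need at 85% emergence?
print(seeds_per_hole(0.85))            # SeedsPerHole(n_seeds=3, bound=2.43)

# missing-spot statistics on a 60 x 120 stand, 1000 replicates per rate
layout = FieldLayout(n_rows=60, n_cols=120, row_spacing=0.6, plant_spacing=0.3)
records = spot_rate_sweep(layout, rates=(0.95, 0.925, 0.9, 0.85, 0.8, 0.75, 0.7),
                          n_replicates=1000, connectivity=8, seed=42)
frame = sweep_to_frame(records)
print(frame.round(2).to_string(index=False))

fit = fit_quadratic(frame["rate"], frame["hundred_dot_spot"])
print(fit.coefficients, fit.vertex)
```

prints

```
 rate  mean_missing  mean_spots  hundred_dot_spot  spot_missing_seedling
 0.95        358.98      292.10              4.06                   1.23
 0.92        540.36      393.00              5.46                   1.37
 0.90        719.08      465.40              6.46                   1.55
 0.85       1078.67      538.84              7.48                   2.00
 0.80       1441.82      531.46              7.38                   2.71
 0.75       1798.54      468.57              6.51                   3.84
 0.70       2159.99      366.87              5.10                   5.89
(-189.63, 310.08, -119.19) (0.8176, 7.5706)
```

Reading the table: at ρ = 0.85 a 7200-position stand loses about 1079
plants spread over ~539 spots — about 7.5 spots per 100 planting points
with 2 missing plants per spot. The spots-per-100-points column is
*unimodal* in ρ: fitting a parabola puts the peak near ρ ≈ 0.82 — gaps are
most numerous at intermediate emergence, because at low ρ they merge into
fewer, larger spots (the per-spot missing count grows roughly like
`exp(−6.2 ρ)` over this range).

The same machinery drives the policy experiments:

```python
from maizesim import run_method_comparison
results = run_method_comparison(n_replicates=200, seed=1)   # ~7 min
```

which shows Method 2 beating Method 1 in mean yield in every one of the
480 factorial cells while also fluctuating less between seasons.

Everything is also exposed as a CLI (`maizesim spot-sweep`,
`compare-methods`, `table1`, `table2`, `fit`, `render-grid`, `run`); every
run drops a `manifest.json` + `config.yaml` from which it can be re-run
bit-for-bit.

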