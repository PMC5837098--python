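"""Seedling-missing-spot statistics and their fitted distribution laws.

A *seedling missing spot* is a maximal connected region of non-emerged
positions in the planting grid (connected components of zeros, under 4- or
8-adjacency).  Sweeping the emergence rate and averaging over replicates
yields the spot statistics:

* mean number of missing seedlings per field,
* mean number of spots per field,
* *hundred-dot spots*: spots per 100 planting points,
* *spot missing seedlings*: average missing plants per spot, computed as
  the ratio of the two means.

Across emergence rates, the hundred-dot-spot count follows a downward
parabola (few spots when almost everything emerges, few but large spots
when little does) and the per-spot missing count grows roughly
exponentially as the rate falls.  Least-squares fits of both laws are
provided here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .field_simulator import EmergenceGrid, FieldLayout, simulate_replicates

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class SpotLabeling:
    """Connected-component labeling of the missing positions.

    ``labels`` is an integer matrix: 0 on emerged cells, ``k`` in 1..n_spots
    on the cells of spot ``k``.
    """

    labels: np.ndarray
    n_spots: int
    connectivity: int


@dataclass(frozen=True)
class SpotStatsRecord:
    """Replicate-averaged missing-spot statistics at one emergence rate."""

    rate: float
    mean_missing: float
    mean_spots: float
    hundred_dot_spot: float
    spot_missing_seedling: float  # NaN when mean_spots == 0
    n_replicates: int


@dataclass(frozen=True)
class CurveFitResult:
    """A least-squares curve fit with its goodness of fit.

    ``coefficients`` is ``(a, b, c)`` for ``y = a x^2 + b x + c`` or
    ``(alpha, beta)`` for ``y = alpha * exp(beta x)``.  ``r_squared`` is the
    coefficient of determination on the scale the fit was performed on
    (original scale for quadratic and nonlinear-exponential fits, log scale
    for the log-linear exponential fit).
    """

    model_kind: str
    coefficients: tuple[float, ...]
    r_squared: float
    x_range: tuple[float, float]
    y_range: tuple[float, float]

    @property
    def vertex(self) -> tuple[float, float]:
        """Vertex (extreme point) of a quadratic fit."""
        if self.model_kind != "quadratic":
            raise ValueError("vertex is defined only for quadratic fits")
        a, b, c = self.coefficients
        return (-b / (2.0 * a), c - b**2 / (4.0 * a))

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.model_kind == "quadratic":
            a, b, c = self.coefficients
            return a * x**2 + b * x + c
        alpha, beta = self.coefficients
        return alpha * np.exp(beta * x)


def label_spots(grid: EmergenceGrid | np.ndarray, connectivity: int = 8) -> SpotLabeling:
    """Label maximal connected components of missing (zero) cells.

    ``connectivity=4`` joins cells sharing an edge; ``connectivity=8`` also
    joins diagonal neighbours.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    cells = grid.cells if isinstance(grid, EmergenceGrid) else np.asarray(grid)
    labels, n_spots = ndimage.label(cells == 0, structure=_STRUCTURES[connectivity])
    return SpotLabeling(labels=labels, n_spots=int(n_spots), connectivity=connectivity)


def spot_statistics(
    grids: Sequence[EmergenceGrid], connectivity: int = 8
) -> SpotStatsRecord:
    """Average missing-spot statistics over replicate grids.

    All grids must share one layout and emergence rate.  The per-spot
    missing count is the ratio of means (mean missing / mean spots), which
    stays defined when individual replicates have no spots; it is NaN only
    if no replicate has any.
    """
    if len(grids) == 0:
        raise ValueError("need at least one grid")
    layouts = {(g.layout, g.rate) for g in grids}
    if len(layouts) > 1:
        raise ValueError("all grids must share the same layout and rate")
    n_positions = grids[0].layout.n_positions
    missing = np.array([int((g.cells == 0).sum()) for g in grids], dtype=float)
    spots = np.array(
        [label_spots(g, connectivity).n_spots for g in grids], dtype=float
    )
    mean_missing = float(missing.mean())
    mean_spots = float(spots.mean())
    return SpotStatsRecord(
        rate=grids[0].rate,
        mean_missing=mean_missing,
        mean_spots=mean_spots,
        hundred_dot_spot=100.0 * mean_spots / n_positions,
        spot_missing_seedling=(mean_missing / mean_spots) if mean_spots > 0 else float("nan"),
        n_replicates=len(grids),
    )


def spot_rate_sweep(
    layout: FieldLayout,
    rates: Sequence[float],
    n_replicates: int = 1000,
    connectivity: int = 8,
    seed: int = 0,
) -> list[SpotStatsRecord]:
    """Run the missing-spot experiment across a sweep of emergence rates.

    Each rate gets ``n_replicates`` independent grids; replicate streams are
    derived deterministically from ``(seed, rate index, replicate)``, so the
    whole sweep is reproducible from one seed.
    """
    records = []
    for k, rate in enumerate(rates):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rates must lie in [0, 1], got {rate}")
        grids = list(simulate_replicates(layout, rate, n_replicates, base_seed=(seed, k)))
        records.append(spot_statistics(grids, connectivity=connectivity))
    return records


def sweep_to_frame(records: Sequence[SpotStatsRecord]) -> pd.DataFrame:
    """Spot-sweep records as a five-column table (one row per rate)."""
    return pd.DataFrame(
        {
            "rate": [r.rate for r in records],
            "mean_missing": [r.mean_missing for r in records],
            "mean_spots": [r.mean_spots for r in records],
            "hundred_dot_spot": [r.hundred_dot_spot for r in records],
            "spot_missing_seedling": [r.spot_missing_seedling for r in records],
        }
    )


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def fit_quadratic(x: Sequence[float], y: Sequence[float]) -> CurveFitResult:
    """Ordinary least squares for ``y = a x^2 + b x + c``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("quadratic fit needs at least 3 points")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("design is rank deficient (points collinear in x, x^2)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    return CurveFitResult(
        model_kind="quadratic",
        coefficients=tuple(float(c) for c in coef),
        r_squared=_r_squared(y, fitted),
        x_range=(float(x.min()), float(x.max())),
        y_range=(float(y.min()), float(y.max())),
    )


def fit_exponential(
    x: Sequence[float], y: Sequence[float], method: str = "log-linear"
) -> CurveFitResult:
    """Least-squares fit of ``y = alpha * exp(beta * x)``.

    ``method="log-linear"`` regresses ``ln y`` on ``x`` (requires y > 0);
    ``method="nonlinear"`` minimises squared error on the original scale,
    initialised from the log-linear solution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("exponential fit needs at least 2 points")
    if method not in ("log-linear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    if np.any(y <= 0):
        raise ValueError("exponential fit requires strictly positive y")
    beta, ln_alpha = np.polyfit(x, np.log(y), 1)
    alpha = float(np.exp(ln_alpha))
    beta = float(beta)
    if method == "nonlinear":
        (alpha, beta), _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(b * t), x, y, p0=(alpha, beta), maxfev=10000
        )
        r2 = _r_squared(y, alpha * np.exp(beta * x))
    else:
        r2 = _r_squared(np.log(y), ln_alpha + beta * x)
    return CurveFitResult(
        model_kind="exponential",
        coefficients=(float(alpha), float(beta)),
        r_squared=r2,
        x_range=(float(x.min()), float(x.max())),
        y_range=(float(y.min()), float(y.max())),
    )
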