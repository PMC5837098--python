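"""Stochastic seedling-emergence grids on a rectangular planting layout.

A field sown by single-seed precise sowing is a rectangular lattice of
planting positions: ``n_rows`` rows a fixed ``row_spacing`` apart, each row
holding ``n_cols`` positions a fixed ``plant_spacing`` apart.  Whether the
seed at a position emerges is an independent Bernoulli trial with success
probability ``rate`` (the field seedling emergence rate), so a simulated
field is a 0/1 matrix: 1 = emerged, 0 = missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .yield_model import M2_PER_HM2


@dataclass(frozen=True)
class FieldLayout:
    """Rectangular planting layout: row/column counts and spacings (m)."""

    n_rows: int
    n_cols: int
    row_spacing: float
    plant_spacing: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("layout needs at least one row and one column")
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_positions(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def width(self) -> float:
        """Planted extent along rows, m (n_cols * plant_spacing)."""
        return self.n_cols * self.plant_spacing

    @property
    def height(self) -> float:
        """Planted extent across rows, m (n_rows * row_spacing)."""
        return self.n_rows * self.row_spacing

    @property
    def area_m2(self) -> float:
        return self.width * self.height

    @property
    def density_per_hm2(self) -> float:
        """Planting density, plants/hm^2 = 10^4/(row_spacing*plant_spacing)."""
        return M2_PER_HM2 / (self.row_spacing * self.plant_spacing)

    @property
    def density_per_m2(self) -> float:
        return 1.0 / (self.row_spacing * self.plant_spacing)


@dataclass(frozen=True)
class EmergenceGrid:
    """A simulated emergence outcome on a layout.

    ``cells`` is an ``(n_rows, n_cols)`` uint8 matrix with 1 = emerged,
    0 = missing; ``rate`` the Bernoulli emergence probability; ``seed`` the
    RNG seed (or seed sequence) that produced it, for provenance.
    """

    layout: FieldLayout
    cells: np.ndarray
    rate: float
    seed: int | tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.uint8)
        if cells.shape != (self.layout.n_rows, self.layout.n_cols):
            raise ValueError(
                f"cells shape {cells.shape} does not match layout "
                f"({self.layout.n_rows}, {self.layout.n_cols})"
            )
        if not np.isin(cells, (0, 1)).all():
            raise ValueError("cells must be binary (0 = missing, 1 = emerged)")
        object.__setattr__(self, "cells", cells)


class EmergenceCounts(NamedTuple):
    n_emerged: int
    n_missing: int
    realized_rate: float


def layout_from_density(
    target_density: float,
    row_spacing: float,
    field_width: float,
    field_height: float,
) -> FieldLayout:
    """Lay out a field of the requested planting density (plants/hm^2).

    The row spacing is fixed; the plant spacing is solved from
    ``density = 10^4/(row_spacing * plant_spacing)`` and the row/column
    counts are the number of whole spacings that fit the field, so the
    realized density matches the target up to one row/column granule.
    """
    if target_density <= 0:
        raise ValueError("target density must be positive")
    if field_width <= 0 or field_height <= 0:
        raise ValueError("field dimensions must be positive")
    plant_spacing = M2_PER_HM2 / (row_spacing * target_density)
    n_rows = math.floor(field_height / row_spacing)
    n_cols = math.floor(field_width / plant_spacing)
    if n_rows < 1 or n_cols < 1:
        raise ValueError(
            f"degenerate layout: spacing ({row_spacing} x {plant_spacing:.4g} m) "
            f"exceeds field ({field_width} x {field_height} m)"
        )
    return FieldLayout(n_rows=n_rows, n_cols=n_cols,
                       row_spacing=row_spacing, plant_spacing=plant_spacing)


def simulate_emergence(
    layout: FieldLayout,
    rate: float,
    seed: int | tuple[int, ...] | np.random.SeedSequence | None = None,
) -> EmergenceGrid:
    """Draw one i.i.d. Bernoulli emergence grid: each cell is 1 w.p. ``rate``.

    Reproducible: the same seed always yields the same grid.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"emergence rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    cells = (rng.random((layout.n_rows, layout.n_cols)) < rate).astype(np.uint8)
    stored = seed if isinstance(seed, (int, tuple, type(None))) else None
    return EmergenceGrid(layout=layout, cells=cells, rate=rate, seed=stored)


def simulate_replicates(
    layout: FieldLayout,
    rate: float,
    n_replicates: int,
    base_seed: int | Sequence[int] = 0,
) -> Iterator[EmergenceGrid]:
    """Yield ``n_replicates`` independent grids with deterministic streams.

    Replicate ``r`` is seeded by the pair ``(base_seed, r)`` so a whole
    experiment is reproducible from one base seed while replicates stay
    statistically independent.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base = tuple(base_seed) if isinstance(base_seed, Sequence) else (int(base_seed),)
    for r in range(n_replicates):
        yield simulate_emergence(layout, rate, seed=base + (r,))


def emergence_counts(grid: EmergenceGrid) -> EmergenceCounts:
    """Counts of emerged/missing positions and the realized emergence rate."""
    n_emerged = int(grid.cells.sum())
    n_total = grid.layout.n_positions
    return EmergenceCounts(
        n_emerged=n_emerged,
        n_missing=n_total - n_emerged,
        realized_rate=n_emerged / n_total,
    )


def export_grid_image(grid: EmergenceGrid, path: str | Path, dot_px: int = 1) -> Path:
    """Write the grid as a lossless binary image (PNG or PGM).

    One ``dot_px`` x ``dot_px`` block per planting position; emerged
    positions are black dots, missing positions white, matching the usual
    rendering of simulated emergence maps.
    """
    if dot_px < 1:
        raise ValueError("dot_px must be >= 1")
    path = Path(path)
    # emerged (1) -> black (0), missing (0) -> white (255)
    pixels = np.where(grid.cells == 1, 0, 255).astype(np.uint8)
    pixels = np.kron(pixels, np.ones((dot_px, dot_px), dtype=np.uint8))
    try:
        Image.fromarray(pixels, mode="L").save(path)
    except OSError as exc:
        raise OSError(f"could not write grid image to {path}: {exc}") from exc
    return path


def load_grid_image(path: str | Path, dot_px: int = 1) -> np.ndarray:
    """Read back a grid image written by :func:`export_grid_image`.

    Returns the binary 0/1 matrix (1 = emerged/black).
    """
    pixels = np.asarray(Image.open(Path(path)).convert("L"))
    if dot_px > 1:
        pixels = pixels[::dot_px, ::dot_px]
    return (pixels < 128).astype(np.uint8)


def counts_to_frame(grids: Sequence[EmergenceGrid]) -> pd.DataFrame:
    """Replicate-level emergence counts as a tidy table (for CSV export)."""
    rows = []
    for r, g in enumerate(grids):
        c = emergence_counts(g)
        rows.append({
            "replicate": r, "rate": g.rate,
            "n_emerged": c.n_emerged, "n_missing": c.n_missing,
            "realized_rate": c.realized_rate,
        })
    return pd.DataFrame(rows)
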