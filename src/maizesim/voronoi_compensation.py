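"""Per-plant nutrition areas from a field-clipped Voronoi tessellation.

Plants neighbouring a missing position take over its ground: each emerged
plant's *nutrition area* is its Voronoi cell, clipped to the field
rectangle.  The per-plant yield is then read off the stand yield parabola
at the plant's equivalent density (the reciprocal of its area), so gaps in
the stand are partially compensated by the enlarged cells around them.

Clipping uses the mirror trick: every plant is reflected across each of the
four field edges before tessellating, and only the cells of the original
points are kept.  The perpendicular bisector between a point and its mirror
is the field edge itself, so cells are cut exactly at the boundary, a full
regular grid partitions the field into exact spacing rectangles, and the
cell areas always sum to the field area.

As an optimisation only plants inside a boundary band are mirrored; the
band depth is derived from the deepest run of missing plants at each edge
(only cells behind such a run can reach the boundary).  A conservation
guard falls back to mirroring everything in the rare case the band was too
shallow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import Voronoi

from .field_simulator import EmergenceGrid, emergence_counts
from .yield_model import M2_PER_HM2, YieldDensityModel, per_plant_yield, yield_at_density


@dataclass(frozen=True)
class PlantMap:
    """Emerged-plant coordinates (m) inside the field rectangle.

    Grid cell (i, j) maps to the cell centre
    ``x = (j + 1/2) * plant_spacing``, ``y = (i + 1/2) * row_spacing``;
    ``field_bounds = (W, H)`` is the planted extent, so every plant sits
    strictly inside with at least a half-spacing margin.
    """

    coordinates: np.ndarray  # (n, 2) float array of (x, y)
    field_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        W, H = self.field_bounds
        if coords.shape[0] == 0:
            raise ValueError("plant map must contain at least one plant")
        if (
            np.any(coords[:, 0] <= 0) or np.any(coords[:, 0] >= W)
            or np.any(coords[:, 1] <= 0) or np.any(coords[:, 1] >= H)
        ):
            raise ValueError("all plants must lie strictly inside the field bounds")
        object.__setattr__(self, "coordinates", coords)


@dataclass(frozen=True)
class CellAreas:
    """Nutrition areas (m^2), aligned with the PlantMap plant order."""

    areas: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if np.any(areas <= 0):
            raise ValueError("every nutrition area must be positive")
        object.__setattr__(self, "areas", areas)


def plant_coordinates(grid: EmergenceGrid) -> PlantMap:
    """Cell-centre coordinates of every emerged plant in the grid."""
    rows, cols = np.nonzero(grid.cells)
    if rows.size == 0:
        raise ValueError("grid has no emerged plants")
    ps, rs = grid.layout.plant_spacing, grid.layout.row_spacing
    coords = np.column_stack([(cols + 0.5) * ps, (rows + 0.5) * rs])
    return PlantMap(coordinates=coords, field_bounds=(grid.layout.width, grid.layout.height))


def _edge_band_depths(cells: np.ndarray) -> tuple[int, int, int, int]:
    """Deepest run of missing cells at (left, right, top, bottom), in cells."""
    def depth(first_emerged_along_axis: np.ndarray) -> int:
        return int(first_emerged_along_axis.max()) if first_emerged_along_axis.size else 0

    emerged = cells != 0
    n_rows, n_cols = cells.shape
    # first emerged index per row from each side; rows with no plant span fully
    any_row = emerged.any(axis=1)
    left = np.where(any_row, emerged.argmax(axis=1), n_cols)
    right = np.where(any_row, emerged[:, ::-1].argmax(axis=1), n_cols)
    any_col = emerged.any(axis=0)
    top = np.where(any_col, emerged.argmax(axis=0), n_rows)
    bottom = np.where(any_col, emerged[::-1].argmax(axis=0), n_rows)
    return depth(left), depth(right), depth(top), depth(bottom)


def _mirror_points(points: np.ndarray, W: float, H: float,
                   bands: tuple[float, float, float, float] | None) -> np.ndarray:
    """Stack the points with their reflections across the four field edges.

    ``bands`` gives per-edge band widths in metres (left, right, top,
    bottom); None mirrors every point across every edge.
    """
    x, y = points[:, 0], points[:, 1]
    if bands is None:
        sel = [np.ones(len(points), bool)] * 4
    else:
        bl, br, bt, bb = bands
        sel = [x < bl, x > W - br, y < bt, y > H - bb]
    mirrored = [
        np.column_stack([-x[sel[0]], y[sel[0]]]),
        np.column_stack([2 * W - x[sel[1]], y[sel[1]]]),
        np.column_stack([x[sel[2]], -y[sel[2]]]),
        np.column_stack([x[sel[3]], 2 * H - y[sel[3]]]),
    ]
    return np.vstack([points] + mirrored)


def _cell_areas_from_voronoi(points: np.ndarray, all_points: np.ndarray) -> np.ndarray:
    """Polygon areas (shoelace) of the first ``len(points)`` Voronoi cells."""
    n = len(points)
    vor = Voronoi(all_points)
    regions = [vor.regions[vor.point_region[i]] for i in range(n)]
    idx = np.concatenate(regions)
    lens = np.fromiter((len(r) for r in regions), dtype=int, count=n)
    if idx.min() < 0:  # unbounded cell: band was too shallow
        return np.full(n, np.nan)
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    nxt = np.arange(idx.size) + 1
    nxt[starts + lens - 1] = starts
    v = vor.vertices[idx]
    w = vor.vertices[idx[nxt]]
    cross = v[:, 0] * w[:, 1] - w[:, 0] * v[:, 1]
    return 0.5 * np.abs(np.add.reduceat(cross, starts))


def voronoi_cell_areas(plants: PlantMap, grid: EmergenceGrid | None = None) -> CellAreas:
    """Clipped-Voronoi nutrition area of every plant.

    Passing the source ``grid`` enables the boundary-band mirror
    optimisation; without it (or whenever the band check fails) all points
    are mirrored.  Either way the areas partition the field exactly.
    """
    points = plants.coordinates
    W, H = plants.field_bounds
    field_area = W * H
    if len(points) == 1:
        return CellAreas(areas=np.array([field_area]))

    bands = None
    if grid is not None:
        dl, dr, dt, db = _edge_band_depths(grid.cells)
        ps, rs = grid.layout.plant_spacing, grid.layout.row_spacing
        margin = max(ps, rs)  # covers diagonal reach of corner cells
        bands = (
            (dl + 1.5) * ps + margin,
            (dr + 1.5) * ps + margin,
            (dt + 1.5) * rs + margin,
            (db + 1.5) * rs + margin,
        )
    areas = _cell_areas_from_voronoi(points, _mirror_points(points, W, H, bands))
    if bands is not None and (
        np.any(np.isnan(areas))
        or abs(areas.sum() - field_area) > 1e-9 * field_area
    ):
        areas = _cell_areas_from_voronoi(points, _mirror_points(points, W, H, None))
    return CellAreas(areas=areas)


def compensated_field_yield(model: YieldDensityModel, grid: EmergenceGrid) -> float:
    """Field yield (t/hm^2) with Voronoi gap compensation.

    A full stand is evaluated directly at the planting density.  Otherwise
    each survivor's yield comes from the parabola at its equivalent density
    (1/area) and the per-plant masses are summed and normalised per hm^2.
    An empty field yields 0 (with a warning).
    """
    counts = emergence_counts(grid)
    if counts.n_emerged == 0:
        warnings.warn("empty field: no emerged plants, yield is 0", stacklevel=2)
        return 0.0
    if counts.n_missing == 0:
        return float(yield_at_density(model, grid.layout.density_per_m2))
    plants = plant_coordinates(grid)
    areas = voronoi_cell_areas(plants, grid=grid).areas
    total_t = float(np.sum(per_plant_yield(model, areas)))
    return total_t * M2_PER_HM2 / grid.layout.area_m2


def render_tessellation(grid: EmergenceGrid, path: str | Path) -> Path:
    """Render the clipped tessellation with missing positions highlighted.

    Writes an SVG/PNG (by extension) showing plant points, their Voronoi
    cell edges, and red markers at missing planting positions.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.spatial import voronoi_plot_2d

    plants = plant_coordinates(grid)
    W, H = plants.field_bounds
    vor = Voronoi(_mirror_points(plants.coordinates, W, H, None))
    fig, ax = plt.subplots(figsize=(8, 8 * H / W))
    voronoi_plot_2d(vor, ax=ax, show_points=False, show_vertices=False, line_width=0.6)
    ax.plot(*plants.coordinates.T, "k.", ms=3, label="emerged")
    miss_r, miss_c = np.nonzero(grid.cells == 0)
    if miss_r.size:
        ax.plot(
            (miss_c + 0.5) * grid.layout.plant_spacing,
            (miss_r + 0.5) * grid.layout.row_spacing,
            "ro", ms=4, mfc="none", label="missing",
        )
    ax.set_xlim(0, W), ax.set_ylim(0, H)
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    path = Path(path)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return path
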