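"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from maizesim import FieldLayout


def bfs_spot_count(cells: np.ndarray, connectivity: int) -> int:
    """Independent flood-fill count of connected zero-components.

    Plain breadth-first search over the missing positions, used as an
    oracle against the production labeling.
    """
    cells = np.asarray(cells)
    n_rows, n_cols = cells.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    seen = np.zeros_like(cells, dtype=bool)
    count = 0
    for i in range(n_rows):
        for j in range(n_cols):
            if cells[i, j] != 0 or seen[i, j]:
                continue
            count += 1
            queue = [(i, j)]
            seen[i, j] = True
            while queue:
                ci, cj = queue.pop()
                for di, dj in steps:
                    ni, nj = ci + di, cj + dj
                    if (
                        0 <= ni < n_rows and 0 <= nj < n_cols
                        and cells[ni, nj] == 0 and not seen[ni, nj]
                    ):
                        seen[ni, nj] = True
                        queue.append((ni, nj))
    return count


@pytest.fixture
def table3_layout() -> FieldLayout:
    """The 60 x 120 lattice with row spacing twice the plant spacing."""
    return FieldLayout(n_rows=60, n_cols=120, row_spacing=0.6, plant_spacing=0.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
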