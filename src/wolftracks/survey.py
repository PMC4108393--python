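"""Virtual aerial track surveys on square survey grids.

A survey grid tiles the 14,400 km^2 study extent with square cells (36, 144,
400 or 576 km^2). A virtual survey samples 20% of cells uniformly without
replacement and marks a sampled cell occupied when any simulated travel path
intersects it (perfect detection). Occupancy is the proportion of surveyed
cells occupied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree, box

from .crw import Path

#: Survey-unit areas (km^2) examined in the grid-size sensitivity analysis.
GRID_AREAS_KM2 = (36.0, 144.0, 400.0, 576.0)

#: Fraction of cells sampled per virtual aerial survey.
SURVEY_FRACTION = 0.20

#: Survey replicates per scenario.
N_REPLICATES = 10


@dataclass
class SurveyGrid:
    """Row-major square-cell grid tiling the study extent exactly."""

    extent: tuple[float, float]
    cell_area_km2: float
    origin: tuple[float, float] = (0.0, 0.0)
    _tree: STRtree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        side = np.sqrt(self.cell_area_km2 * 1e6)
        nx = self.extent[0] / side
        ny = self.extent[1] / side
        if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
            raise ValueError(
                f"cell side {side:.0f} m does not divide the extent {self.extent}"
            )
        self.cell_side = float(side)
        self.nx = int(round(nx))
        self.ny = int(round(ny))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_box(self, cell_id: int):
        row, col = divmod(cell_id, self.nx)
        x0 = self.origin[0] + col * self.cell_side
        y0 = self.origin[1] + row * self.cell_side
        return box(x0, y0, x0 + self.cell_side, y0 + self.cell_side)

    def tree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree([self.cell_box(i) for i in range(self.n_cells)])
        return self._tree

    def to_geojson(self, path) -> None:
        feats = []
        for i in range(self.n_cells):
            b = self.cell_box(i)
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"cell_id": i},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [list(map(list, b.exterior.coords))],
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class SurveyResult:
    """One virtual survey replicate."""

    replicate: int
    sampled_cell_ids: frozenset[int]
    occupied_cell_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.occupied_cell_ids <= self.sampled_cell_ids:
            raise ValueError("occupied cells must be a subset of sampled cells")

    @property
    def occupancy(self) -> float:
        return len(self.occupied_cell_ids) / len(self.sampled_cell_ids)


def build_grid(extent: tuple[float, float], cell_area_km2: float) -> SurveyGrid:
    """Square-cell survey grid; the cell side must divide the extent exactly."""
    return SurveyGrid(extent=extent, cell_area_km2=cell_area_km2)


def sample_cells(
    grid: SurveyGrid,
    fraction: float = SURVEY_FRACTION,
    rng: np.random.Generator | int | None = None,
) -> frozenset[int]:
    """Uniform without-replacement sample of round(fraction * n_cells) cells.

    Rounding is round-half-even; a sample rounding to zero is forced to one
    cell with a warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(rng)
    n = round(fraction * grid.n_cells)
    if n == 0:
        warnings.warn("sample fraction rounds to zero cells; surveying one", stacklevel=2)
        n = 1
    return frozenset(rng.choice(grid.n_cells, size=n, replace=False).tolist())


def cell_intersections(paths: list[Path], grid: SurveyGrid) -> frozenset[int]:
    """Cells whose closed squares are geometrically intersected by any path.

    Uses exact segment-box predicates on the whole polyline (a segment
    crossing a cell without an interior vertex still occupies it; touching a
    shared boundary occupies both adjacent cells).
    """
    if not paths:
        return frozenset()
    tree = grid.tree()
    occupied: set[int] = set()
    for p in paths:
        occupied.update(tree.query(p.line(), predicate="intersects").tolist())
    return frozenset(occupied)


def occupancy_rate(
    paths: list[Path], grid: SurveyGrid, sampled_ids: frozenset[int]
) -> float:
    """Proportion of surveyed cells intersected by a travel path."""
    if not sampled_ids:
        raise ValueError("sampled_ids must be non-empty")
    occupied = cell_intersections(paths, grid)
    return len(occupied & sampled_ids) / len(sampled_ids)


def replicate_survey(
    paths_for_replicate,
    grid: SurveyGrid,
    fraction: float = SURVEY_FRACTION,
    n_replicates: int = N_REPLICATES,
    rng: np.random.Generator | int | None = None,
    resample_cells: bool = True,
    detection_prob: float = 1.0,
) -> tuple[float, float, list[SurveyResult]]:
    """Mean and SD of occupancy over replicate virtual surveys.

    ``paths_for_replicate`` is either a static list of paths or a callable
    ``f(rng) -> list[Path]`` redrawing the per-territory path selection each
    replicate. Surveyed cells are redrawn per replicate unless
    ``resample_cells`` is False (one draw shared by all replicates).
    ``detection_prob`` is a hook for imperfect track detection (each
    occupied surveyed cell is detected independently with this
    probability); the survey protocol assumes perfect detection, so it
    defaults to 1 and is left there in all standard analyses.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0 <= detection_prob <= 1:
        raise ValueError("detection_prob must be in [0, 1]")
    rng = np.random.default_rng(rng)
    fixed_cells = None if resample_cells else sample_cells(grid, fraction, rng)
    results = []
    for rep in range(n_replicates):
        paths = paths_for_replicate(rng) if callable(paths_for_replicate) else paths_for_replicate
        sampled = fixed_cells if fixed_cells is not None else sample_cells(grid, fraction, rng)
        occupied = cell_intersections(paths, grid) & sampled
        if detection_prob < 1.0:
            occupied = {c for c in sorted(occupied) if rng.random() < detection_prob}
        results.append(
            SurveyResult(
                replicate=rep,
                sampled_cell_ids=sampled,
                occupied_cell_ids=frozenset(occupied),
            )
        )
    occ = np.array([r.occupancy for r in results])
    return float(occ.mean()), float(occ.std(ddof=1)) if len(occ) > 1 else 0.0, results


def results_to_frame(
    results: list[SurveyResult], **labels
) -> pd.DataFrame:
    """Tidy per-replicate table (scenario labels passed as keyword columns)."""
    rows = [
        {
            **labels,
            "replicate": r.replicate,
            "n_sampled": len(r.sampled_cell_ids),
            "n_occupied": len(r.occupied_cell_ids),
            "occupancy": r.occupancy,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
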