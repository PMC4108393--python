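"""Scenario sweeps: occupancy-abundance curves under movement-rate, pack
cohesion, lone-wolf and survey-unit-size variation.

A scenario fixes the movement month (December = long movements, February =
short), the number of independent hunting units per pack (1, 2 or 4), and
whether lone wolves (a fixed fraction of the total wolf population,
unconstrained by territories) are present. For each pack density a territory
layout is built, a library of 2-day travel paths is simulated per territory,
and replicate virtual surveys on each grid yield mean occupancy.

Seed discipline: a master seed spawns named substreams (layout, library,
path selection, surveyed cells, loners), so paired contrasts (December vs
February, cohesive vs split packs, loners on vs off) share layouts and
surveyed cells and differ only in the factor of interest.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import crw, survey
from .landscape import LandscapeRaster, generate_rsf_surface
from .params import MONTHLY_PARAMS, MovementParams
from .territories import (
    OVERLAP_TARGET,
    STUDY_EXTENT_M,
    TerritoryLayout,
    layout_territories,
    territory_area_for_density,
)

logger = logging.getLogger(__name__)

#: Loners as a fraction of the total wolf population.
LONER_FRACTION = 0.13

#: Mean observed pack size, used to convert pack counts to wolf numbers.
MEAN_PACK_SIZE = 7.8

#: Pack densities swept in the occupancy-abundance curves (packs/1,000 km^2).
DEFAULT_DENSITIES = tuple(np.round(np.arange(0.0, 5.51, 0.5), 1))

HUNTING_UNIT_LEVELS = (1, 2, 4)


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one scenario sweep (or the full experiment cross)."""

    month: str = "December"
    hunting_units: int = 1
    loners_enabled: bool = False
    loner_fraction: float = LONER_FRACTION
    mean_pack_size: float = MEAN_PACK_SIZE
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    grid_areas: tuple[float, ...] = survey.GRID_AREAS_KM2
    survey_fraction: float = survey.SURVEY_FRACTION
    n_replicates: int = survey.N_REPLICATES
    library_size: int = crw.LIBRARY_SIZE
    n_candidates: int = crw.N_CANDIDATES
    extent: tuple[float, float] = STUDY_EXTENT_M
    overlap_target: float = OVERLAP_TARGET
    rsf_cell_size: float = 500.0
    rsf_smoothness: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hunting_units not in HUNTING_UNIT_LEVELS:
            raise ValueError(f"hunting_units must be one of {HUNTING_UNIT_LEVELS}")
        if not 0 <= self.loner_fraction < 1:
            raise ValueError("loner_fraction must be in [0, 1)")
        if any(d < 0 for d in self.densities):
            raise ValueError("densities must be non-negative")
        if self.month not in MONTHLY_PARAMS:
            raise ValueError(f"unknown month {self.month!r}")

    @property
    def movement_params(self) -> MovementParams:
        return MONTHLY_PARAMS[self.month]

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


@dataclass
class OccupancyCurve:
    """Mean occupancy vs pack density per grid size for one scenario."""

    labels: dict
    rows: pd.DataFrame  # grid_km2, density, mean_occupancy, sd_occupancy

    def to_frame(self) -> pd.DataFrame:
        df = self.rows.copy()
        for k, v in self.labels.items():
            df.insert(0, k, v)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible child random stream of a master seed."""
    ints = [
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) & 0xFFFFFFFF
        for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *ints]))


def loner_count(
    layout: TerritoryLayout | int,
    mean_pack_size: float = MEAN_PACK_SIZE,
    loner_fraction: float = LONER_FRACTION,
) -> int:
    """Number of lone wolves so loners form ``loner_fraction`` of the TOTAL
    population (pack wolves + loners): round(f/(1-f) * n_packs * pack_size)."""
    if not 0 <= loner_fraction < 1:
        raise ValueError("loner_fraction must be in [0, 1)")
    n_packs = layout if isinstance(layout, int) else len(layout)
    pack_wolves = n_packs * mean_pack_size
    return int(round(loner_fraction / (1.0 - loner_fraction) * pack_wolves))


def scenario_landscape(config: ScenarioConfig) -> LandscapeRaster:
    """Synthetic habitat-bias surface padded by the largest territory diameter."""
    positive = [d for d in config.densities if d > 0]
    if positive:
        max_area = territory_area_for_density(min(positive))
        pad = 2.0 * np.sqrt(max_area * 1e6 / np.pi)
    else:
        pad = 0.1 * config.extent[0]
    rng = substream(config.seed, "rsf")
    return generate_rsf_surface(
        config.extent, config.rsf_cell_size, config.rsf_smoothness, rng, pad=pad
    )


def draw_pack_paths(
    library: crw.PathLibrary,
    hunting_units: int,
    rng: np.random.Generator,
) -> list[crw.Path]:
    """Draw ``hunting_units`` paths per territory without replacement."""
    paths: list[crw.Path] = []
    for pack_id in sorted(library.paths):
        pool = library.paths[pack_id]
        if len(pool) < hunting_units:
            raise ValueError(
                f"library for pack {pack_id} has {len(pool)} paths; "
                f"need >= {hunting_units}"
            )
        idx = rng.choice(len(pool), size=hunting_units, replace=False)
        paths.extend(pool[i] for i in idx)
    return paths


def assemble_scenario(
    config: ScenarioConfig,
    density: float,
    library: crw.PathLibrary | None,
    rng: np.random.Generator,
    landscape: LandscapeRaster | None = None,
    loner_rng: np.random.Generator | None = None,
) -> list[crw.Path]:
    """Path set surveyed in one replicate: pack hunting-unit paths + loners."""
    paths: list[crw.Path] = []
    n_packs = 0
    if library is not None and library.paths:
        paths.extend(draw_pack_paths(library, config.hunting_units, rng))
        n_packs = len(library.paths)
    if config.loners_enabled:
        n_lone = loner_count(n_packs, config.mean_pack_size, config.loner_fraction)
        paths.extend(
            crw.simulate_loner_paths(
                config.extent,
                config.movement_params,
                n_lone,
                landscape,
                loner_rng if loner_rng is not None else rng,
                config.n_candidates,
            )
        )
    return paths


def assemble_cumulative(
    config: ScenarioConfig,
    library: crw.PathLibrary,
    rng: np.random.Generator,
) -> dict[int, list[crw.Path]]:
    """Nested hunting-unit path sets: the 1-unit draw is a prefix of the
    2-unit draw, which is a prefix of the 4-unit draw (for paired
    monotonicity checks)."""
    draws: dict[int, list[crw.Path]] = {hu: [] for hu in HUNTING_UNIT_LEVELS}
    for pack_id in sorted(library.paths):
        pool = library.paths[pack_id]
        idx = rng.choice(len(pool), size=max(HUNTING_UNIT_LEVELS), replace=False)
        for hu in HUNTING_UNIT_LEVELS:
            draws[hu].extend(pool[i] for i in idx[:hu])
    return draws


def build_library(
    config: ScenarioConfig,
    density: float,
    landscape: LandscapeRaster | None,
    library_size: int | None = None,
) -> tuple[TerritoryLayout, crw.PathLibrary | None]:
    """Territory layout and path library for one density (seed substreams)."""
    dkey = int(round(density * 10))
    layout = layout_territories(
        config.extent, density, config.overlap_target,
        substream(config.seed, "layout", dkey),
    )
    if not len(layout):
        return layout, None
    lib = crw.generate_path_library(
        layout,
        config.movement_params,
        landscape,
        library_size or config.library_size,
        substream(config.seed, "library", dkey, config.month),
        config.n_candidates,
    )
    return layout, lib


def _survey_density(
    config: ScenarioConfig,
    density: float,
    library: crw.PathLibrary | None,
    landscape: LandscapeRaster | None,
) -> list[dict]:
    dkey = int(round(density * 10))
    rows = []
    for area in config.grid_areas:
        grid = survey.build_grid(config.extent, area)
        gkey = int(area)
        pathsel_rng = substream(config.seed, "pathsel", dkey, gkey)
        loner_rng = substream(config.seed, "loners", dkey, gkey)
        cells_rng = substream(config.seed, "cells", dkey, gkey)

        def provider(_rng):
            return assemble_scenario(
                config, density, library, pathsel_rng, landscape, loner_rng
            )

        mean, sd, _ = survey.replicate_survey(
            provider, grid, config.survey_fraction, config.n_replicates, cells_rng
        )
        rows.append(
            {
                "grid_km2": area,
                "density": density,
                "mean_occupancy": mean,
                "sd_occupancy": sd,
            }
        )
    return rows


def run_curve(config: ScenarioConfig, landscape: LandscapeRaster | None = None) -> OccupancyCurve:
    """Occupancy-abundance curve for one scenario across grids and densities."""
    if landscape is None:
        landscape = scenario_landscape(config)
    rows: list[dict] = []
    for density in config.densities:
        _, lib = build_library(config, density, landscape)
        rows.extend(_survey_density(config, density, lib, landscape))
        logger.info("density %.1f done (%s)", density, config.month)
    df = pd.DataFrame(rows).sort_values(["grid_km2", "density"]).reset_index(drop=True)
    labels = {
        "month": config.month,
        "hunting_units": config.hunting_units,
        "loners": config.loners_enabled,
    }
    return OccupancyCurve(labels=labels, rows=df)


def enumerate_scenarios(
    months=("December", "February"),
    hunting_units=HUNTING_UNIT_LEVELS,
    loners=(False, True),
) -> list[dict]:
    """The scenario cross of the full experiment (labels only)."""
    return [
        {"month": m, "hunting_units": hu, "loners_enabled": lo}
        for m in months
        for hu in hunting_units
        for lo in loners
    ]


def run_full_experiment(base_config: ScenarioConfig) -> pd.DataFrame:
    """Tidy results for the full scenario cross.

    Layouts, habitat surface, path libraries, path selections and surveyed
    cells are shared across scenarios through the named substreams, so the
    month, cohesion and loner contrasts are paired. Libraries are built once
    per (density, month) and reused by every hunting-unit / loner scenario.
    """
    landscape = scenario_landscape(base_config)
    scenarios = enumerate_scenarios()
    frames = []
    for density in base_config.densities:
        libs: dict[str, crw.PathLibrary | None] = {}
        for sc in scenarios:
            config = base_config.with_(**sc)
            if config.month not in libs:
                _, libs[config.month] = build_library(config, density, landscape)
            rows = _survey_density(config, density, libs[config.month], landscape)
            df = pd.DataFrame(rows)
            df.insert(0, "loners", config.loners_enabled)
            df.insert(0, "hunting_units", config.hunting_units)
            df.insert(0, "month", config.month)
            frames.append(df)
        logger.info("density %.1f: all %d scenarios done", density, len(scenarios))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["month", "hunting_units", "loners", "grid_km2", "density"]
    ).reset_index(drop=True)


@dataclass
class StabilizationResult:
    """Running mean of occupancy over replicates (survey-effort adequacy)."""

    running_means: pd.DataFrame  # columns k, running_mean
    stabilized_k: int
    tolerance: float


def stabilization_check(
    config: ScenarioConfig,
    density: float,
    grid_area: float,
    max_replicates: int = 30,
    tolerance: float = 0.02,
    landscape: LandscapeRaster | None = None,
) -> StabilizationResult:
    """Running mean of occupancy over k = 1..max_replicates replicates and
    the smallest k within ``tolerance`` of the final mean."""
    if max_replicates < 2:
        raise ValueError("max_replicates must be >= 2")
    if landscape is None:
        landscape = scenario_landscape(config)
    _, lib = build_library(config, density, landscape)
    grid = survey.build_grid(config.extent, grid_area)
    dkey = int(round(density * 10))
    pathsel_rng = substream(config.seed, "pathsel", dkey, int(grid_area), "stab")
    loner_rng = substream(config.seed, "loners", dkey, int(grid_area), "stab")
    cells_rng = substream(config.seed, "cells", dkey, int(grid_area), "stab")

    def provider(_rng):
        return assemble_scenario(config, density, lib, pathsel_rng, landscape, loner_rng)

    _, _, results = survey.replicate_survey(
        provider, grid, config.survey_fraction, max_replicates, cells_rng
    )
    occ = np.array([r.occupancy for r in results])
    running = np.cumsum(occ) / np.arange(1, len(occ) + 1)
    final = running[-1]
    within = np.abs(running - final) < tolerance
    stabilized_k = int(np.argmax(within) + 1) if within.any() else len(running)
    df = pd.DataFrame({"k": np.arange(1, len(running) + 1), "running_mean": running})
    return StabilizationResult(df, stabilized_k, tolerance)
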