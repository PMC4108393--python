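"""Telemetry decomposition and movement statistics.

Steps are straight-line displacements between consecutive GPS fixes and
turning angles are changes in direction between consecutive steps; steps
above the 150 m threshold are "moving" (travel) steps. Month-specific
movement parameters fitted here feed the travel-path simulator, and the
path-characteristic statistics (total length, survey cells intersected,
linear-feature crossings) support validation of simulated against observed
paths by paired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, MultiPoint

from .crw import Path
from .landscape import GPSFixSeries, LineFeatureSet
from .params import MOVE_THRESHOLD_M, MovementParams, wrap_angle
from .survey import SurveyGrid, cell_intersections


@dataclass
class StepSeries:
    """Per-step records for one or more wolves.

    ``steps`` columns: wolf_id, length (m), turning_angle (deg in (-180, 180],
    NaN where undefined), moving (bool), month.
    """

    steps: pd.DataFrame

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def lengths(self) -> np.ndarray:
        return self.steps["length"].to_numpy()

    @property
    def moving(self) -> np.ndarray:
        return self.steps["moving"].to_numpy()

    def moving_lengths(self, month: str | None = None) -> np.ndarray:
        df = self.steps
        if month is not None:
            df = df[df["month"] == month]
        return df.loc[df["moving"], "length"].to_numpy()

    def to_csv(self, path) -> None:
        self.steps.to_csv(path, index=False)


def concat_steps(series: list[StepSeries]) -> StepSeries:
    return StepSeries(pd.concat([s.steps for s in series], ignore_index=True))


def compute_steps(series: GPSFixSeries) -> StepSeries:
    """Decompose a fix series into steps, turning angles and movement states.

    Steps spanning flagged gaps (fix interval off the nominal by > 10%) are
    excluded; a turning angle is undefined for the first step and for any
    step whose predecessor was excluded.
    """
    cols = ["wolf_id", "length", "turning_angle", "moving", "month"]
    if len(series) < 2:
        return StepSeries(pd.DataFrame(columns=cols))
    dx = np.diff(series.x)
    dy = np.diff(series.y)
    lengths = np.hypot(dx, dy)
    headings = np.degrees(np.arctan2(dy, dx))
    turns = np.full(len(lengths), np.nan)
    turns[1:] = wrap_angle(headings[1:] - headings[:-1])
    gap = series.gap_flags()
    # a step after an excluded step has no defined previous heading
    turns[1:][gap[:-1]] = np.nan
    months = (
        series.months[:-1]
        if series.months is not None
        else np.repeat("", len(lengths))
    )
    moving = lengths > MOVE_THRESHOLD_M
    prev_moving = np.concatenate([[False], moving[:-1]])
    df = pd.DataFrame(
        {
            "wolf_id": series.wolf_id,
            "length": lengths,
            "turning_angle": turns,
            "moving": moving,
            "prev_moving": prev_moving,
            "month": months,
        }
    )
    return StepSeries(df.loc[~gap].reset_index(drop=True))


def fit_movement_params(
    steps: StepSeries, month: str, min_moving_steps: int = 30
) -> MovementParams:
    """Fit month-specific movement parameters from classified steps.

    step_mean/step_sd are the natural-scale sample mean and SD of moving-step
    lengths; p_move is the fraction of the month's steps in the moving state;
    turn_mean/turn_sd are the circular mean and circular (angular) deviation
    of turning angles between successive travel moves (a moving step whose
    predecessor was also moving) — the change of direction after a bed- or
    kill-site stop carries no information about directional persistence;
    truncation bounds are the sample min/max of moving steps.
    """
    df = steps.steps
    sub = df[df["month"] == month] if month else df
    if sub.empty:
        raise ValueError(f"no steps for month {month!r}")
    mov = sub.loc[sub["moving"], "length"].to_numpy()
    if len(mov) < min_moving_steps:
        raise ValueError(
            f"only {len(mov)} moving steps in {month!r}; "
            f"need >= {min_moving_steps} for a stable fit"
        )
    travel = sub["moving"] & sub.get("prev_moving", True)
    angles = sub.loc[travel, "turning_angle"].dropna().to_numpy()
    if len(angles):
        turn_mean = float(stats.circmean(angles, high=180.0, low=-180.0))
        turn_sd = float(stats.circstd(angles, high=180.0, low=-180.0))
    else:  # pragma: no cover - needs >= 2 consecutive moving steps normally
        turn_mean, turn_sd = 0.0, 0.0
    return MovementParams(
        month=month,
        step_mean=float(mov.mean()),
        step_sd=float(mov.std(ddof=1)) if len(mov) > 1 else 0.0,
        turn_mean=turn_mean,
        turn_sd=max(turn_sd, 1e-9),  # keep validity for degenerate samples
        step_min=float(mov.min()),
        step_max=float(mov.max()),
        p_move=float(sub["moving"].mean()),
    )


def compare_monthly_steps(steps) -> pd.DataFrame:
    """Welch two-sample t-tests on moving-step lengths between month pairs.

    Accepts a StepSeries (month column used) or a mapping
    ``{month: moving-step lengths}``. Returns one row per unordered pair
    (month_a, month_b, t, p); empty with fewer than two months.
    """
    if isinstance(steps, StepSeries):
        by_month = {
            m: steps.moving_lengths(m)
            for m in pd.unique(steps.steps["month"])
        }
    else:
        by_month = {m: np.asarray(v, dtype=float) for m, v in steps.items()}
    months = [m for m, v in by_month.items() if len(v)]
    rows = []
    for i, a in enumerate(months):
        for b in months[i + 1:]:
            t, p = stats.ttest_ind(by_month[a], by_month[b], equal_var=False)
            rows.append({"month_a": a, "month_b": b, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows, columns=["month_a", "month_b", "t", "p"])


def compute_mcp_area(series: GPSFixSeries) -> float:
    """100% minimum-convex-polygon (convex hull) area of all fixes, km^2."""
    if len(series) < 3:
        raise ValueError("need >= 3 fixes for a convex polygon")
    hull = MultiPoint(np.column_stack([series.x, series.y])).convex_hull
    if hull.area == 0.0:
        warnings.warn("collinear fixes: MCP area is zero", stacklevel=2)
    return hull.area / 1e6


def movement_territory_correlation(
    mean_step_by_wolf, mcp_by_wolf
) -> tuple[float, float]:
    """Spearman rank correlation between per-wolf mean 2-h step length and
    winter MCP area (ties by average ranks)."""
    a = np.asarray(mean_step_by_wolf, dtype=float)
    b = np.asarray(mcp_by_wolf, dtype=float)
    if len(a) != len(b) or len(a) < 4:
        raise ValueError("need >= 4 paired values")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


@dataclass
class PathStats:
    """Characteristics of one 2-day travel path."""

    path_id: str
    total_length_km: float
    cells_intersected: dict[float, int] = field(default_factory=dict)
    river_crossings: int = 0
    road_pipeline_crossings: int = 0

    def as_row(self) -> dict:
        row = {
            "path_id": self.path_id,
            "path_length_km": self.total_length_km,
            "river_crossings": self.river_crossings,
            "road_pipeline_crossings": self.road_pipeline_crossings,
        }
        for area, n in sorted(self.cells_intersected.items()):
            row[f"cells_{int(area)}km2"] = n
        return row


def stats_to_frame(stats_list: list[PathStats]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in stats_list])


def _count_crossings(line: LineString, feature_lines: list[np.ndarray]) -> int:
    """Transversal intersection points between a path and polylines.

    Each intersection point counts once; a collinear overlap stretch counts
    as a single crossing.
    """
    n = 0
    for verts in feature_lines:
        inter = line.intersection(LineString(verts))
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        n += sum(1 for _ in geoms)
    return n


def path_characteristics(
    path: Path, grids: list[SurveyGrid], features: LineFeatureSet | None = None
) -> PathStats:
    """Total length, per-grid distinct cells intersected, and feature crossings."""
    if path.vertices.shape[0] < 2:
        raise ValueError("path needs >= 2 vertices")
    line = path.line()
    cells = {
        g.cell_area_km2: len(cell_intersections([path], g)) for g in grids
    }
    rivers = roads = 0
    if features is not None:
        rivers = _count_crossings(line, features.by_kind("river"))
        roads = _count_crossings(line, features.by_kind("road", "pipeline"))
    return PathStats(
        path_id=path.owner,
        total_length_km=path.total_length_km,
        cells_intersected=cells,
        river_crossings=rivers,
        road_pipeline_crossings=roads,
    )


def paired_path_comparison(
    stats_a: list[PathStats], stats_b: list[PathStats]
) -> pd.DataFrame:
    """Paired t-tests per path characteristic between two matched path sets.

    Rows: characteristic, mean_a, sd_a, mean_b, sd_b, t, p. Lists must be
    matched pairwise (same length, paths paired by start location).
    """
    if len(stats_a) != len(stats_b):
        raise ValueError("path lists must be matched pairwise (equal length)")
    fa = stats_to_frame(stats_a).drop(columns="path_id")
    fb = stats_to_frame(stats_b).drop(columns="path_id")
    rows = []
    for col in fa.columns:
        a = fa[col].to_numpy(dtype=float)
        b = fb[col].to_numpy(dtype=float)
        diffs = a - b
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        rows.append(
            {
                "characteristic": col,
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1),
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def path_validation_harness(
    params: MovementParams,
    grids: list[SurveyGrid],
    features: LineFeatureSet | None,
    territory=None,
    landscape=None,
    n_paths: int = 22,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulated-vs-simulated path comparison, paired by start location.

    Mirrors the validation design that compares observed and simulated 2-day
    paths: two independent sets of ``n_paths`` paths are simulated from the
    same parameters and shared start locations, their characteristics
    computed, and paired t-tests run per characteristic. With identical
    generating parameters every comparison should usually be non-significant.
    """
    from .crw import simulate_path
    from .territories import Territory

    rng = np.random.default_rng(rng)
    if territory is None:
        # starts spread over the central region of the smallest grid extent
        extent = grids[0].extent if grids else (120_000.0, 120_000.0)
        starts = rng.uniform([0, 0], extent, size=(n_paths, 2))
    else:
        from .crw import _uniform_point_in_disc

        starts = np.array(
            [_uniform_point_in_disc(territory, rng) for _ in range(n_paths)]
        )
    sets = []
    for tag in ("a", "b"):
        stats_list = []
        for k in range(n_paths):
            p = simulate_path(
                territory, params, landscape, rng=rng, start=starts[k]
            )
            p.owner = f"{tag}{k}"
            stats_list.append(path_characteristics(p, grids, features))
        sets.append(stats_list)
    return paired_path_comparison(sets[0], sets[1])
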