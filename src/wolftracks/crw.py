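"""Two-state, habitat-biased correlated random walk for wolf travel paths.

Each 2-h step is either "moving" (log-normal step length truncated to the
observed support, wrapped-normal turning angle added to the previous travel
bearing) or "not moving" (sub-threshold displacement standing in for bed- and
kill-site steps). Habitat bias follows the candidate-step construction: at
each moving step several candidate steps are drawn and one is selected with
probability proportional to the habitat weight at its endpoint. Pack paths
are confined to their territory circle; lone-wolf paths are unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm
from shapely.geometry import LineString

from .landscape import LandscapeRaster
from .params import MovementParams, wrap_angle
from .territories import Territory, TerritoryLayout

logger = logging.getLogger(__name__)

#: Number of candidate steps scored by habitat weight at each moving step.
N_CANDIDATES = 20

#: Steps in a 2-day travel path at 2-h fixes.
STEPS_2DAY = 24

#: Bounded boundary-reflection retries before a path is rejected outright.
MAX_STEP_RETRIES = 10

#: Default library size: simulated travel paths per territory per month.
LIBRARY_SIZE = 1000


class PathRejected(RuntimeError):
    """A path could not be kept inside its territory within the retry budget."""


@dataclass
class Path:
    """One simulated travel path: vertices at 2-h step boundaries."""

    owner: str
    vertices: np.ndarray  # (n_steps + 1, 2) metres
    moving: np.ndarray  # (n_steps,) bool
    month: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.moving = np.asarray(self.moving, dtype=bool)
        if self.vertices.shape[0] != self.moving.shape[0] + 1:
            raise ValueError("need one more vertex than steps")

    @property
    def n_steps(self) -> int:
        return len(self.moving)

    @property
    def step_lengths(self) -> np.ndarray:
        return np.hypot(*np.diff(self.vertices, axis=0).T)

    @property
    def total_length_m(self) -> float:
        return float(self.step_lengths.sum())

    @property
    def total_length_km(self) -> float:
        return self.total_length_m / 1000.0

    def line(self) -> LineString:
        return LineString(self.vertices)

    def to_frame(self) -> pd.DataFrame:
        states = np.concatenate([["start"], np.where(self.moving, "moving", "not_moving")])
        return pd.DataFrame(
            {
                "path_id": self.owner,
                "step": np.arange(self.vertices.shape[0]),
                "x_m": self.vertices[:, 0],
                "y_m": self.vertices[:, 1],
                "state": states,
            }
        )


@dataclass
class PathLibrary:
    """Per-territory collections of simulated travel paths for one month."""

    month: str
    paths: dict[int, list[Path]] = field(default_factory=dict)

    @property
    def n_paths(self) -> int:
        return sum(len(v) for v in self.paths.values())

    def __getitem__(self, pack_id: int) -> list[Path]:
        return self.paths[pack_id]


def paths_to_csv(paths: list[Path], out) -> None:
    pd.concat([p.to_frame() for p in paths], ignore_index=True).to_csv(out, index=False)


def paths_to_geojson(paths: list[Path], out) -> None:
    import json

    feats = [
        {
            "type": "Feature",
            "properties": {"owner": p.owner, "month": p.month},
            "geometry": {"type": "LineString", "coordinates": p.vertices.tolist()},
        }
        for p in paths
    ]
    with open(out, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _sample_moving_lengths(params: MovementParams, rng, size: int) -> np.ndarray:
    """Truncated log-normal moving-step lengths via inverse-CDF sampling."""
    mu, sigma = params.lognormal_params()
    lo = norm.cdf((np.log(params.move_threshold) - mu) / sigma)
    hi = 1.0 if params.step_max is None else norm.cdf(
        (np.log(params.step_max) - mu) / sigma
    )
    u = lo + (hi - lo) * rng.random(size)
    return np.exp(mu + sigma * ndtri(u))


def draw_step(
    prev_bearing: float | None,
    params: MovementParams,
    rng: np.random.Generator,
) -> tuple[str, float, float]:
    """Draw one unbiased step: (state, length in m, absolute bearing in deg).

    Moving steps turn relative to ``prev_bearing`` (uniform heading if the
    walk has no travel history yet); not-moving steps take a uniform heading
    and a sub-threshold displacement.
    """
    if rng.random() < params.p_move:
        length = float(_sample_moving_lengths(params, rng, 1)[0])
        if prev_bearing is None:
            bearing = float(rng.uniform(-180.0, 180.0))
        else:
            turn = rng.normal(params.turn_mean, params.turn_sd)
            bearing = wrap_angle(prev_bearing + turn)
        return "moving", length, bearing
    length = float(rng.uniform(0.0, params.move_threshold))
    bearing = float(rng.uniform(-180.0, 180.0))
    return "not_moving", length, bearing


def _uniform_point_in_disc(territory: Territory, rng) -> np.ndarray:
    cx, cy = territory.centre
    r = territory.radius * np.sqrt(rng.random())
    ang = rng.uniform(0, 2 * np.pi)
    return np.array([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def _candidate_scores(
    endpoints: np.ndarray,
    landscape: LandscapeRaster | None,
    territory: Territory | None,
) -> np.ndarray:
    if landscape is None:
        scores = np.ones(endpoints.shape[0])
    else:
        scores = np.asarray(
            landscape.value_at(endpoints[:, 0], endpoints[:, 1]), dtype=float
        )
    if territory is not None:
        scores = np.where(
            territory.contains(endpoints[:, 0], endpoints[:, 1]), scores, 0.0
        )
    return scores


def _simulate_path_once(
    territory: Territory | None,
    params: MovementParams,
    landscape: LandscapeRaster | None,
    n_steps: int,
    rng: np.random.Generator,
    n_candidates: int,
    start: np.ndarray,
    state_transitions: tuple[float, float] | None,
) -> Path:
    pos = start.copy()
    vertices = np.empty((n_steps + 1, 2))
    vertices[0] = pos
    moving_flags = np.empty(n_steps, dtype=bool)
    travel_bearing: float | None = None
    state_moving = None  # used only for the Markov option

    for i in range(n_steps):
        if state_transitions is None or state_moving is None:
            state_moving = rng.random() < params.p_move
        else:
            p_mm, p_nm = state_transitions
            state_moving = rng.random() < (p_mm if state_moving else p_nm)
        moving_flags[i] = state_moving

        if state_moving:
            bearing_ref = travel_bearing
            chosen = None
            for _ in range(MAX_STEP_RETRIES):
                lengths = _sample_moving_lengths(params, rng, n_candidates)
                if bearing_ref is None:
                    bearings = rng.uniform(-180.0, 180.0, n_candidates)
                else:
                    turns = rng.normal(params.turn_mean, params.turn_sd, n_candidates)
                    bearings = wrap_angle(bearing_ref + turns)
                rad = np.radians(bearings)
                endpoints = pos + np.column_stack(
                    [lengths * np.cos(rad), lengths * np.sin(rad)]
                )
                scores = _candidate_scores(endpoints, landscape, territory)
                total = scores.sum()
                if total > 0:
                    if n_candidates == 1:
                        idx = 0
                    else:
                        idx = int(
                            np.searchsorted(
                                np.cumsum(scores) / total, rng.random(), side="right"
                            )
                        )
                        idx = min(idx, n_candidates - 1)
                    chosen = (endpoints[idx], float(bearings[idx]))
                    break
                # all candidates left the territory: reflect toward its centre
                cx, cy = territory.centre
                bearing_ref = float(
                    np.degrees(np.arctan2(cy - pos[1], cx - pos[0]))
                )
            if chosen is None:
                raise PathRejected(
                    f"confinement failure at step {i} after {MAX_STEP_RETRIES} retries"
                )
            pos, travel_bearing = chosen
        else:
            for _ in range(MAX_STEP_RETRIES + 1):
                length = rng.uniform(0.0, params.move_threshold)
                heading = np.radians(rng.uniform(-180.0, 180.0))
                cand = pos + length * np.array([np.cos(heading), np.sin(heading)])
                if territory is None or territory.contains(cand[0], cand[1]):
                    break
            else:  # pragma: no cover - centre-pointing fallback always succeeds
                cx, cy = territory.centre
                heading = np.arctan2(cy - pos[1], cx - pos[0])
                cand = pos + 1.0 * np.array([np.cos(heading), np.sin(heading)])
            pos = cand
        vertices[i + 1] = pos

    return Path(owner="", vertices=vertices, moving=moving_flags, month=params.month)


def simulate_path(
    territory: Territory | None,
    params: MovementParams,
    landscape: LandscapeRaster | None,
    n_steps: int = STEPS_2DAY,
    rng: np.random.Generator | int | None = None,
    n_candidates: int = N_CANDIDATES,
    start: np.ndarray | None = None,
    state_transitions: tuple[float, float] | None = None,
    max_path_attempts: int = 100,
) -> Path:
    """Simulate one travel path, resimulating on confinement failure.

    With ``territory`` None the walk is unconstrained (lone wolves,
    ground-truth telemetry); with ``landscape`` None or ``n_candidates`` 1
    the habitat bias vanishes and the walk reduces to a plain correlated
    random walk. ``state_transitions`` optionally replaces the independent
    Bernoulli state process with a first-order Markov chain
    (p_move_given_moving, p_move_given_not_moving).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(rng)
    for attempt in range(max_path_attempts):
        if start is not None:
            start_pos = np.asarray(start, dtype=float)
        elif territory is not None:
            start_pos = _uniform_point_in_disc(territory, rng)
        else:
            start_pos = np.zeros(2)
        try:
            return _simulate_path_once(
                territory, params, landscape, n_steps, rng,
                n_candidates, start_pos, state_transitions,
            )
        except PathRejected as exc:
            logger.info("resimulating path (attempt %d): %s", attempt + 1, exc)
    raise PathRejected(
        f"failed to simulate a confined path in {max_path_attempts} attempts"
    )


def generate_path_library(
    layout: TerritoryLayout,
    params: MovementParams,
    landscape: LandscapeRaster | None,
    n_paths: int = LIBRARY_SIZE,
    rng: np.random.Generator | int | None = None,
    n_candidates: int = N_CANDIDATES,
) -> PathLibrary:
    """Simulate ``n_paths`` 2-day paths inside every territory of a layout."""
    if not len(layout):
        raise ValueError("layout has no territories")
    rng = np.random.default_rng(rng)
    lib = PathLibrary(month=params.month)
    for terr in layout.territories:
        paths = []
        for k in range(n_paths):
            p = simulate_path(
                terr, params, landscape, STEPS_2DAY, rng, n_candidates
            )
            p.owner = f"pack{terr.pack_id}_path{k}"
            paths.append(p)
        lib.paths[terr.pack_id] = paths
    return lib


def simulate_loner_paths(
    extent: tuple[float, float],
    params: MovementParams,
    n_loners: int,
    landscape: LandscapeRaster | None,
    rng: np.random.Generator | int | None = None,
    n_candidates: int = N_CANDIDATES,
) -> list[Path]:
    """Unconstrained 2-day paths starting uniformly within the extent."""
    rng = np.random.default_rng(rng)
    out = []
    for k in range(int(n_loners)):
        start = rng.uniform([0, 0], extent)
        p = simulate_path(
            None, params, landscape, STEPS_2DAY, rng, n_candidates, start=start
        )
        p.owner = f"loner{k}"
        out.append(p)
    return out


def expected_path_length_m(params: MovementParams, n_steps: int = STEPS_2DAY) -> float:
    """Expected total path length: moving and not-moving contributions."""
    not_moving_mean = params.move_threshold / 2.0
    return n_steps * (
        params.p_move * params.step_mean + (1 - params.p_move) * not_moving_mean
    )
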