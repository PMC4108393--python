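"""Synthetic landscape inputs: habitat-quality rasters, linear features, telemetry.

The habitat surface plays the role of a resource-selection-function (RSF)
weight w(x, y) in (0, 1] used to bias simulated movement; its empirical form
is not modelled, only its role as a smooth spatial preference weight. Linear
features (roads, pipelines, rivers) support path-crossing statistics, and the
telemetry generator provides ground-truth GPS fix series for
parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .params import MovementParams

LINE_FEATURE_KINDS = ("road", "pipeline", "river")

#: Floor of the rescaled habitat surface; avoids zero-weight traps.
RSF_FLOOR = 0.05


@dataclass
class LandscapeRaster:
    """Regular grid of habitat-quality weights in (0, 1].

    Row 0 is the southernmost row; values[i, j] covers the square
    [origin_x + j*cell, origin_x + (j+1)*cell) x [origin_y + i*cell, ...).
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.values.min() <= 0 or self.values.max() > 1:
            raise ValueError("habitat values must lie in (0, 1]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def value_at(self, x, y):
        """Habitat weight at planar coordinates (vectorised).

        Coordinates beyond the raster edge clamp to the nearest edge cell, so
        unconstrained paths that stray past the padded extent still score.
        """
        col = np.clip(
            ((np.asarray(x) - self.origin_x) // self.cell_size).astype(int),
            0, self.n_cols - 1,
        )
        row = np.clip(
            ((np.asarray(y) - self.origin_y) // self.cell_size).astype(int),
            0, self.n_rows - 1,
        )
        return self.values[row, col]

    def to_csv(self, path) -> None:
        rows, cols = np.indices(self.values.shape)
        pd.DataFrame(
            {"row": rows.ravel(), "col": cols.ravel(), "value": self.values.ravel()}
        ).to_csv(path, index=False)

    def to_tiff(self, path) -> None:
        """Write a single-band float TIFF plus a JSON georeference sidecar."""
        import tifffile

        tifffile.imwrite(path, self.values.astype(np.float32))
        sidecar = {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_size": self.cell_size,
            "crs": "local planar metres",
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh)


@dataclass
class LineFeatureSet:
    """Linear landscape features: (kind, polyline) pairs in planar metres."""

    features: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        checked = []
        for kind, verts in self.features:
            if kind not in LINE_FEATURE_KINDS:
                raise ValueError(f"unknown feature kind {kind!r}")
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 2 or verts.shape[1] != 2:
                raise ValueError("polylines need >= 2 planar vertices")
            checked.append((kind, verts))
        self.features = checked

    def by_kind(self, *kinds: str) -> list[np.ndarray]:
        return [v for k, v in self.features if k in kinds]

    def to_geojson(self, path) -> None:
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"kind": kind},
                    "geometry": {
                        "type": "LineString",
                        "coordinates": verts.tolist(),
                    },
                }
                for kind, verts in self.features
            ],
        }
        with open(path, "w") as fh:
            json.dump(fc, fh)


@dataclass
class GPSFixSeries:
    """Ordered GPS fixes for one wolf: timestamps in hours, coordinates in m."""

    wolf_id: str
    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    nominal_interval: float = 2.0
    months: np.ndarray | None = None  # optional per-fix calendar month label

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.timestamps) == len(self.x) == len(self.y)):
            raise ValueError("timestamps, x, y must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.months is not None:
            self.months = np.asarray(self.months, dtype=object)
            if len(self.months) != len(self.timestamps):
                raise ValueError("months must match the number of fixes")

    def __len__(self) -> int:
        return len(self.timestamps)

    def gap_flags(self) -> np.ndarray:
        """True for intervals deviating > 10% from the nominal fix interval."""
        dt = np.diff(self.timestamps)
        return np.abs(dt - self.nominal_interval) > 0.1 * self.nominal_interval

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "wolf_id": self.wolf_id,
                "timestamp_h": self.timestamps,
                "x_m": self.x,
                "y_m": self.y,
            }
        )
        if self.months is not None:
            df["month"] = self.months
        return df


def telemetry_to_csv(series: list[GPSFixSeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, index=False
    )


def telemetry_from_csv(path) -> list[GPSFixSeries]:
    df = pd.read_csv(path)
    out = []
    for wolf_id, grp in df.groupby("wolf_id", sort=False):
        grp = grp.sort_values("timestamp_h")
        out.append(
            GPSFixSeries(
                wolf_id=str(wolf_id),
                timestamps=grp["timestamp_h"].to_numpy(),
                x=grp["x_m"].to_numpy(),
                y=grp["y_m"].to_numpy(),
                months=grp["month"].to_numpy() if "month" in grp else None,
            )
        )
    return out


def generate_rsf_surface(
    extent: tuple[float, float],
    cell_size: float,
    smoothness: float,
    seed: int | np.random.Generator,
    pad: float = 0.0,
) -> LandscapeRaster:
    """Smooth random habitat-quality surface with values in (RSF_FLOOR, 1].

    White noise is smoothed with a Gaussian kernel of standard deviation
    ``smoothness`` (the correlation length, metres), z-scored against the
    filter's exact output standard deviation (impulse response on the same
    grid, so boundary handling is accounted for), and mapped through the
    normal CDF into (RSF_FLOOR, 1]. This keeps the marginal habitat-weight
    distribution stable across smoothness choices: at realistic correlation
    lengths the surface spans nearly the full range, while a correlation
    length on the order of the extent degenerates to a near-constant surface
    rather than having residual micro-noise stretched to full range.
    ``pad`` extends the raster beyond the extent on every side so territory
    and loner movement past the study boundary still has defined weights.
    """
    from scipy.stats import norm

    width, height = extent
    if width <= 0 or height <= 0:
        raise ValueError(f"extent must be positive, got {extent}")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if smoothness < cell_size:
        raise ValueError("smoothness must be at least one cell")
    rng = np.random.default_rng(seed)
    n_cols = int(np.ceil((width + 2 * pad) / cell_size))
    n_rows = int(np.ceil((height + 2 * pad) / cell_size))
    sigma = smoothness / cell_size
    noise = rng.standard_normal((n_rows, n_cols))
    smooth = gaussian_filter(noise, sigma=sigma, mode="reflect")
    impulse = np.zeros((n_rows, n_cols))
    impulse[n_rows // 2, n_cols // 2] = 1.0
    kernel = gaussian_filter(impulse, sigma=sigma, mode="reflect")
    sd = float(np.sqrt((kernel**2).sum()))
    u = norm.cdf(smooth / sd)
    vals = np.clip(RSF_FLOOR + (1.0 - RSF_FLOOR) * u, RSF_FLOOR, 1.0)
    return LandscapeRaster(
        origin_x=-pad, origin_y=-pad, cell_size=cell_size, values=vals
    )


def generate_line_features(
    extent: tuple[float, float],
    n_per_kind: dict[str, int] | int,
    seed: int | np.random.Generator,
) -> LineFeatureSet:
    """Random linear features spanning the extent.

    Roads and pipelines are near-straight transects with slight jitter;
    rivers meander (sinusoidal drift plus noise, many vertices).
    """
    width, height = extent
    rng = np.random.default_rng(seed)
    if isinstance(n_per_kind, int):
        n_per_kind = {k: n_per_kind for k in LINE_FEATURE_KINDS}
    feats: list[tuple[str, np.ndarray]] = []
    for kind in LINE_FEATURE_KINDS:
        for _ in range(int(n_per_kind.get(kind, 0))):
            horizontal = rng.random() < 0.5
            span = width if horizontal else height
            offset = rng.uniform(0, height if horizontal else width)
            if kind == "river":
                t = np.linspace(0.0, span, 60)
                amp = rng.uniform(0.02, 0.08) * span
                phase = rng.uniform(0, 2 * np.pi)
                cross = (
                    offset
                    + amp * np.sin(2 * np.pi * t / span * rng.uniform(1, 3) + phase)
                    + rng.normal(0, 0.005 * span, t.size)
                )
            else:
                t = np.linspace(0.0, span, 5)
                cross = offset + rng.normal(0, 0.01 * span, t.size)
            verts = np.column_stack([t, cross] if horizontal else [cross, t])
            feats.append((kind, verts))
    return LineFeatureSet(features=feats)


def generate_synthetic_telemetry(
    params: MovementParams,
    n_wolves: int,
    n_days: int,
    seed: int | np.random.Generator,
) -> list[GPSFixSeries]:
    """Ground-truth GPS fix series from the movement model on flat habitat.

    Each wolf is an unconstrained 2-state correlated random walk sampled at
    the nominal fix interval for ``n_days`` days; the generating parameters
    are known exactly, so fitted movement statistics can be checked against
    them.
    """
    from .crw import simulate_path

    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    rng = np.random.default_rng(seed)
    steps_per_day = int(round(24.0 / params.step_interval))
    n_steps = steps_per_day * n_days
    out = []
    for w in range(n_wolves):
        path = simulate_path(
            territory=None, params=params, landscape=None, n_steps=n_steps, rng=rng
        )
        ts = np.arange(n_steps + 1) * params.step_interval
        out.append(
            GPSFixSeries(
                wolf_id=f"wolf_{w:02d}",
                timestamps=ts,
                x=path.vertices[:, 0],
                y=path.vertices[:, 1],
                nominal_interval=params.step_interval,
                months=np.repeat(params.month, n_steps + 1),
            )
        )
    return out
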