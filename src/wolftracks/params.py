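"""Winter wolf movement parameters.

Month-specific step-length and turning-angle statistics from 2-h GPS fixes,
together with the moving-state probability and the 150 m movement threshold
that separates travel steps from bed-/kill-site steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.stats import norm

#: Displacement (m) below which a 2-h step is classified as "not moving".
MOVE_THRESHOLD_M = 150.0

#: Nominal GPS fix interval in hours.
STEP_INTERVAL_H = 2.0

#: Marginal probability that a wolf is in the moving state during a 2-h step.
P_MOVE_DEFAULT = 0.57


@dataclass(frozen=True)
class MovementParams:
    """Movement statistics for one calendar month of winter telemetry.

    step_mean / step_sd are the natural-scale mean and SD (m) of moving-step
    lengths; moving steps are modelled as a log-normal truncated to
    [move_threshold, step_max]. turn_mean / turn_sd (degrees) parameterise a
    wrapped-normal turning-angle distribution, counter-clockwise positive.
    """

    month: str
    step_mean: float
    step_sd: float
    turn_mean: float
    turn_sd: float
    step_min: float = MOVE_THRESHOLD_M
    step_max: float | None = None
    p_move: float = P_MOVE_DEFAULT
    step_interval: float = STEP_INTERVAL_H
    move_threshold: float = MOVE_THRESHOLD_M

    def __post_init__(self) -> None:
        if not self.step_mean > self.move_threshold:
            raise ValueError(
                f"step_mean ({self.step_mean}) must exceed the movement "
                f"threshold ({self.move_threshold})"
            )
        if not 0.0 <= self.p_move <= 1.0:
            raise ValueError(f"p_move must be in [0, 1], got {self.p_move}")
        if not self.turn_sd > 0:
            raise ValueError("turn_sd must be positive")

    def with_(self, **kwargs) -> "MovementParams":
        return replace(self, **kwargs)

    def lognormal_params(self) -> tuple[float, float]:
        """(meanlog, sdlog) of the moving-step length distribution.

        Calibrated so the log-normal *truncated* to
        [move_threshold, step_max] reproduces step_mean and step_sd on the
        natural scale.
        """
        return _calibrated_lognormal(
            self.step_mean, self.step_sd, self.move_threshold, self.step_max
        )


def moment_matched_lognormal(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (meanlog, sdlog) for an untruncated log-normal."""
    sdlog2 = np.log1p((sd / mean) ** 2)
    meanlog = np.log(mean) - sdlog2 / 2.0
    return float(meanlog), float(np.sqrt(sdlog2))


def truncated_lognormal_moments(
    mu: float, sigma: float, lower: float, upper: float | None
) -> tuple[float, float]:
    """Mean and SD of a log-normal(mu, sigma) truncated to [lower, upper]."""
    la = (np.log(lower) - mu) / sigma
    lb = np.inf if upper is None else (np.log(upper) - mu) / sigma
    z = norm.cdf(lb) - norm.cdf(la)
    if z <= 0:
        raise ValueError("empty truncation interval")
    m1 = np.exp(mu + sigma**2 / 2) * (norm.cdf(lb - sigma) - norm.cdf(la - sigma)) / z
    m2 = (
        np.exp(2 * mu + 2 * sigma**2)
        * (norm.cdf(lb - 2 * sigma) - norm.cdf(la - 2 * sigma))
        / z
    )
    var = m2 - m1**2
    return float(m1), float(np.sqrt(max(var, 0.0)))


@lru_cache(maxsize=64)
def _calibrated_lognormal(
    mean: float, sd: float, lower: float, upper: float | None
) -> tuple[float, float]:
    """(meanlog, sdlog) whose truncation to [lower, upper] has the given moments.

    Starts from the untruncated method-of-moments solution and root-finds on
    (meanlog, log sdlog). Without an upper bound the truncation at 150 m is
    negligible and the start point is already the answer to ~1e-6.
    """
    mu0, sig0 = moment_matched_lognormal(mean, sd)
    if upper is None:
        return mu0, sig0

    def resid(theta):
        mu, logsig = theta
        m, s = truncated_lognormal_moments(mu, np.exp(logsig), lower, upper)
        return [m - mean, s - sd]

    sol = optimize.root(resid, [mu0, np.log(sig0)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"log-normal calibration failed: {sol.message}")
    mu, logsig = sol.x
    return float(mu), float(np.exp(logsig))


# Monthly presets (2-h fixes, Dec-Feb winters 2006-2008, northeastern Alberta).
# December and February span the full range of winter movement rates and are
# the two months used for path simulation; truncation bounds are the observed
# minima/maxima of moving steps in those months.
DECEMBER = MovementParams(
    month="December", step_mean=3013.0, step_sd=2657.0,
    turn_mean=-2.46, turn_sd=103.85, step_min=162.0, step_max=12283.0,
)
FEBRUARY = MovementParams(
    month="February", step_mean=1488.0, step_sd=1606.0,
    turn_mean=0.48, turn_sd=105.12, step_min=151.0, step_max=11843.0,
)
JANUARY = MovementParams(
    month="January", step_mean=2118.0, step_sd=2159.0,
    turn_mean=2.56, turn_sd=108.17,
)
WINTER = MovementParams(
    month="Dec-Feb", step_mean=1928.0, step_sd=2074.0,
    turn_mean=0.10, turn_sd=105.12,
)

MONTHLY_PARAMS: dict[str, MovementParams] = {
    "December": DECEMBER,
    "January": JANUARY,
    "February": FEBRUARY,
    "Dec-Feb": WINTER,
}


def wrap_angle(angle):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return float(w) if np.isscalar(angle) else w
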