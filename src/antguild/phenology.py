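"""Annually periodic phenology curves.

Foraging effort of each ant species and seasonal food production are both
represented as non-negative, annually periodic functions of day of year,
known only at a handful of measurement days (monthly for foraging, 17
roughly even time points for the resource curve).  Values between knots are
obtained by linear interpolation; the curve wraps around at the end of the
year.  Foraging curves are max-normalized, i.e. expressed as a fraction of
the species' maximal observed effort.

The module also provides the transformations used by the climate-change
scenarios: seasonal shifts (earlier springs / later falls), temperature-
driven rescaling via a thermal performance curve, and absolute food
supplementation at the resource knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "MONTH_START",
    "PhenologyCurve",
    "TemperatureSeries",
    "ThermalResponse",
    "interpolate",
    "normalize",
    "shift_phenology",
    "apply_warming",
    "supplement_resource",
]

#: Non-leap calendar: day 0 is Jan 1.
DAYS_PER_YEAR = 365.0

#: First day-of-year of each month, Jan..Dec (non-leap year).
MONTH_START = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334])
MONTH_LENGTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def periodic_interp(query, days, values, period=DAYS_PER_YEAR):
    """Linear interpolation of a periodic tabulated function.

    ``days`` must be strictly increasing within one period; the segment from
    the last knot back to the first (through the year boundary) is part of
    the curve.  ``values`` may be negative (used for temperature series).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size == 0:
        raise ValueError("cannot interpolate an empty curve")
    if days.size == 1:
        return np.full_like(np.asarray(query, dtype=float), values[0])
    # extend one knot on each side so np.interp sees the wrap-around segment
    x = np.concatenate(([days[-1] - period], days, [days[0] + period]))
    y = np.concatenate(([values[-1]], values, [values[0]]))
    q = np.mod(np.asarray(query, dtype=float), period)
    return np.interp(q, x, y)


@dataclass(frozen=True)
class PhenologyCurve:
    """Annually periodic, piecewise-linear, non-negative activity curve.

    Parameters
    ----------
    days
        Day-of-year knot positions in ``[0, period)``, strictly increasing.
    values
        Non-negative values at the knots (fractions of a seasonal maximum
        for normalized curves).
    period
        Year length in days (365 by default).
    """

    days: np.ndarray
    values: np.ndarray
    period: float = DAYS_PER_YEAR

    def __post_init__(self):
        days = np.atleast_1d(np.asarray(self.days, dtype=float))
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if days.size != values.size:
            raise ValueError("days and values must have equal length")
        if days.size == 0:
            raise ValueError("phenology curve needs at least one knot")
        if np.any(np.diff(days) <= 0):
            raise ValueError("day points must be strictly increasing")
        if days[0] < 0 or days[-1] >= self.period:
            raise ValueError("day points must lie in [0, period)")
        if np.any(values < 0):
            raise ValueError("phenology values must be non-negative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)

    def __call__(self, day):
        return interpolate(self, day)

    @property
    def n_knots(self) -> int:
        return self.days.size

    def daily(self, step: float = 1.0) -> np.ndarray:
        """Values sampled on the integer-day grid ``0, step, 2*step, ...``."""
        grid = np.arange(0.0, self.period, step)
        return interpolate(self, grid)

    def integral(self) -> float:
        """Integral of the curve over one full period (trapezoid, exact for
        a piecewise-linear periodic function sampled at its knots)."""
        x = np.concatenate((self.days, [self.days[0] + self.period]))
        y = np.concatenate((self.values, [self.values[0]]))
        return float(np.trapezoid(y, x))

    def with_values(self, values) -> "PhenologyCurve":
        return replace(self, values=np.asarray(values, dtype=float))


def interpolate(curve: PhenologyCurve, day):
    """Piecewise-linear periodic interpolation; exact at the knots."""
    return periodic_interp(day, curve.days, curve.values, curve.period)


def normalize(curve: PhenologyCurve) -> PhenologyCurve:
    """Rescale so the maximal knot value is exactly 1.

    Raises ``ValueError`` on an all-zero curve, where the operation is
    undefined.
    """
    peak = float(np.max(curve.values))
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero curve")
    return curve.with_values(curve.values / peak)


@dataclass(frozen=True)
class TemperatureSeries:
    """Monthly mean temperatures (deg C), interpolated to a daily series.

    Monthly means are anchored at mid-month and joined by periodic linear
    interpolation, giving a continuous daily temperature course.
    """

    monthly: np.ndarray
    period: float = DAYS_PER_YEAR

    def __post_init__(self):
        monthly = np.asarray(self.monthly, dtype=float)
        if monthly.shape != (12,):
            raise ValueError("a temperature series needs exactly 12 monthly means")
        object.__setattr__(self, "monthly", monthly)

    def __call__(self, day):
        mid = MONTH_START + MONTH_LENGTH / 2.0
        return periodic_interp(day, mid, self.monthly, self.period)

    def daily(self) -> np.ndarray:
        return self(np.arange(0.0, self.period))


@dataclass(frozen=True)
class ThermalResponse:
    """Gaussian thermal performance curve for foraging propensity.

    ``response(T) = exp(-0.5 ((T - t_opt)/width)^2)``, a non-negative
    relative propensity with maximum 1 at the thermal optimum.  These
    fixture curves are synthetic stand-ins for unpublished per-species
    foraging--temperature data and are fully user-replaceable.
    """

    t_opt: float
    width: float
    name: str = ""

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("thermal response width must be positive")

    def __call__(self, temperature):
        z = (np.asarray(temperature, dtype=float) - self.t_opt) / self.width
        return np.exp(-0.5 * z * z)


# --- seasonal-shift machinery -------------------------------------------------

_SPRING_START = float(MONTH_START[2])   # Mar 1
_SPRING_END = float(MONTH_START[7] - 1)  # Jul 31
_FALL_START = float(MONTH_START[8])     # Sep 1
_FALL_END = float(MONTH_START[1] - 1)   # Jan 31


def _spring_weight(days: np.ndarray) -> np.ndarray:
    """Cross-fade weight: 1 on Mar 1..Jul 31, 0 on Sep 1..Jan 31, linear
    across the buffer months August and February."""
    d = np.mod(np.asarray(days, dtype=float), DAYS_PER_YEAR)
    w = np.zeros_like(d)
    spring = (d >= _SPRING_START) & (d <= _SPRING_END)
    w[spring] = 1.0
    feb = (d > _FALL_END) & (d < _SPRING_START)
    w[feb] = (d[feb] - _FALL_END) / (_SPRING_START - _FALL_END)
    aug = (d > _SPRING_END) & (d < _FALL_START)
    w[aug] = (_FALL_START - d[aug]) / (_FALL_START - _SPRING_END)
    return w


def shift_phenology(
    curve: PhenologyCurve,
    weeks: int,
    *,
    renormalize: bool = True,
    allow_any_weeks: bool = False,
) -> PhenologyCurve:
    """Extend the summer: spring activity earlier, fall activity later.

    For output day ``d`` in the spring window (Mar 1 - Jul 31) the value is
    the input at ``d + 7*weeks`` (activity that used to happen later now
    happens earlier); in the fall window (Sep 1 - Jan 31) it is the input at
    ``d - 7*weeks``.  August and February blend the two shifted branches
    with linear cross-fade weights so the result is continuous.  The result
    is sampled daily and re-normalized by default.

    ``weeks`` outside 1..4 (the scenario range) is rejected unless
    ``allow_any_weeks`` is set.
    """
    weeks = int(weeks)
    if not allow_any_weeks and not 1 <= weeks <= 4:
        raise ValueError("shift must be between 1 and 4 weeks (override with allow_any_weeks)")
    grid = np.arange(0.0, curve.period)
    delta = 7.0 * weeks
    spring_branch = interpolate(curve, grid + delta)
    fall_branch = interpolate(curve, grid - delta)
    w = _spring_weight(grid)
    values = w * spring_branch + (1.0 - w) * fall_branch
    out = PhenologyCurve(grid, values, curve.period)
    return normalize(out) if renormalize else out


def apply_warming(
    curve: PhenologyCurve,
    response: ThermalResponse,
    temps: TemperatureSeries,
    delta_t: float,
    *,
    zero_floor: float = 1e-6,
    clip: bool = True,
) -> PhenologyCurve:
    """Rescale a foraging curve for a uniform temperature increase.

    The daily value is multiplied by ``response(T(d)+delta_t)/response(T(d))``:
    foraging goes up on days the warmed temperature is closer to the species'
    thermal optimum and down on days it overshoots.  Where the baseline
    response is effectively zero (< ``zero_floor``) the warmed response is
    used directly as an absolute propensity, which avoids the 0/0 at the
    edges of the foraging season.  Values are clipped to [0, 1] (a fraction
    of maximal effort cannot exceed 1) and the curve is *not* re-normalized,
    so warming can genuinely depress a species' seasonal activity.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be non-negative")
    grid = np.arange(0.0, curve.period)
    base = interpolate(curve, grid)
    t0 = temps(grid)
    resp0 = response(t0)
    resp1 = response(t0 + delta_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(resp0 < zero_floor, resp1, base * resp1 / np.maximum(resp0, zero_floor))
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return PhenologyCurve(grid, scaled, curve.period)


def supplement_resource(curve: PhenologyCurve, supplement) -> PhenologyCurve:
    """Add absolute food supplementation at the resource curve's knots.

    The supplement vector must match the knot count; entries are added to
    the knot values with linear interpolation between knots as usual.  The
    result is deliberately not re-normalized: supplementation is an
    absolute addition to food availability.
    """
    supplement = np.asarray(supplement, dtype=float)
    if supplement.shape != curve.values.shape:
        raise ValueError(
            f"supplement length {supplement.size} != knot count {curve.n_knots}"
        )
    if np.any(supplement < 0):
        raise ValueError("supplement entries must be non-negative")
    return curve.with_values(curve.values + supplement)
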