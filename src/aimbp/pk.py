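"""Rudimentary pharmacokinetics: dose records -> plasma-concentration curves.

A single-compartment description adequate for charted ICU medication data:
an IV bolus of ``D`` mg mixes into the volume of distribution ``V`` (liters)
producing a peak plasma concentration ``D / V`` (reported in ng/mL), reached
via a linear ramp over the drug's peak-onset time, and eliminated afterwards
by first-order decay with the drug's half-life.  Continuous infusions are
represented as a superposition of per-grid-step micro-boluses, which
converges to the continuous-infusion solution as the grid step shrinks.

Time is measured in minutes throughout; concentrations in ng/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DrugSpec",
    "DoseEvent",
    "ConcentrationSeries",
    "NoActivePeriodError",
    "bolus_concentration",
    "infusion_concentration",
    "concentration_from_events",
    "mean_active_concentration",
]

#: mg -> ng and L -> mL; the single place the unit conversion lives.
_MG_PER_L_TO_NG_PER_ML = 1e6 / 1e3


class NoActivePeriodError(ValueError):
    """Raised when a concentration series has no strictly positive values."""


@dataclass(frozen=True)
class DrugSpec:
    """Pharmacokinetic constants for one drug.

    Parameters
    ----------
    name : str
        Drug identifier (e.g. ``"labetalol"``).
    half_life : float
        Elimination half-life in minutes (> 0).
    volume_of_distribution : float
        Central volume of distribution in liters (> 0).
    time_to_peak : float
        Minutes from administration to peak plasma concentration (>= 0).
    route : {"bolus", "infusion"}
        Default administration route.
    """

    name: str
    half_life: float
    volume_of_distribution: float
    time_to_peak: float = 0.0
    route: str = "bolus"

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError(f"half_life must be > 0, got {self.half_life}")
        if self.volume_of_distribution <= 0:
            raise ValueError(
                f"volume_of_distribution must be > 0, got {self.volume_of_distribution}"
            )
        if self.time_to_peak < 0:
            raise ValueError(f"time_to_peak must be >= 0, got {self.time_to_peak}")
        if self.route not in ("bolus", "infusion"):
            raise ValueError(f"route must be 'bolus' or 'infusion', got {self.route!r}")


@dataclass(frozen=True)
class DoseEvent:
    """One medication-administration record.

    Exactly one of ``amount`` (mg, for a bolus) or ``rate`` (mg/hr, for an
    infusion-rate change effective until the next rate event) must be set.
    """

    time: float
    drug: str
    amount: float | None = None
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if (self.amount is None) == (self.rate is None):
            raise ValueError("exactly one of amount (bolus) or rate (infusion) required")
        if self.amount is not None and self.amount <= 0:
            raise ValueError(f"bolus amount must be > 0 mg, got {self.amount}")
        if self.rate is not None and self.rate < 0:
            raise ValueError(f"infusion rate must be >= 0 mg/hr, got {self.rate}")

    @property
    def is_bolus(self) -> bool:
        return self.amount is not None


@dataclass
class ConcentrationSeries:
    """Plasma concentration of one drug over a uniform time grid (ng/mL)."""

    drug: str
    time: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_grid(self.time)
        if self.values.shape != self.time.shape:
            raise ValueError("values and time must have the same shape")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.0


def _check_grid(time_grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("time grid must be a non-empty 1-D array")
    if grid.size > 1:
        steps = np.diff(grid)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("time grid must be uniformly spaced and increasing")
    return grid


def unit_bolus_profile(tau: np.ndarray, spec: DrugSpec) -> np.ndarray:
    """Concentration response (ng/mL) to a 1 mg bolus at elapsed time ``tau`` min.

    Zero before the dose, linear ramp to the peak over ``time_to_peak``, then
    exponential half-life decay.
    """
    tau = np.asarray(tau, dtype=float)
    peak = _MG_PER_L_TO_NG_PER_ML / spec.volume_of_distribution
    out = np.zeros_like(tau)
    if spec.time_to_peak > 0:
        ramp = (tau >= 0) & (tau < spec.time_to_peak)
        out[ramp] = peak * tau[ramp] / spec.time_to_peak
    post = tau >= spec.time_to_peak
    out[post] = peak * np.exp2(-(tau[post] - spec.time_to_peak) / spec.half_life)
    return out


def bolus_concentration(
    dose: float,
    spec: DrugSpec,
    time_grid: Sequence[float] | np.ndarray,
    dose_time: float = 0.0,
) -> ConcentrationSeries:
    """Concentration curve of a single IV bolus of ``dose`` mg given at ``dose_time``."""
    if dose <= 0:
        raise ValueError(f"dose must be > 0 mg, got {dose}")
    grid = _check_grid(np.asarray(time_grid))
    values = dose * unit_bolus_profile(grid - dose_time, spec)
    return ConcentrationSeries(spec.name, grid, values)


def infusion_concentration(
    rate_events: Iterable[DoseEvent],
    spec: DrugSpec,
    time_grid: Sequence[float] | np.ndarray,
) -> ConcentrationSeries:
    """Concentration from a piecewise-constant infusion-rate schedule.

    Each grid interval running at rate ``rho`` mg/hr contributes a micro-bolus
    of ``rho * dt / 60`` mg at the interval start, handled exactly as
    :func:`bolus_concentration`; the curve is the superposition of all
    micro-boluses.  Halving the grid step refines the approximation.
    """
    grid = _check_grid(np.asarray(time_grid))
    events = sorted(rate_events, key=lambda e: e.time)
    for ev in events:
        if ev.is_bolus:
            raise ValueError("infusion_concentration expects rate events only")
    if grid.size < 2 or not events:
        return ConcentrationSeries(spec.name, grid, np.zeros_like(grid))
    dt = grid[1] - grid[0]
    # rate in effect at each grid point (from the most recent event)
    ev_times = np.array([e.time for e in events])
    ev_rates = np.array([e.rate for e in events])
    idx = np.searchsorted(ev_times, grid, side="right") - 1
    rates = np.where(idx >= 0, ev_rates[np.clip(idx, 0, None)], 0.0)

    values = np.zeros_like(grid)
    unit = unit_bolus_profile(grid - grid[0], spec)
    for k, rho in enumerate(rates):
        if rho > 0:
            values[k:] += (rho * dt / 60.0) * unit[: grid.size - k]
    return ConcentrationSeries(spec.name, grid, values)


def concentration_from_events(
    events: Iterable[DoseEvent],
    spec: DrugSpec,
    time_grid: Sequence[float] | np.ndarray,
) -> ConcentrationSeries:
    """Combined curve for one drug from mixed bolus and infusion-rate events."""
    grid = _check_grid(np.asarray(time_grid))
    values = np.zeros_like(grid)
    boluses = [e for e in events if e.drug == spec.name and e.is_bolus]
    rate_events = [e for e in events if e.drug == spec.name and not e.is_bolus]
    for ev in boluses:
        values += bolus_concentration(ev.amount, spec, grid, dose_time=ev.time).values
    if rate_events:
        values += infusion_concentration(rate_events, spec, grid).values
    return ConcentrationSeries(spec.name, grid, values)


def mean_active_concentration(c: ConcentrationSeries) -> float:
    """Arithmetic mean concentration over grid points where the drug is present.

    The "active period" is the set of grid points with strictly positive
    concentration; an all-zero series has no active period and raises
    :class:`NoActivePeriodError`.
    """
    active = c.values > 0
    if not np.any(active):
        raise NoActivePeriodError(f"{c.drug}: concentration is zero everywhere")
    return float(np.mean(c.values[active]))
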