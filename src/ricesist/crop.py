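"""Reduced daily rice LAI dynamics with a multiplicative stress factor.

The simulator is a deliberately compact stand-in for a full crop growth
model: daily gross assimilation is radiation-use efficiency times the
radiation intercepted by the canopy (Beer's law), a stress factor
``f`` in [0, 1] scales that assimilation (1 = healthy, 0 = fully
stressed), and leaf area declines at a fixed relative rate once
accumulated thermal time passes a senescence threshold.  The interface
is pluggable so a full physiological model can be substituted without
touching anything downstream.

The season is fixed: daily steps over DOY 160-255, sampled at 5-day
intervals into a canonical 20-point series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, MissingForcingError
from .meteo import AngstromCoefficients, DEFAULT_ANGSTROM, MeteoDay, sunshine_to_radiation

#: First and last simulated day of year (inclusive).
SEASON_START, SEASON_END = 160, 255
#: The canonical 20 sampling days: 160, 165, ..., 255.
CANONICAL_DOYS = tuple(range(SEASON_START, SEASON_END + 1, 5))


@dataclass(frozen=True)
class CropParams:
    """Tunable constants of the reduced LAI model.

    ``rue`` (assimilate per MJ of intercepted radiation) and
    ``leaf_conversion`` (LAI increment per unit assimilate) only enter
    as a product; they are kept separate so either can be swapped for
    literature values.  Defaults are configuration chosen so the
    unstressed curve peaks near LAI 6 in mid-season under subtropical
    summer forcing.
    """

    lai_init: float = 0.3
    rue: float = 0.55
    k_ext: float = 0.6
    leaf_conversion: float = 0.020
    t_base: float = 8.0
    tt_senescence: float = 900.0
    senescence_rate: float = 0.045

    def __post_init__(self) -> None:
        for name in (
            "lai_init",
            "rue",
            "k_ext",
            "leaf_conversion",
            "t_base",
            "tt_senescence",
            "senescence_rate",
        ):
            if getattr(self, name) <= 0 and name != "t_base":
                raise InvalidInputError(f"CropParams.{name} must be positive")
        if not 0 < self.k_ext <= 1.5:
            raise InvalidInputError("k_ext must lie in (0, 1.5]")


@dataclass(frozen=True)
class LAISeries:
    """One pixel-year of LAI sampled on the canonical 5-day grid."""

    year: int
    doys: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if tuple(self.doys) != CANONICAL_DOYS:
            raise InvalidInputError(
                "LAISeries must be sampled on the canonical DOY grid "
                f"{CANONICAL_DOYS[0]}..{CANONICAL_DOYS[-1]} step 5"
            )
        if values.shape != (len(CANONICAL_DOYS),):
            raise InvalidInputError("LAISeries needs exactly 20 samples")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise InvalidInputError("LAI values must be finite and non-negative")


@dataclass(frozen=True)
class ObservationSet:
    """Sparse (DOY, LAI) observations used for calibration."""

    doys: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.doys) == 0:
            raise InvalidInputError("ObservationSet must contain >= 1 observation")
        if len(self.doys) != len(self.values):
            raise InvalidInputError("doys and values must have equal length")
        for d in self.doys:
            if not SEASON_START <= d <= SEASON_END:
                raise InvalidInputError(
                    f"observation doy {d} outside [{SEASON_START}, {SEASON_END}]"
                )


@dataclass(frozen=True)
class PSOConfig:
    """Global-best particle swarm settings for the 1-D stress-factor fit."""

    n_particles: int = 20
    max_iterations: int = 100
    cost_threshold: float = 1e-8
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    seed: int = 0
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise InvalidInputError("n_particles must be >= 1")
        if self.max_iterations < 0:
            raise InvalidInputError("max_iterations must be >= 0")
        if self.bounds != (0.0, 1.0):
            raise InvalidInputError("stress-factor search bounds are fixed to [0, 1]")


@dataclass(frozen=True)
class CalibrationResult:
    f_hat: float
    cost_hat: float
    converged: bool
    trace: np.ndarray = field(repr=False)  # best cost per iteration


def ndvi_to_lai(ndvi):
    """Empirical exponential NDVI-to-LAI transfer: 0.361 * exp(3.69 * NDVI)."""
    arr = np.asarray(ndvi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("NDVI must be finite")
    out = 0.361 * np.exp(3.69 * arr)
    return float(out) if np.isscalar(ndvi) or arr.ndim == 0 else out


def _check_season_coverage(meteo: Sequence[MeteoDay]) -> list[MeteoDay]:
    by_doy = {d.doy: d for d in meteo}
    missing = [d for d in range(SEASON_START, SEASON_END + 1) if d not in by_doy]
    if missing:
        raise MissingForcingError(missing)
    return [by_doy[d] for d in range(SEASON_START, SEASON_END + 1)]


def daily_radiation(
    meteo: Sequence[MeteoDay], coeffs: AngstromCoefficients = DEFAULT_ANGSTROM
) -> np.ndarray:
    """Surface radiation (MJ m-2 d-1) for every day of the season window."""
    days = _check_season_coverage(meteo)
    return np.array([sunshine_to_radiation(d, coeffs).rs for d in days])


def simulate_lai_daily(
    params: CropParams,
    meteo: Sequence[MeteoDay],
    f,
    coeffs: AngstromCoefficients = DEFAULT_ANGSTROM,
) -> np.ndarray:
    """Daily LAI trajectory over DOY 160..255.

    ``f`` may be a scalar, a per-day vector of length 96, or a
    (96, n_pixels) array; the returned trajectory has shape (96,) or
    (96, n_pixels) accordingly.  The daily update is

        CVF_t  = rue * Rs_t * (1 - exp(-k_ext * LAI_t))
        LAI_{t+1} = LAI_t + leaf_conversion * f_t * CVF_t - sen_t * LAI_t

    with ``sen_t = senescence_rate`` once cumulative thermal time above
    ``t_base`` exceeds ``tt_senescence``, else 0; LAI is floored at 0.
    """
    days = _check_season_coverage(meteo)
    n_days = len(days)
    rs = np.array([sunshine_to_radiation(d, coeffs).rs for d in days])
    tmean = np.array([(d.tmax + d.tmin) / 2.0 for d in days])
    tt = np.cumsum(np.maximum(tmean - params.t_base, 0.0))
    senescing = tt > params.tt_senescence

    f_arr = np.asarray(f, dtype=float)
    if f_arr.ndim == 0:
        f_arr = np.full(n_days, float(f_arr))
    if f_arr.shape[0] != n_days:
        raise InvalidInputError(
            f"f curve must have one value per day ({n_days}), got {f_arr.shape}"
        )
    if np.any(f_arr < 0) or np.any(f_arr > 1):
        raise InvalidInputError("stress factor f must lie in [0, 1]")

    shape = (n_days,) if f_arr.ndim == 1 else (n_days, f_arr.shape[1])
    out = np.empty(shape, dtype=float)
    lai = np.broadcast_to(params.lai_init, shape[1:]).astype(float).copy()
    out[0] = lai
    for t in range(n_days - 1):
        cvf = params.rue * rs[t] * (1.0 - np.exp(-params.k_ext * lai))
        growth = params.leaf_conversion * f_arr[t] * cvf
        loss = params.senescence_rate * lai if senescing[t] else 0.0
        lai = np.maximum(lai + growth - loss, 0.0)
        out[t + 1] = lai
    return out


def sample_canonical(daily: np.ndarray, shift_steps: int = 0) -> np.ndarray:
    """Sample a daily trajectory at the canonical DOYs.

    ``shift_steps`` delays (positive) or advances (negative) phenology
    by whole 5-day steps: the value reported at DOY d is the trajectory
    at d - 5*shift_steps, clamped to the season window.
    """
    idx = np.clip(
        np.array(CANONICAL_DOYS) - SEASON_START - 5 * int(shift_steps),
        0,
        daily.shape[0] - 1,
    )
    return daily[idx]


def simulate_lai(
    params: CropParams,
    meteo: Sequence[MeteoDay],
    f: float,
    year: int = 0,
    coeffs: AngstromCoefficients = DEFAULT_ANGSTROM,
) -> LAISeries:
    """Simulate one pixel-year and sample it on the canonical grid."""
    daily = simulate_lai_daily(params, meteo, float(f), coeffs)
    return LAISeries(year=year, doys=CANONICAL_DOYS, values=sample_canonical(daily))


def cost_function(
    observed: ObservationSet, simulated: LAISeries, max_doy_gap: int = 2
) -> float:
    """Mean squared difference between observations and the simulation.

    Each observation is matched to the nearest simulated DOY; a gap
    larger than ``max_doy_gap`` days is an error rather than a silent
    extrapolation.
    """
    doys = np.asarray(simulated.doys)
    total = 0.0
    for d, v in zip(observed.doys, observed.values):
        j = int(np.argmin(np.abs(doys - d)))
        if abs(int(doys[j]) - d) > max_doy_gap:
            raise InvalidInputError(
                f"observation at doy {d} has no simulated sample within "
                f"{max_doy_gap} days"
            )
        total += (v - simulated.values[j]) ** 2
    return total / len(observed.doys)


def _cost_of_f(f, observed, params, meteo, coeffs=DEFAULT_ANGSTROM):
    sim = simulate_lai(params, meteo, float(f), coeffs=coeffs)
    return cost_function(observed, sim)


def grid_search_stress_factor(
    observed: ObservationSet,
    params: CropParams,
    meteo: Sequence[MeteoDay],
    n_points: int = 1001,
) -> tuple[float, float]:
    """Brute-force reference: minimize the cost on a uniform grid over [0, 1].

    The stress factor enters the daily update multiplicatively, so all
    grid candidates are simulated in one batched pass.
    """
    grid = np.linspace(0.0, 1.0, n_points)
    f_daily = np.broadcast_to(grid, (SEASON_END - SEASON_START + 1, n_points))
    daily = simulate_lai_daily(params, meteo, f_daily)
    sampled = sample_canonical(daily)  # (20, n_points)
    doys = np.asarray(CANONICAL_DOYS)
    costs = np.zeros(n_points)
    for d, v in zip(observed.doys, observed.values):
        j = int(np.argmin(np.abs(doys - d)))
        costs += (v - sampled[j]) ** 2
    costs /= len(observed.doys)
    best = int(np.argmin(costs))
    return float(grid[best]), float(costs[best])


def calibrate_stress_factor(
    observed: ObservationSet,
    params: CropParams,
    meteo: Sequence[MeteoDay],
    pso: PSOConfig = PSOConfig(),
) -> CalibrationResult:
    """Fit the season-constant stress factor by global-best particle swarm.

    The swarm minimizes the observation-vs-simulation mean squared
    error over f in [0, 1]; iteration stops at ``max_iterations`` or
    once the best cost drops below ``cost_threshold``.  Non-convergence
    is not an error: the best position found so far is returned with
    ``converged=False``.
    """
    rng = np.random.default_rng(pso.seed)
    lo, hi = pso.bounds
    pos = rng.uniform(lo, hi, pso.n_particles)
    vel = rng.uniform(-(hi - lo), hi - lo, pso.n_particles) * 0.1

    cost = np.array([_cost_of_f(p, observed, params, meteo) for p in pos])
    pbest, pbest_cost = pos.copy(), cost.copy()
    g = int(np.argmin(pbest_cost))
    gbest, gbest_cost = float(pbest[g]), float(pbest_cost[g])

    trace = [gbest_cost]
    converged = gbest_cost <= pso.cost_threshold
    for _ in range(pso.max_iterations):
        if converged:
            break
        r1 = rng.random(pso.n_particles)
        r2 = rng.random(pso.n_particles)
        vel = (
            pso.inertia * vel
            + pso.cognitive * r1 * (pbest - pos)
            + pso.social * r2 * (gbest - pos)
        )
        pos = np.clip(pos + vel, lo, hi)
        cost = np.array([_cost_of_f(p, observed, params, meteo) for p in pos])
        improved = cost < pbest_cost
        pbest[improved] = pos[improved]
        pbest_cost[improved] = cost[improved]
        g = int(np.argmin(pbest_cost))
        if pbest_cost[g] < gbest_cost:
            gbest, gbest_cost = float(pbest[g]), float(pbest_cost[g])
        trace.append(gbest_cost)
        converged = gbest_cost <= pso.cost_threshold

    return CalibrationResult(
        f_hat=gbest,
        cost_hat=gbest_cost,
        converged=converged,
        trace=np.asarray(trace),
    )


def with_params(params: CropParams, **overrides) -> CropParams:
    """Return a copy of ``params`` with selected fields replaced."""
    return replace(params, **overrides)
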