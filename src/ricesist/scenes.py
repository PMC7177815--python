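"""Synthetic two-year LAI scenes with known per-pixel stress truth.

The generator realizes the conceptual stress typology the index is
designed to separate:

* heavy-metal pixels sit in spatial blocks, each pixel carrying a latent
  contamination level that depresses assimilation identically in both
  years (chronic, season-long, inter-annually stable);
* abrupt (pest/disease) pixels are scattered, depressed only inside a
  short window of a single year;
* nutrition pixels form zones whose season-long severity is redrawn
  independently each year (chronic but inter-annually unstable);
* everything else is healthy.

Each pixel-year is produced by the daily crop simulator under the
pixel's stress curve, phenology-shifted by the year's transplanting
offset, with additive Gaussian observation noise floored at zero.
All randomness flows from one mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crop import (
    CANONICAL_DOYS,
    CropParams,
    SEASON_END,
    SEASON_START,
    sample_canonical,
    simulate_lai_daily,
)
from .errors import InvalidInputError
from .meteo import MeteoDay
from .raster import GeoRef, SceneStack

#: Truth-label codes.
CLASS_HEALTHY = 0
CLASS_HEAVY_METAL = 1
CLASS_ABRUPT = 2
CLASS_NUTRITION = 3
CLASS_NON_RICE = 255

CLASS_NAMES = {
    CLASS_HEALTHY: "healthy",
    CLASS_HEAVY_METAL: "heavy_metal",
    CLASS_ABRUPT: "abrupt",
    CLASS_NUTRITION: "nutrition",
    CLASS_NON_RICE: "non_rice",
}

_STRESS_KINDS = ("healthy", "heavy_metal", "abrupt", "nutrition")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of a synthetic scene pair.

    Severity defaults: heavy-metal latent level ~ U(0.3, 0.8) reducing
    the stress factor to f = 1 - 0.6*level; abrupt stress forces
    f = 0.4 inside a 20-day window of one year; nutrition severity
    ~ U(0.2, 0.6) i.i.d. per year through the same multiplicative
    effect, f = 1 - 0.6*severity, so the two chronic stressors look
    alike within a season and differ only in inter-annual stability.
    """

    rows: int = 100
    cols: int = 100
    seed: int = 0
    rice_fraction: float = 0.9
    years: tuple[int, int] = (2017, 2018)
    phenology_shift: tuple[int, int] = (0, 1)
    noise_sd: float = 0.15
    latitude_deg: float = 27.7
    n_heavy_metal_blocks: int = 3
    n_nutrition_zones: int = 2
    block_size_frac: tuple[float, float] = (0.10, 0.16)
    heavy_metal_level_range: tuple[float, float] = (0.3, 0.8)
    heavy_metal_effect: float = 0.6
    abrupt_fraction: float = 0.02
    abrupt_window: tuple[int, int] = (190, 210)
    abrupt_year_index: int = 0
    abrupt_f: float = 0.4
    nutrition_severity_range: tuple[float, float] = (0.2, 0.6)
    nutrition_effect: float = 0.6
    crop_params: CropParams = field(default_factory=CropParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.rice_fraction <= 1.0:
            raise InvalidInputError("rice_fraction must lie in (0, 1]")
        lo, hi = self.abrupt_window
        if not (SEASON_START <= lo <= hi <= SEASON_END):
            raise InvalidInputError("abrupt_window must lie within the season")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.abrupt_year_index not in (0, 1):
            raise InvalidInputError("abrupt_year_index must be 0 or 1")


@dataclass
class TruthLabels:
    """Ground truth co-registered with the generated scenes."""

    classes: np.ndarray  # uint8, CLASS_* codes
    contamination: np.ndarray  # latent level; 0 outside heavy metal, NaN non-rice


def synthetic_meteo(
    year: int, seed: int, latitude_deg: float = 27.7
) -> list[MeteoDay]:
    """Plausible subtropical summer weather for one season.

    A smooth seasonal cycle in temperature and sunshine with
    day-to-day noise; the year enters the seed so adjacent years are
    similar but not identical, like real forcing.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, year]))
    days = []
    for doy in range(SEASON_START, SEASON_END + 1):
        phase = (doy - 130) / 190.0 * np.pi
        tmax = 30.0 + 4.0 * np.sin(phase) + rng.normal(0.0, 1.2)
        tmin = tmax - 8.0 + rng.normal(0.0, 0.8)
        sun = float(np.clip(6.5 + 2.0 * np.sin(phase) + rng.normal(0.0, 2.0), 0.0, 12.5))
        days.append(
            MeteoDay(
                doy=doy,
                tmax=round(tmax, 2),
                tmin=round(min(tmin, tmax), 2),
                sunshine_hours=round(sun, 2),
                latitude_deg=latitude_deg,
            )
        )
    return days


def stress_profile(
    kind: str,
    year_index: int,
    config: ScenarioConfig,
    rng: np.random.Generator,
    level: float | None = None,
) -> np.ndarray:
    """Daily stress-factor curve (length 96) for one pixel-year.

    ``level`` pins the heavy-metal contamination level so the two years
    share it; for nutrition stress the severity is drawn from ``rng``
    at every call, giving inter-annually independent severities.
    """
    n_days = SEASON_END - SEASON_START + 1
    if kind == "healthy":
        return np.ones(n_days)
    if kind == "heavy_metal":
        if level is None:
            level = float(rng.uniform(*config.heavy_metal_level_range))
        return np.full(n_days, 1.0 - config.heavy_metal_effect * level)
    if kind == "nutrition":
        severity = float(rng.uniform(*config.nutrition_severity_range))
        return np.full(n_days, 1.0 - config.nutrition_effect * severity)
    if kind == "abrupt":
        f = np.ones(n_days)
        if year_index == config.abrupt_year_index:
            doys = np.arange(SEASON_START, SEASON_END + 1)
            lo, hi = config.abrupt_window
            f[(doys >= lo) & (doys <= hi)] = config.abrupt_f
        return f
    raise InvalidInputError(f"unknown stress kind {kind!r}; expected {_STRESS_KINDS}")


def _place_blocks(
    rng: np.random.Generator,
    classes: np.ndarray,
    rice: np.ndarray,
    n_blocks: int,
    size_frac: tuple[float, float],
    code: int,
) -> None:
    """Carve rectangular stress blocks into unclaimed rice area."""
    rows, cols = classes.shape
    base = min(rows, cols)
    for _ in range(n_blocks):
        for _attempt in range(50):
            h = max(2, int(rng.uniform(*size_frac) * base))
            w = max(2, int(rng.uniform(*size_frac) * base))
            r0 = int(rng.integers(0, max(rows - h, 1)))
            c0 = int(rng.integers(0, max(cols - w, 1)))
            region = (slice(r0, r0 + h), slice(c0, c0 + w))
            if np.all(classes[region][rice[region]] == CLASS_HEALTHY):
                sub = classes[region]
                sub[rice[region]] = code
                break


def generate_scene(
    config: ScenarioConfig,
) -> tuple[SceneStack, SceneStack, TruthLabels]:
    """Generate the two yearly scene stacks and their ground truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_level, rng_y0, rng_y1 = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    rows, cols = config.rows, config.cols

    rice = rng_layout.random((rows, cols)) < config.rice_fraction
    classes = np.full((rows, cols), CLASS_HEALTHY, dtype=np.uint8)
    classes[~rice] = CLASS_NON_RICE

    _place_blocks(
        rng_layout, classes, rice,
        config.n_heavy_metal_blocks, config.block_size_frac, CLASS_HEAVY_METAL,
    )
    _place_blocks(
        rng_layout, classes, rice,
        config.n_nutrition_zones, config.block_size_frac, CLASS_NUTRITION,
    )
    healthy = (classes == CLASS_HEALTHY)
    n_abrupt = int(round(config.abrupt_fraction * healthy.sum()))
    idx = np.flatnonzero(healthy.ravel())
    chosen = rng_layout.choice(idx, size=n_abrupt, replace=False)
    classes.ravel()[chosen] = CLASS_ABRUPT

    contamination = np.zeros((rows, cols))
    contamination[~rice] = np.nan
    hm = classes == CLASS_HEAVY_METAL
    contamination[hm] = rng_level.uniform(
        *config.heavy_metal_level_range, size=int(hm.sum())
    )

    truth = TruthLabels(classes=classes, contamination=contamination)

    stacks = []
    for year_index, (year, rng_year) in enumerate(
        zip(config.years, (rng_y0, rng_y1))
    ):
        meteo = synthetic_meteo(year, config.seed, config.latitude_deg)
        n_days = SEASON_END - SEASON_START + 1
        rice_idx = np.flatnonzero(rice.ravel())
        pix_classes = classes.ravel()[rice_idx]
        pix_level = contamination.ravel()[rice_idx]

        f_daily = np.ones((n_days, rice_idx.size))
        for kind, code in (
            ("heavy_metal", CLASS_HEAVY_METAL),
            ("nutrition", CLASS_NUTRITION),
            ("abrupt", CLASS_ABRUPT),
        ):
            sel = np.flatnonzero(pix_classes == code)
            for k in sel:
                f_daily[:, k] = stress_profile(
                    kind,
                    year_index,
                    config,
                    rng_year,
                    level=pix_level[k] if kind == "heavy_metal" else None,
                )

        daily = simulate_lai_daily(config.crop_params, meteo, f_daily)
        sampled = sample_canonical(daily, config.phenology_shift[year_index])
        if config.noise_sd > 0:
            sampled = sampled + rng_year.normal(0.0, config.noise_sd, sampled.shape)
        sampled = np.maximum(sampled, 0.0)

        lai = np.full((len(CANONICAL_DOYS), rows, cols), np.nan)
        lai.reshape(len(CANONICAL_DOYS), -1)[:, rice_idx] = sampled
        stacks.append(
            SceneStack(year=year, lai=lai, rice_mask=rice, georef=GeoRef())
        )
    return stacks[0], stacks[1], truth
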