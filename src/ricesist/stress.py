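"""Per-pixel stress level, temporal dissimilarity and temporal stability.

The stress level of a pixel-year is its DTW distance to an unstressed
reference simulation for that year; larger distance means the pixel's
canopy development deviated more from healthy growth.  Temporal
dissimilarity is the DTW distance between the pixel's own series in two
consecutive years; its min-max complement is temporal stability, high
for pixels whose (possibly depressed) trajectory repeats year after
year — the temporal fingerprint of chronic contamination as opposed to
one-off pest or disease outbreaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .crop import CANONICAL_DOYS, CropParams, LAISeries, simulate_lai
from .dtw import DTWConfig, dtw_distance_batch
from .errors import DegenerateRangeError, InvalidInputError
from .meteo import MeteoDay
from .raster import SceneStack


@dataclass
class StressSurfaces:
    """All per-pixel stress surfaces plus the extrema used to normalize them."""

    s_raw: dict[int, np.ndarray]
    s_norm: dict[int, np.ndarray]
    s_final: np.ndarray
    td: np.ndarray
    ts: np.ndarray
    extrema: dict[str, float] = field(default_factory=dict)


def normalize_minmax(
    raster: np.ndarray, mask: np.ndarray, degenerate_value: float = 0.0
) -> tuple[np.ndarray, float, float]:
    """Min-max rescale masked cells to [0, 1]; NaN outside the mask.

    A degenerate range (all masked values equal, including the
    single-pixel case) maps every masked cell to ``degenerate_value``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateRangeError("normalization mask selects no pixels")
    vals = np.asarray(raster, dtype=float)[mask]
    if not np.all(np.isfinite(vals)):
        raise InvalidInputError("masked values must be finite for normalization")
    vmin, vmax = float(vals.min()), float(vals.max())
    out = np.full(raster.shape, np.nan)
    if vmax > vmin:
        out[mask] = (np.asarray(raster, dtype=float)[mask] - vmin) / (vmax - vmin)
    else:
        out[mask] = degenerate_value
    return out, vmin, vmax


def reference_series(
    params: CropParams, meteo: Sequence[MeteoDay], year: int
) -> LAISeries:
    """No-stress (f = 1) simulation used as the healthy benchmark for a year."""
    return simulate_lai(params, meteo, 1.0, year=year)


def stress_level(
    stack: SceneStack, reference: LAISeries, config: DTWConfig = DTWConfig()
) -> np.ndarray:
    """Per rice pixel, DTW distance between its series and the reference."""
    if tuple(reference.doys) != tuple(stack.doys):
        raise InvalidInputError("stack and reference must share the DOY grid")
    series = stack.pixel_series()
    ref = np.broadcast_to(reference.values, series.shape)
    dist = dtw_distance_batch(ref, series, config)
    out = np.full(stack.shape, np.nan)
    out[stack.rice_mask] = dist
    return out


def combined_stress(
    s_norm_a: np.ndarray, s_norm_b: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Two-year mean of normalized stress levels."""
    if s_norm_a.shape != s_norm_b.shape or s_norm_a.shape != mask.shape:
        raise InvalidInputError("stress rasters and mask must be co-registered")
    out = np.full(s_norm_a.shape, np.nan)
    out[mask] = 0.5 * (s_norm_a[mask] + s_norm_b[mask])
    return out


def temporal_dissimilarity(
    stack_a: SceneStack, stack_b: SceneStack, config: DTWConfig = DTWConfig()
) -> np.ndarray:
    """Per rice pixel, DTW distance between its two yearly series."""
    if stack_a.shape != stack_b.shape or not np.array_equal(
        stack_a.rice_mask, stack_b.rice_mask
    ):
        raise InvalidInputError("yearly stacks must share grid and rice mask")
    dist = dtw_distance_batch(stack_a.pixel_series(), stack_b.pixel_series(), config)
    out = np.full(stack_a.shape, np.nan)
    out[stack_a.rice_mask] = dist
    return out


def temporal_stability(
    td: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """TS = 1 - minmax(TD); a constant TD field maps to TS = 1 everywhere."""
    norm, tdmin, tdmax = normalize_minmax(td, mask, degenerate_value=0.0)
    out = np.full(td.shape, np.nan)
    out[mask] = 1.0 - norm[mask]
    return out, tdmin, tdmax


def stress_surfaces(
    stack_a: SceneStack,
    stack_b: SceneStack,
    reference_a: LAISeries,
    reference_b: LAISeries,
    config: DTWConfig = DTWConfig(),
) -> StressSurfaces:
    """Compute every temporal surface for a two-year pair of scenes.

    Each year is normalized against its own extrema before the two-year
    averaging, so a year with generally poorer radiation does not
    dominate the combined stress level.
    """
    mask = stack_a.rice_mask
    s_a = stress_level(stack_a, reference_a, config)
    s_b = stress_level(stack_b, reference_b, config)
    sn_a, smin_a, smax_a = normalize_minmax(s_a, mask)
    sn_b, smin_b, smax_b = normalize_minmax(s_b, mask)
    s_final = combined_stress(sn_a, sn_b, mask)
    td = temporal_dissimilarity(stack_a, stack_b, config)
    ts, tdmin, tdmax = temporal_stability(td, mask)
    return StressSurfaces(
        s_raw={stack_a.year: s_a, stack_b.year: s_b},
        s_norm={stack_a.year: sn_a, stack_b.year: sn_b},
        s_final=s_final,
        td=td,
        ts=ts,
        extrema={
            f"smin_{stack_a.year}": smin_a,
            f"smax_{stack_a.year}": smax_a,
            f"smin_{stack_b.year}": smin_b,
            f"smax_{stack_b.year}": smax_b,
            "tdmin": tdmin,
            "tdmax": tdmax,
        },
    )
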