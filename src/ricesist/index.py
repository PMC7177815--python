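"""The composite stress index and its summaries.

The index is the geometric mean of three normalized factors — stress
level, temporal stability, and local spatial autocorrelation of
temporal stability — so it is high only where the canopy is depressed,
the depression repeats across years, and neighboring paddies behave
the same way: the joint signature of chronic heavy-metal contamination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedCorrelationError


def compute_sist(
    s_norm: np.ndarray, ts: np.ndarray, i_norm: np.ndarray
) -> np.ndarray:
    """SIST = (S_norm * TS * I_norm)^(1/3), NaN where any factor is NaN."""
    arrs = [np.asarray(a, dtype=float) for a in (s_norm, ts, i_norm)]
    if not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
        raise InvalidInputError("component rasters must be co-registered")
    for name, a in zip(("s_norm", "ts", "i_norm"), arrs):
        vals = a[np.isfinite(a)]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise InvalidInputError(f"{name} must lie in [0, 1] where defined")
    prod = arrs[0] * arrs[1] * arrs[2]
    return np.clip(prod, 0.0, 1.0) ** (1.0 / 3.0)


def zonal_summary(
    sist: np.ndarray, zones: np.ndarray, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-zone pixel count, mean, median, and exceedance fraction.

    Zones with no defined SIST pixel appear with count 0.  The
    exceedance threshold is configuration, not science; 0.5 by default.
    """
    sist = np.asarray(sist, dtype=float)
    zones = np.asarray(zones)
    if sist.shape != zones.shape:
        raise InvalidInputError("sist and zones must be co-registered")
    rows = []
    for z in np.unique(zones):
        vals = sist[(zones == z) & np.isfinite(sist)]
        rows.append(
            {
                "zone": z,
                "count": int(vals.size),
                "mean": float(vals.mean()) if vals.size else np.nan,
                "median": float(np.median(vals)) if vals.size else np.nan,
                "frac_above": float((vals > threshold).mean()) if vals.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    """Product-moment correlation between paired samples."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidInputError("x and y must be paired")
    if x.size < 3:
        raise InvalidInputError("need >= 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    return float(stats.pearsonr(x, y).statistic)
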