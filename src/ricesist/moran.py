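"""Local Moran's I of a masked raster with a 3x3 neighborhood.

The Anselin local statistic is computed per rice pixel with the field
mean and variance taken over all rice pixels; only rice neighbors
contribute.  Positive values flag spatial clustering (similar neighbors),
negative values local dispersion.  Chronically contaminated paddies show
up as positive-I clusters of high temporal stability, whereas one-off
stress events sit as negative-I outliers among stable neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import convolve

from .errors import InvalidInputError
from .stress import normalize_minmax

#: Cluster-label codes used in uint8 raster exports.
LABEL_NONE = 0
LABEL_HIGH_HIGH = 1
LABEL_LOW_LOW = 2
LABEL_HIGH_LOW = 3
LABEL_LOW_HIGH = 4
LABEL_NODATA = 255

_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)

WeightScheme = Literal["row", "binary"]


@dataclass
class LocalMoranSurfaces:
    i_raw: np.ndarray
    i_norm: np.ndarray
    labels: np.ndarray
    global_mean: float
    m2: float
    global_i: float
    extrema: dict[str, float] = field(default_factory=dict)


def _neighbor_sums(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3 sums of masked deviations and counts of masked neighbors.

    Edges use truncated neighborhoods: the convolution pads with zeros,
    which contribute nothing because non-rice cells are zeroed out.
    """
    z = np.where(mask, values, 0.0)
    nsum = convolve(z, _KERNEL, mode="constant", cval=0.0)
    ncount = convolve(mask.astype(float), _KERNEL, mode="constant", cval=0.0)
    return nsum, ncount


def local_morans_i(
    values: np.ndarray,
    mask: np.ndarray,
    scheme: WeightScheme = "row",
) -> LocalMoranSurfaces:
    """Local Moran's I, its min-max normalization, and cluster labels.

    ``scheme='row'`` divides each pixel's neighbor sum by its rice
    neighbor count (weights 1/k), making the statistic comparable
    between edge and interior pixels; ``'binary'`` uses unit weights.
    Pixels with no rice neighbor get NaN I and the nodata label.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise InvalidInputError("values and mask must be co-registered")
    if scheme not in ("row", "binary"):
        raise InvalidInputError("scheme must be 'row' or 'binary'")
    n = int(mask.sum())
    if n < 2:
        raise InvalidInputError("need >= 2 rice pixels for spatial autocorrelation")

    x = values[mask]
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("masked values must be finite")
    xbar = float(x.mean())
    m2 = float(((x - xbar) ** 2).mean())

    dev = values - xbar
    nsum, ncount = _neighbor_sums(dev, mask)
    has_nbr = mask & (ncount > 0)

    i_raw = np.full(values.shape, np.nan)
    if not has_nbr.any():
        # every rice pixel is isolated: no spatial structure to measure
        labels = cluster_labels(values, i_raw, mask, xbar)
        return LocalMoranSurfaces(
            i_raw=i_raw,
            i_norm=np.full(values.shape, np.nan),
            labels=labels,
            global_mean=xbar,
            m2=m2,
            global_i=float("nan"),
            extrema={"imin": float("nan"), "imax": float("nan")},
        )
    if m2 == 0.0:
        warnings.warn(
            "zero variance across rice pixels; local Moran's I defined as 0",
            stacklevel=2,
        )
        i_raw[has_nbr] = 0.0
        global_i = 0.0
    else:
        lag = np.zeros_like(dev)
        if scheme == "row":
            lag[has_nbr] = nsum[has_nbr] / ncount[has_nbr]
        else:
            lag[has_nbr] = nsum[has_nbr]
        i_raw[has_nbr] = dev[has_nbr] * lag[has_nbr] / m2
        global_i = global_morans_i(values, mask, scheme)

    i_norm, imin, imax = normalize_minmax(i_raw, has_nbr, degenerate_value=0.0)
    labels = cluster_labels(values, i_raw, mask, xbar)
    return LocalMoranSurfaces(
        i_raw=i_raw,
        i_norm=i_norm,
        labels=labels,
        global_mean=xbar,
        m2=m2,
        global_i=global_i,
        extrema={"imin": imin, "imax": imax},
    )


def global_morans_i(
    values: np.ndarray, mask: np.ndarray, scheme: WeightScheme = "row"
) -> float:
    """Global Moran's I, (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    x = values[mask]
    xbar = float(x.mean())
    denom = float(((x - xbar) ** 2).sum())
    if denom == 0.0:
        return 0.0
    dev = values - xbar
    nsum, ncount = _neighbor_sums(dev, mask)
    has_nbr = mask & (ncount > 0)
    if not has_nbr.any():
        return float("nan")
    if scheme == "row":
        num = float((dev[has_nbr] * nsum[has_nbr] / ncount[has_nbr]).sum())
        s0 = float(has_nbr.sum())  # each row of weights sums to 1
    else:
        num = float((dev[has_nbr] * nsum[has_nbr]).sum())
        s0 = float(ncount[mask].sum())
    n = int(mask.sum())
    return n / s0 * num / denom


def normalize_morans(
    i_raw: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Min-max normalization of the local statistic (shared contract)."""
    defined = np.asarray(mask, dtype=bool) & np.isfinite(i_raw)
    return normalize_minmax(i_raw, defined, degenerate_value=0.0)


def cluster_labels(
    values: np.ndarray,
    i_raw: np.ndarray,
    mask: np.ndarray,
    global_mean: float,
) -> np.ndarray:
    """Label each rice pixel by its local-association quadrant.

    High-high: positive I with an above-mean value (clustered high);
    low-low: positive I below the mean; negative I splits into
    high-low / low-high by the sign of the pixel's deviation.  Exact
    zeros (I or deviation) and isolated pixels map to 'none'/nodata.
    """
    labels = np.full(values.shape, LABEL_NODATA, dtype=np.uint8)
    mask = np.asarray(mask, dtype=bool)
    defined = mask & np.isfinite(i_raw)
    labels[defined] = LABEL_NONE
    dev = values - global_mean
    pos = defined & (i_raw > 0)
    neg = defined & (i_raw < 0)
    labels[pos & (dev > 0)] = LABEL_HIGH_HIGH
    labels[pos & (dev < 0)] = LABEL_LOW_LOW
    labels[neg & (dev > 0)] = LABEL_HIGH_LOW
    labels[neg & (dev < 0)] = LABEL_LOW_HIGH
    return labels
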