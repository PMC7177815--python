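"""Post-classification cleanup and confusion-matrix accuracy statistics.

The classifier producing the land-cover map is external; this module
removes speckle (tiny 4-connected rice objects) from its output and
derives overall accuracy, Cohen's kappa and per-class user's/producer's
accuracy from a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidInputError

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are the mapped class, columns the reference."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise InvalidInputError("counts must be square and match labels")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise InvalidInputError("counts must be non-negative integers")
        if counts.sum() == 0:
            raise InvalidInputError("confusion matrix must contain samples")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise InvalidInputError(
                "confusion CSV must have identical row and column labels"
            )
        return cls(labels=tuple(df.columns), counts=df.to_numpy(dtype=np.int64))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.labels, columns=self.labels).to_csv(path)


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """Overall accuracy, Cohen's kappa and per-class accuracies.

    Proportions are returned on the 0-1 scale.  A class with a zero row
    (column) total has no defined user's (producer's) accuracy and is
    reported as None rather than 0.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    po = diag.sum() / total
    pe = float((row * col).sum()) / total**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    users = {
        lab: (float(diag[i] / row[i]) if row[i] > 0 else None)
        for i, lab in enumerate(cm.labels)
    }
    producers = {
        lab: (float(diag[i] / col[i]) if col[i] > 0 else None)
        for i, lab in enumerate(cm.labels)
    }
    return {
        "overall_accuracy": float(po),
        "kappa": float(kappa),
        "users_accuracy": users,
        "producers_accuracy": producers,
    }


def remove_small_objects(
    raster: np.ndarray,
    target_class: int,
    min_pixels: int = 4,
    connectivity: int = 4,
) -> np.ndarray:
    """Remove 4-connected target-class objects smaller than ``min_pixels``.

    Removed pixels take the mode of the non-target classes touching the
    object (8-neighborhood); ties — and objects entirely surrounded by
    target pixels — fall back to the class of the nearest non-target
    pixel in Euclidean distance.  Objects of exactly ``min_pixels`` are
    kept.  The operation is idempotent.
    """
    raster = np.asarray(raster)
    if connectivity not in (4, 8):
        raise InvalidInputError("connectivity must be 4 or 8")
    struct = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    is_target = raster == target_class
    lab, n_obj = ndimage.label(is_target, structure=struct)
    if n_obj == 0:
        return raster.copy()
    sizes = np.bincount(lab.ravel())

    out = raster.copy()
    non_target = ~is_target
    # nearest non-target pixel for every cell, for the tie/enclosed fallback
    _, (near_r, near_c) = ndimage.distance_transform_edt(
        is_target, return_indices=True
    )
    for obj in range(1, n_obj + 1):
        if sizes[obj] >= min_pixels:
            continue
        component = lab == obj
        ring = ndimage.binary_dilation(component, structure=_STRUCT_8) & non_target
        fill = None
        if ring.any():
            classes, counts = np.unique(raster[ring], return_counts=True)
            winners = classes[counts == counts.max()]
            if winners.size == 1:
                fill = int(winners[0])
        if fill is None:
            rr, cc = np.nonzero(component)
            dists = (near_r[rr, cc] - rr) ** 2 + (near_c[rr, cc] - cc) ** 2
            k = int(np.argmin(dists))
            fill = int(raster[near_r[rr[k], cc[k]], near_c[rr[k], cc[k]]])
        out[component] = fill
    return out
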