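"""Constrained dynamic time warping between LAI series.

Classic O(mn) dynamic programming with the three-way local step
(insertion, match, deletion), optional Sakoe-Chiba global band around
the slope-adjusted diagonal, and optimal-path backtracking.  The
distance is the plain sum of local costs along the best path; no
path-length normalization is applied because the downstream index
min-max normalizes anyway.

Indices in reported warping paths are 1-based, matching the usual
presentation of the recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import InfeasibleBandError, InvalidInputError


@dataclass(frozen=True)
class DTWConfig:
    """Settings for the warping computation.

    band_radius_r
        Half-width ``r`` of the Sakoe-Chiba band in sample units;
        ``None`` or a radius covering the whole grid disables the
        constraint.  Default 3 samples (15 days on the 5-day grid),
        enough to absorb typical year-to-year transplanting shifts.
    local_distance
        Pointwise cost: absolute difference (keeps the distance in LAI
        units) or squared difference.
    """

    band_radius_r: float | None = 3.0
    local_distance: Literal["absolute", "squared"] = "absolute"
    return_path: bool = False

    def __post_init__(self) -> None:
        if self.band_radius_r is not None and self.band_radius_r < 0:
            raise InvalidInputError("band_radius_r must be >= 0")
        if self.local_distance not in ("absolute", "squared"):
            raise InvalidInputError("local_distance must be 'absolute' or 'squared'")


@dataclass(frozen=True)
class DTWResult:
    distance: float
    path: tuple[tuple[int, int], ...] | None = None
    cost_matrix: np.ndarray | None = field(default=None, repr=False)


def band_mask(m: int, n: int, r: float | None) -> np.ndarray:
    """Boolean (m, n) admissibility mask of the Sakoe-Chiba band.

    Cell (i, j), 1-based, is admissible iff ``|j - (n/m) * i| <= r``.
    ``r=None`` admits every cell.
    """
    if m < 1 or n < 1:
        raise InvalidInputError("series must be non-empty")
    if r is None:
        return np.ones((m, n), dtype=bool)
    i = np.arange(1, m + 1)[:, None]
    j = np.arange(1, n + 1)[None, :]
    return np.abs(j - (n / m) * i) <= r + 1e-12


def _band_is_feasible(mask: np.ndarray) -> bool:
    """True iff a monotone step path connects the two corners inside the band."""
    m, n = mask.shape
    reach = np.zeros((m, n), dtype=bool)
    if not (mask[0, 0] and mask[m - 1, n - 1]):
        return False
    reach[0, 0] = True
    for i in range(m):
        for j in range(n):
            if i == j == 0 or not mask[i, j]:
                continue
            if (i > 0 and reach[i - 1, j]) or (j > 0 and reach[i, j - 1]) or (
                i > 0 and j > 0 and reach[i - 1, j - 1]
            ):
                reach[i, j] = True
    return bool(reach[m - 1, n - 1])


def _local_cost(a: np.ndarray, b: np.ndarray, kind: str) -> np.ndarray:
    diff = a[:, None] - b[None, :]
    return np.abs(diff) if kind == "absolute" else diff**2


def dtw_distance(a, b, config: DTWConfig = DTWConfig()) -> DTWResult:
    """DTW distance (and optionally the optimal path) between two series.

    Raises :class:`InfeasibleBandError` when the band excludes every
    complete path, which can happen for small ``r`` with unequal
    lengths.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size == 0 or b.size == 0:
        raise InvalidInputError("inputs must be non-empty 1-D series")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("series values must be finite")

    m, n = a.size, b.size
    mask = band_mask(m, n, config.band_radius_r)
    if not _band_is_feasible(mask):
        raise InfeasibleBandError(
            f"band radius {config.band_radius_r} admits no complete path "
            f"for lengths ({m}, {n})"
        )

    delta = _local_cost(a, b, config.local_distance)
    acc = np.full((m, n), np.inf)
    acc[0, 0] = delta[0, 0]
    for i in range(m):
        for j in range(n):
            if i == j == 0 or not mask[i, j]:
                continue
            prev = np.inf
            if i > 0:
                prev = acc[i - 1, j]
            if j > 0:
                prev = min(prev, acc[i, j - 1])
            if i > 0 and j > 0:
                prev = min(prev, acc[i - 1, j - 1])
            if np.isfinite(prev):
                acc[i, j] = delta[i, j] + prev

    distance = float(acc[m - 1, n - 1])
    path = _backtrack(acc, m, n) if config.return_path else None
    return DTWResult(distance=distance, path=path, cost_matrix=acc)


def _backtrack(acc: np.ndarray, m: int, n: int) -> tuple[tuple[int, int], ...]:
    """Recover one optimal path, 1-based, preferring diagonal moves on ties."""
    path = [(m, n)]
    i, j = m - 1, n - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda c: c[0])
        path.append((i + 1, j + 1))
    return tuple(reversed(path))


def dtw_distance_batch(
    A: np.ndarray, B: np.ndarray, config: DTWConfig = DTWConfig()
) -> np.ndarray:
    """DTW distances between paired rows of two (p, m) / (p, n) stacks.

    Vectorized over the pixel axis: the dynamic program iterates over
    the (m, n) grid once while operating on all pixels simultaneously.
    Identical to calling :func:`dtw_distance` row by row.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise InvalidInputError("expected (p, m) and (p, n) arrays with equal p")
    p, m = A.shape
    n = B.shape[1]
    mask = band_mask(m, n, config.band_radius_r)
    if not _band_is_feasible(mask):
        raise InfeasibleBandError(
            f"band radius {config.band_radius_r} admits no complete path "
            f"for lengths ({m}, {n})"
        )

    if config.local_distance == "absolute":
        delta = np.abs(A[:, :, None] - B[:, None, :])
    else:
        delta = (A[:, :, None] - B[:, None, :]) ** 2

    acc = np.full((m, n, p), np.inf)
    acc[0, 0] = delta[:, 0, 0]
    for i in range(m):
        for j in range(n):
            if i == j == 0 or not mask[i, j]:
                continue
            prev = np.full(p, np.inf)
            if i > 0:
                prev = np.minimum(prev, acc[i - 1, j])
            if j > 0:
                prev = np.minimum(prev, acc[i, j - 1])
            if i > 0 and j > 0:
                prev = np.minimum(prev, acc[i - 1, j - 1])
            acc[i, j] = delta[:, i, j] + prev
    return acc[m - 1, n - 1]
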