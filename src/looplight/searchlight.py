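"""Cubic searchlights and event-by-event distance matrices.

For every in-mask voxel a ``side x side x side`` cube is collected (clipped at
the volume boundary and the mask), the voxels-by-event-types pattern is
extracted from a beta map, each event-type column is Z-scored across voxels to
remove mean response differences between events, and an N x N distance matrix
(Euclidean by default, correlation as an alternative) is formed between event
columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidParameterError
from .glm import BetaMap

logger = logging.getLogger(__name__)

__all__ = [
    "Searchlight",
    "DistanceMatrix",
    "iter_searchlights",
    "extract_pattern",
    "zscore_columns",
    "distance_matrix",
]


@dataclass(frozen=True)
class Searchlight:
    center: tuple  # (x, y, z)
    voxels: np.ndarray  # (V_sl, 3) in-mask voxel indices, center included
    side: int


@dataclass(frozen=True)
class DistanceMatrix:
    values: np.ndarray  # (N, N) symmetric, nonnegative, zero diagonal
    metric: str


def iter_searchlights(
    mask: np.ndarray, side: int = 3, centers=None
) -> Iterator[Searchlight]:
    """Yield one searchlight per in-mask voxel (or per requested center).

    Cube positions outside the volume or outside the mask are dropped from the
    voxel list; partial searchlights at boundaries are retained.
    """
    if side % 2 == 0 or side < 3:
        raise InvalidParameterError(f"searchlight side must be odd and >= 3, got {side}")
    mask = np.asarray(mask, dtype=bool)
    half = side // 2
    if centers is None:
        centers = np.argwhere(mask)
    for cx, cy, cz in centers:
        if not mask[cx, cy, cz]:
            continue
        sl = (
            slice(max(cx - half, 0), min(cx + half + 1, mask.shape[0])),
            slice(max(cy - half, 0), min(cy + half + 1, mask.shape[1])),
            slice(max(cz - half, 0), min(cz + half + 1, mask.shape[2])),
        )
        local = np.argwhere(mask[sl])
        local[:, 0] += sl[0].start
        local[:, 1] += sl[1].start
        local[:, 2] += sl[2].start
        yield Searchlight(center=(int(cx), int(cy), int(cz)), voxels=local, side=side)


def extract_pattern(betas: BetaMap, sl: Searchlight) -> np.ndarray:
    """(V_sl, N) pattern; rows follow ``sl.voxels`` order, columns event type."""
    v = sl.voxels
    return betas.data[v[:, 0], v[:, 1], v[:, 2], :]


def zscore_columns(pattern: np.ndarray) -> np.ndarray:
    """Z-score each event-type column across voxels (population SD).

    Constant columns map to all zeros.  This removes per-event mean activation
    differences so that only the multivoxel pattern geometry drives distances.
    """
    mu = pattern.mean(axis=0, keepdims=True)
    sd = pattern.std(axis=0, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return np.where(sd > 0, (pattern - mu) / sd_safe, 0.0)


def distance_matrix(pattern: np.ndarray, metric: str = "euclidean") -> DistanceMatrix:
    """N x N distance matrix between event-type columns.

    ``euclidean``: plain L2 between columns.  ``correlation``: 1 - Pearson;
    a zero-variance column is assigned distance 1 to every other column.
    """
    cols = pattern.T  # (N, V_sl)
    if metric == "euclidean":
        values = squareform(pdist(cols, metric="euclidean"))
    elif metric == "correlation":
        sd = cols.std(axis=1)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning(
                "%d zero-variance columns in correlation distance", degenerate.sum()
            )
        safe = np.where(degenerate[:, None], 1.0, cols)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(safe)
        values = 1.0 - corr
        values[degenerate, :] = 1.0
        values[:, degenerate] = 1.0
        np.fill_diagonal(values, 0.0)
        values = np.maximum(values, 0.0)
        values = 0.5 * (values + values.T)
    else:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    return DistanceMatrix(values=values, metric=metric)
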