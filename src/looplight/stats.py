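"""Barcode test statistics and whole-brain statistic maps.

Each searchlight's barcode is reduced to two scalars: the persistence of the
longest-lived loop (``max_persistence``) and an indicator of whether the 1-D
barcode contains exactly one interval (``single_loop``).  An optional ratio
threshold prunes short loop intervals that are dominated by a longer one
("topological noise") before the indicator is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncompleteAnalysisError, InvalidParameterError
from .persistence import Barcode

__all__ = [
    "STATISTICS",
    "StatMap",
    "max_loop_persistence",
    "single_loop_indicator",
    "ratio_threshold_filter",
    "build_stat_maps",
]

STATISTICS = ("max_persistence", "single_loop")


@dataclass
class StatMap:
    """One scalar statistic per searchlight center voxel."""

    data: np.ndarray  # X x Y x Z
    statistic: str
    mask: np.ndarray


def max_loop_persistence(barcode: Barcode) -> float:
    """Persistence (death - birth) of the longest-lived loop; 0 if none."""
    loops = barcode.in_dim(1)
    if not loops:
        return 0.0
    return max(iv.death - iv.birth for iv in loops)


def single_loop_indicator(barcode: Barcode) -> int:
    """1 iff the 1-D barcode contains exactly one interval."""
    return int(barcode.n_loops == 1)


def ratio_threshold_filter(barcode: Barcode, ratio: float) -> Barcode:
    """Prune dominated loop intervals below the first persistence gap >= ratio.

    Loop intervals are sorted by persistence descending; scanning down, the
    first position where an interval is at least ``ratio`` times longer than
    the next one marks the noise floor — that next interval and every shorter
    one are removed.  If no such gap exists, all intervals are kept; a sole
    interval (and the longest interval generally) is always retained.
    Dimension-0 intervals pass through untouched.
    """
    if ratio < 1:
        raise InvalidParameterError(f"ratio must be >= 1, got {ratio}")
    loops = sorted(barcode.in_dim(1), key=lambda iv: iv.death - iv.birth, reverse=True)
    cut = len(loops)
    for i in range(len(loops) - 1):
        p_i = loops[i].death - loops[i].birth
        p_next = loops[i + 1].death - loops[i + 1].birth
        if p_i >= ratio * p_next:
            cut = i + 1
            break
    intervals = [iv for iv in barcode.intervals if iv.dim != 1] + loops[:cut]
    intervals.sort(key=lambda iv: (iv.dim, iv.birth, iv.death))
    return Barcode(intervals=tuple(intervals))


def build_stat_maps(
    barcodes: dict, mask: np.ndarray, statistic: str
) -> StatMap:
    """Assemble a statistic map from per-center barcodes.

    ``barcodes`` maps center (x, y, z) tuples to :class:`Barcode`; every
    in-mask voxel must be present.
    """
    if statistic not in STATISTICS:
        raise InvalidParameterError(f"unknown statistic {statistic!r}")
    mask = np.asarray(mask, dtype=bool)
    fn = max_loop_persistence if statistic == "max_persistence" else single_loop_indicator
    data = np.zeros(mask.shape)
    missing = 0
    for center in map(tuple, np.argwhere(mask)):
        bc = barcodes.get(center)
        if bc is None:
            missing += 1
            continue
        data[center] = fn(bc)
    if missing:
        raise IncompleteAnalysisError(f"{missing} in-mask voxels have no barcode")
    return StatMap(data=data, statistic=statistic, mask=mask)
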