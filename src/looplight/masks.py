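"""Synthetic brain and ROI masks.

The simulated "brain" is an ellipsoid inscribed in the volume; the signal ROI
is a compact blob of a requested voxel count placed in one hemisphere, and the
control ROI is its mirror image across the mid-plane of the first axis.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidMaskError
from .inference import mirror_roi
from .signal import SignalPatterns

__all__ = ["ellipsoid_mask", "ball_roi", "default_masks", "place_patterns", "roi_flat_indices"]


def ellipsoid_mask(shape, margin: float = 1.0) -> np.ndarray:
    """Ellipsoid inscribed in ``shape`` with ``margin`` voxels of border."""
    grids = np.indices(shape, dtype=float)
    center = [(s - 1) / 2.0 for s in shape]
    radii = [max(s / 2.0 - margin, 1.0) for s in shape]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def ball_roi(brain_mask: np.ndarray, center, n_voxels: int) -> np.ndarray:
    """The ``n_voxels`` in-brain voxels nearest to ``center`` (a compact blob)."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    coords = np.argwhere(brain_mask)
    if len(coords) < n_voxels:
        raise InvalidMaskError(
            f"brain mask has {len(coords)} voxels, ROI needs {n_voxels}"
        )
    d2 = ((coords - np.asarray(center, float)) ** 2).sum(axis=1)
    pick = coords[np.argsort(d2, kind="stable")[:n_voxels]]
    roi = np.zeros_like(brain_mask)
    roi[pick[:, 0], pick[:, 1], pick[:, 2]] = True
    return roi


def default_masks(shape=(24, 24, 16), roi_voxels: int = 60):
    """Brain, signal-ROI and mirrored control-ROI masks.

    The signal ROI sits in the first-axis "left" half so its mirror is
    disjoint from it.  Returns ``(brain, signal_roi, control_roi)``.
    """
    brain = ellipsoid_mask(shape)
    center = (shape[0] * 0.25, shape[1] / 2.0, shape[2] / 2.0)
    roi = ball_roi(brain, center, roi_voxels)
    control = mirror_roi(roi)
    if (roi & control).any():
        raise InvalidMaskError("signal and control ROIs overlap; move the ROI center")
    if not (control & brain).all() and not control[brain].any():
        raise InvalidMaskError("mirrored control ROI fell outside the brain")
    return brain, roi, control


def roi_flat_indices(roi_mask: np.ndarray) -> np.ndarray:
    """Flat (raveled, C-order) indices of ROI voxels, 0-based (x, y, z)."""
    return np.flatnonzero(np.asarray(roi_mask, dtype=bool).ravel())


def place_patterns(patterns: SignalPatterns, roi_mask: np.ndarray) -> SignalPatterns:
    """Attach ROI voxel locations to a pattern set."""
    idx = roi_flat_indices(roi_mask)
    if len(idx) != patterns.n_voxels:
        raise InvalidMaskError(
            f"ROI has {len(idx)} voxels but patterns have {patterns.n_voxels}"
        )
    return SignalPatterns(
        patterns=patterns.patterns, psc=patterns.psc, roi_voxels=idx
    )
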