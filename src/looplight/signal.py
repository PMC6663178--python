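"""Ground-truth topological signal: N points on a circle embedded in voxel space.

The signal model places ``n_types`` equispaced points on a planar circle,
pushes them into a V-voxel region of interest through a random orthonormal
(distance-preserving) linear map, shifts the result to be nonnegative, and
rescales so that the global maximum equals the requested percent signal
change.  The shift and scale are *global* (a single affine transform of the
whole pattern matrix), so the N x N inter-pattern distance geometry of the
circle is preserved up to one positive scalar — the property the downstream
topological analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDesignError, InvalidDimensionError, InvalidSignalError

__all__ = [
    "CirclePoints",
    "EmbeddingMap",
    "SignalPatterns",
    "make_circle_points",
    "make_orthonormal_embedding",
    "embed_and_scale",
]


@dataclass(frozen=True)
class CirclePoints:
    """``n_types`` equispaced points on a planar circle of given radius."""

    coords: np.ndarray  # (N, 2)
    n_types: int
    radius: float

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d**2).sum(-1))


@dataclass(frozen=True)
class EmbeddingMap:
    """A 2 x V orthonormal basis plus an optional nonnegative per-voxel offset."""

    basis: np.ndarray  # (2, V)
    offset: np.ndarray = None  # (V,)

    def __post_init__(self):
        if self.offset is None:
            object.__setattr__(self, "offset", np.zeros(self.basis.shape[1]))

    @property
    def n_voxels(self) -> int:
        return self.basis.shape[1]


@dataclass(frozen=True)
class SignalPatterns:
    """Per-event-type voxel amplitudes in percent-signal-change units.

    ``patterns[k, v]`` is the evoked amplitude of voxel ``v`` for event type
    ``k``.  ``roi_voxels`` optionally records where the V pattern voxels live
    inside a 3-D mask (flat indices, 0-based (x, y, z) raveling).
    """

    patterns: np.ndarray  # (N, V), all >= 0
    psc: float
    roi_voxels: np.ndarray = field(default=None)

    @property
    def n_types(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def distance_matrix(self) -> np.ndarray:
        d = self.patterns[:, None, :] - self.patterns[None, :, :]
        return np.sqrt((d**2).sum(-1))

    def to_tsv(self, path) -> None:
        """Write patterns as TSV: rows = event types, columns = voxel indices."""
        import pandas as pd

        cols = (
            [str(v) for v in self.roi_voxels]
            if self.roi_voxels is not None
            else [str(v) for v in range(self.n_voxels)]
        )
        pd.DataFrame(self.patterns, columns=cols).to_csv(path, sep="\t", index=False)


def make_circle_points(n_types: int, radius: float = 1.0) -> CirclePoints:
    """Return ``n_types`` equispaced points at angles 2*pi*k/N on a circle.

    Raises
    ------
    InvalidDesignError
        If ``n_types < 3`` (no loop can be formed) or ``radius <= 0``.
    """
    if n_types < 3:
        raise InvalidDesignError(
            f"need at least 3 event types to form a loop, got {n_types}"
        )
    if radius <= 0:
        raise InvalidDesignError(f"radius must be positive, got {radius}")
    angles = 2.0 * np.pi * np.arange(n_types) / n_types
    coords = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    return CirclePoints(coords=coords, n_types=int(n_types), radius=float(radius))


def make_orthonormal_embedding(
    n_voxels: int, rng: np.random.Generator
) -> EmbeddingMap:
    """Draw a uniformly random 2-D orthonormal basis in ``n_voxels`` dimensions.

    Two independent standard-normal vectors are orthonormalized (thin QR);
    rotation invariance of the Gaussian makes the spanned plane uniform on the
    Grassmannian.  Deterministic given the generator state.
    """
    if n_voxels < 2:
        raise InvalidDimensionError(
            f"embedding needs at least 2 voxels, got {n_voxels}"
        )
    g = rng.standard_normal((n_voxels, 2))
    q, r = np.linalg.qr(g)
    # fix signs so the map is a deterministic function of g
    q = q * np.sign(np.diag(r))
    return EmbeddingMap(basis=np.ascontiguousarray(q.T))


def embed_and_scale(
    points: CirclePoints, embedding: EmbeddingMap, psc: float
) -> SignalPatterns:
    """Embed circle points into voxel space, shift positive, scale max to ``psc``.

    ``raw = coords @ basis`` is shifted by the global minimum so every entry is
    nonnegative, then multiplied by ``psc / max`` so the single largest entry
    equals ``psc`` exactly.  ``psc = 0`` returns an all-zero pattern set.
    """
    if psc < 0:
        raise InvalidSignalError(f"percent signal change must be >= 0, got {psc}")
    raw = points.coords @ embedding.basis + embedding.offset
    if psc == 0:
        return SignalPatterns(patterns=np.zeros_like(raw), psc=0.0)
    shifted = raw - raw.min()
    top = shifted.max()
    if top <= 0:
        raise InvalidSignalError("degenerate embedding: all pattern values equal")
    return SignalPatterns(patterns=(shifted / top) * psc, psc=float(psc))
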