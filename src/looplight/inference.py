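"""Nonparametric group inference: sign-flip permutations with TFCE.

The per-participant statistic maps are whole-brain demeaned (the barcode
statistics are not zero-centered under the null), a one-sample t map is formed
across participants, threshold-free cluster enhancement (TFCE) integrates
cluster extent and height over all thresholds, and family-wise corrected
p-values come from the maximum enhanced statistic over random sign flips of
the participant maps (valid under a symmetric voxelwise null).  Exhaustive
enumeration of all 2^n flip patterns is used for small samples.

Two TFCE engines exist: :func:`tfce_transform`, a direct per-threshold
connected-component implementation (scipy.ndimage), and a numba union-find
engine used inside the permutation loop; they compute the same discrete-sum
transform and are cross-checked in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

from .errors import InsufficientSampleError, InvalidMaskError, InvalidParameterError
from .stats import StatMap

__all__ = [
    "TfceParams",
    "GroupResult",
    "demean_map",
    "tfce_transform",
    "sign_flip_test",
    "mirror_roi",
    "roi_significance_proportion",
]


@dataclass(frozen=True)
class TfceParams:
    """TFCE parameters; defaults follow common randomise practice.

    ``dh = None`` means each map uses its own positive maximum divided by
    ``n_steps``.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float = None
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self):
        if self.E <= 0 or self.H <= 0 or (self.dh is not None and self.dh <= 0):
            raise InvalidParameterError("E, H and dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise InvalidParameterError("connectivity must be 6, 18 or 26")


@dataclass
class GroupResult:
    """Corrected p map, significance mask and ROI summary proportions."""

    p_map: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    mask: np.ndarray
    n_perm: int
    exhaustive: bool
    roi_proportions: dict = None


def demean_map(stat_map: StatMap, mask: np.ndarray = None) -> StatMap:
    """Subtract the whole-brain in-mask mean; out-of-mask voxels stay 0."""
    mask = np.asarray(stat_map.mask if mask is None else mask, dtype=bool)
    if not mask.any():
        raise InvalidMaskError("mask selects no voxels")
    data = np.zeros_like(stat_map.data, dtype=float)
    data[mask] = stat_map.data[mask] - stat_map.data[mask].mean()
    return StatMap(data=data, statistic=stat_map.statistic, mask=mask)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def _thresholds(vmax: float, params: TfceParams):
    dh = params.dh if params.dh is not None else vmax / params.n_steps
    if dh <= 0:
        return dh, np.array([])
    return dh, np.arange(dh, vmax + 1e-12, dh)


def tfce_transform(
    data: np.ndarray, params: TfceParams = TfceParams(), mask: np.ndarray = None
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a 3-D map.

    enhanced(v) = sum over thresholds h = dh, 2dh, ... of
    extent(cluster of v at h)^E * h^H * dh, where clusters are connected
    components of {value >= h}.  Nonpositive voxels map to 0.
    """
    data = np.asarray(data, dtype=float)
    if mask is not None:
        data = np.where(np.asarray(mask, dtype=bool), data, 0.0)
    out = np.zeros_like(data)
    vmax = data.max()
    if vmax <= 0:
        return out
    dh, hs = _thresholds(vmax, params)
    struct = _structure(params.connectivity)
    for h in hs:
        supra = data >= h
        labels, n = ndimage.label(supra, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        incr = (sizes.astype(float) ** params.E) * (h**params.H) * dh
        incr[0] = 0.0
        out += incr[labels]
    return out


# ---------------------------------------------------------------------------
# fast TFCE engine (union-find over descending thresholds) for permutations


@njit(cache=True)
def _tfce_fast_kernel(vals, order, nbr_indptr, nbr_indices, E, H, dh, n_steps):
    n = vals.shape[0]
    parent = np.full(n, -1, dtype=np.int64)  # -1 = inactive
    size = np.zeros(n, dtype=np.int64)
    offset = np.zeros(n)  # accumulated enhancement relative to parent
    roots = np.empty(n, dtype=np.int64)
    n_roots = 0
    ptr = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        # activate voxels with value >= h (descending order walk)
        while ptr < n and vals[order[ptr]] >= h - 1e-12 * dh:
            v = order[ptr]
            ptr += 1
            parent[v] = v
            size[v] = 1
            offset[v] = 0.0
            roots[n_roots] = v
            n_roots += 1
            for e in range(nbr_indptr[v], nbr_indptr[v + 1]):
                u = nbr_indices[e]
                if parent[u] == -1:
                    continue
                # find roots of u and v
                ru = u
                while parent[ru] != ru:
                    ru = parent[ru]
                rv = v
                while parent[rv] != rv:
                    rv = parent[rv]
                if ru == rv:
                    continue
                if size[ru] < size[rv]:
                    ru, rv = rv, ru
                # attach rv under ru, preserving accumulated offsets
                parent[rv] = ru
                offset[rv] -= offset[ru]
                size[ru] += size[rv]
        # accumulate this threshold's increment on every active cluster
        w = 0
        for r_i in range(n_roots):
            r = roots[r_i]
            if parent[r] == r:
                offset[r] += (size[r] ** E) * (h**H) * dh
                roots[w] = r
                w += 1
        n_roots = w
    # resolve each active voxel's total enhancement along its parent chain
    out = np.zeros(n)
    for v in range(n):
        if parent[v] == -1:
            continue
        total = 0.0
        x = v
        while True:
            total += offset[x]
            if parent[x] == x:
                break
            x = parent[x]
        out[v] = total
    return out


class _TfceEngine:
    """Precomputes the in-mask neighbor graph once; evaluates TFCE repeatedly."""

    def __init__(self, mask: np.ndarray, params: TfceParams):
        self.mask = np.asarray(mask, dtype=bool)
        self.params = params
        self.flat_idx = np.flatnonzero(self.mask.ravel())
        idx_of = -np.ones(self.mask.size, dtype=np.int64)
        idx_of[self.flat_idx] = np.arange(len(self.flat_idx))
        struct = _structure(params.connectivity)
        offs = np.argwhere(struct) - 1
        offs = offs[np.any(offs != 0, axis=1)]
        coords = np.argwhere(self.mask)
        indptr = [0]
        indices = []
        shape = self.mask.shape
        for x, y, z in coords:
            for dx, dy, dz in offs:
                a, b, c = x + dx, y + dy, z + dz
                if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                    if self.mask[a, b, c]:
                        indices.append(idx_of[(a * shape[1] + b) * shape[2] + c])
            indptr.append(len(indices))
        self.nbr_indptr = np.asarray(indptr, dtype=np.int64)
        self.nbr_indices = np.asarray(indices, dtype=np.int64)

    def __call__(self, data: np.ndarray) -> np.ndarray:
        """Return the enhanced values at in-mask voxels (1-D array)."""
        vals = np.where(self.mask, data, 0.0).ravel()[self.flat_idx]
        vmax = vals.max() if vals.size else 0.0
        if vmax <= 0:
            return np.zeros(len(self.flat_idx))
        p = self.params
        dh = p.dh if p.dh is not None else vmax / p.n_steps
        n_steps = int(np.floor(vmax / dh + 1e-12))
        order = np.argsort(-vals)
        return _tfce_fast_kernel(
            vals, order, self.nbr_indptr, self.nbr_indices, p.E, p.H, dh, n_steps
        )


_ENGINE_CACHE: dict = {}


def _get_engine(mask: np.ndarray, params: TfceParams) -> _TfceEngine:
    """Reuse the neighbor graph across calls with the same mask/connectivity."""
    key = (mask.tobytes(), mask.shape, params.connectivity)
    engine = _ENGINE_CACHE.get(key)
    if engine is None or engine.params != params:
        engine = _TfceEngine(mask, params)
        if len(_ENGINE_CACHE) > 8:
            _ENGINE_CACHE.clear()
        _ENGINE_CACHE[key] = engine
    return engine


def _t_maps(stack: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """One-sample t maps for each sign-flip row.

    ``stack`` is (n_subjects, n_voxels); ``flips`` is (n_perm, n_subjects) of
    +-1.  Zero-variance voxels get t = 0 when the mean is 0 too, otherwise a
    large finite value of the mean's sign.
    """
    n = stack.shape[0]
    mean = flips @ stack / n
    # flipping signs leaves |x| unchanged: var = E[x^2] - mean^2
    sq = (stack**2).sum(axis=0) / n
    var = np.maximum(sq[None, :] - mean**2, 0.0) * (n / (n - 1))
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0
    big = 1e10
    t[np.isposinf(t)] = big
    t[np.isneginf(t)] = -big
    return t


def sign_flip_test(
    maps,
    params: TfceParams = TfceParams(),
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator = None,
    mask: np.ndarray = None,
    exhaustive_limit: int = 4096,
) -> GroupResult:
    """One-sample sign-flip permutation test with TFCE and max-statistic FWE.

    The observed statistic is the TFCE-enhanced one-sample t map of the
    (already demeaned) participant maps.  The null records the maximum
    enhanced value per sign-flip pattern.  When 2^n <= ``exhaustive_limit``
    all flip patterns are enumerated (corrected p = count / 2^n, the identity
    pattern guaranteeing p >= 2^-n); otherwise ``n_perm`` random patterns are
    drawn and p = (1 + count) / (1 + n_perm).
    """
    arrs = [m.data if isinstance(m, StatMap) else np.asarray(m, float) for m in maps]
    if len(arrs) < 2:
        raise InsufficientSampleError("group test needs at least 2 participants")
    if mask is None:
        first = maps[0]
        mask = first.mask if isinstance(first, StatMap) else np.ones(arrs[0].shape, bool)
    mask = np.asarray(mask, dtype=bool)
    n = len(arrs)
    stack = np.stack([a.ravel()[np.flatnonzero(mask.ravel())] for a in arrs])

    exhaustive = 2**n <= exhaustive_limit
    if exhaustive:
        patterns = np.array(
            [[1 - 2 * ((i >> s) & 1) for s in range(n)] for i in range(2**n)],
            dtype=float,
        )
    else:
        if rng is None:
            rng = np.random.default_rng()
        patterns = rng.choice([-1.0, 1.0], size=(n_perm, n))

    engine = _get_engine(mask, params)
    identity = np.ones((1, n))
    obs_t = _t_maps(stack, identity)[0]
    tvol = np.zeros(mask.shape)
    tvol[mask] = obs_t
    obs_enh = engine(tvol)

    t_null = _t_maps(stack, patterns)
    null_max = np.empty(len(patterns))
    for i in range(len(patterns)):
        tvol[mask] = t_null[i]
        null_max[i] = engine(tvol).max(initial=0.0)

    counts = (null_max[None, :] >= obs_enh[:, None] - 1e-12).sum(axis=1)
    if exhaustive:
        p_in = counts / len(patterns)
    else:
        p_in = (1.0 + counts) / (1.0 + len(patterns))
    p_map = np.ones(mask.shape)
    p_map[mask] = p_in
    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = p_in < alpha
    return GroupResult(
        p_map=p_map,
        sig_mask=sig,
        alpha=float(alpha),
        mask=mask,
        n_perm=len(patterns),
        exhaustive=exhaustive,
    )


def mirror_roi(roi_mask: np.ndarray) -> np.ndarray:
    """Reflect a mask across the mid-plane of the first (left-right) axis."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.ndim != 3:
        raise InvalidMaskError("ROI mask must be 3-D")
    return roi_mask[::-1, :, :].copy()


def roi_significance_proportion(result: GroupResult, roi_mask: np.ndarray) -> float:
    """Fraction of ROI voxels that are significant."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n_roi = roi_mask.sum()
    if n_roi == 0:
        raise InvalidMaskError("ROI mask is empty")
    return float((result.sig_mask & roi_mask).sum() / n_roi)
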