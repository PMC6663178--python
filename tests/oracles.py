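"""Independent test oracles, deliberately naive and separate from the package.

``naive_rips_barcode`` builds the full dense GF(2) boundary matrix of the Rips
filtration and reduces it with explicit loops — a direct transcription of the
textbook algorithm, sharing no code with looplight's implementation.
"""

import math
from itertools import combinations

import numpy as np


def naive_rips_barcode(dist, max_dim=1):
    """Barcode as a sorted list of (dim, birth, death); zero bars dropped."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    simplices = [((i,), 0.0) for i in range(n)]
    for e in combinations(range(n), 2):
        simplices.append((e, float(dist[e[0], e[1]])))
    if max_dim >= 1:
        for t in combinations(range(n), 3):
            val = max(dist[t[0], t[1]], dist[t[0], t[2]], dist[t[1], t[2]])
            simplices.append((t, float(val)))
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    m = len(simplices)
    pos = {s[0]: i for i, s in enumerate(simplices)}

    # dense GF(2) boundary matrix
    B = np.zeros((m, m), dtype=bool)
    for j, (verts, _) in enumerate(simplices):
        if len(verts) > 1:
            for face in combinations(verts, len(verts) - 1):
                B[pos[face], j] = True

    def low(col):
        nz = np.nonzero(col)[0]
        return int(nz[-1]) if len(nz) else -1

    lows = {}
    for j in range(m):
        while True:
            lj = low(B[:, j])
            if lj == -1 or lj not in lows:
                break
            B[:, j] ^= B[:, lows[lj]]
        lj = low(B[:, j])
        if lj != -1:
            lows[lj] = j

    paired_rows = set(lows.keys())
    paired_cols = set(lows.values())
    out = []
    for i, j in lows.items():
        dim = len(simplices[i][0]) - 1
        birth, death = simplices[i][1], simplices[j][1]
        if death > birth and dim <= max_dim:
            out.append((dim, birth, death))
    for i, (verts, val) in enumerate(simplices):
        if i not in paired_rows and i not in paired_cols:
            dim = len(verts) - 1
            if dim <= max_dim:
                out.append((dim, val, math.inf))
    return sorted(out)


def barcode_as_tuples(barcode):
    return sorted((iv.dim, iv.birth, iv.death) for iv in barcode.intervals)


def single_linkage_merge_heights(dist):
    """H0 finite deaths via scipy's agglomerative clustering (single linkage)."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    z = linkage(squareform(np.asarray(dist, float), checks=False), method="single")
    return sorted(z[:, 2].tolist())


def tfce_single_voxel(value, E, H, dh):
    """Hand summation for an isolated positive voxel: sum 1^E * h^H * dh."""
    total, h = 0.0, dh
    while h <= value + 1e-12:
        total += (1.0**E) * (h**H) * dh
        h += dh
    return total
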