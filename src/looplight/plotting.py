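"""Small plotting helpers (persistence diagrams, distance matrices)."""

from __future__ import annotations

import numpy as np


def plot_persistence_diagram(barcode, ax=None, inf_pad: float = 1.1):
    """Scatter births vs deaths; clusters as circles, loops as crosses."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    finite = [iv.death for iv in barcode.intervals if np.isfinite(iv.death)]
    top = (max(finite) if finite else 1.0) * inf_pad
    for dim, marker, label in ((0, "o", "clusters (H0)"), (1, "x", "loops (H1)")):
        ivs = barcode.in_dim(dim)
        if not ivs:
            continue
        births = [iv.birth for iv in ivs]
        deaths = [iv.death if np.isfinite(iv.death) else top for iv in ivs]
        ax.scatter(births, deaths, marker=marker, label=label)
    ax.plot([0, top], [0, top], color="grey", lw=0.8)
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    ax.legend()
    return ax


def plot_distance_matrix(dm, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = getattr(dm, "values", dm)
    im = ax.imshow(values, cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label=f"{getattr(dm, 'metric', '')} distance")
    ax.set_xlabel("event type")
    ax.set_ylabel("event type")
    return ax
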