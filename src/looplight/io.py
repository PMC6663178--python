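"""NIfTI and TSV input/output helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import Volume4D
from .glm import BetaMap
from .stats import StatMap


def save_volume(path, vol: Volume4D) -> None:
    """Write a 4-D run as NIfTI with the TR in the time zoom."""
    import nibabel as nib

    img = nib.Nifti1Image(vol.data.astype(np.float32), affine=np.eye(4))
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_volume(path, mask: np.ndarray = None) -> Volume4D:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    tr = float(img.header.get_zooms()[3]) if data.ndim == 4 else 1.0
    if mask is None:
        mask = np.any(data != 0, axis=-1)
    return Volume4D(data=data, mask=np.asarray(mask, bool), tr=tr)


def save_mask(path, mask: np.ndarray) -> None:
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4)), str(path)
    )


def load_mask(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_beta_map(path, betas: BetaMap, type_names=None, sidecar=None) -> None:
    """4-D NIfTI (4th axis = event type) plus optional TSV naming the types."""
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(betas.data.astype(np.float32), affine=np.eye(4)), str(path)
    )
    if sidecar is not None:
        names = type_names or [f"type_{k}" for k in range(betas.n_types)]
        pd.DataFrame({"index": range(len(names)), "event_type": names}).to_csv(
            sidecar, sep="\t", index=False
        )


def save_stat_map(path, stat_map: StatMap) -> None:
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(stat_map.data.astype(np.float32), affine=np.eye(4)), str(path)
    )


def barcodes_to_tsv(path, barcodes: dict) -> None:
    """TSV with columns (center_x, center_y, center_z, dim, birth, death)."""
    rows = [
        (cx, cy, cz, iv.dim, iv.birth, iv.death)
        for (cx, cy, cz), bc in barcodes.items()
        for iv in bc.intervals
    ]
    pd.DataFrame(
        rows, columns=["center_x", "center_y", "center_z", "dim", "birth", "death"]
    ).to_csv(path, sep="\t", index=False)
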