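"""Model/Results surface over the analysis pipeline.

:class:`SearchlightTopology` is the first-level model: given simulated (or
loaded) 4-D runs and their event tables, ``fit()`` runs the per-run GLM,
averages the betas, sweeps the searchlight, computes a Rips barcode per center
and returns :class:`SearchlightTopologyResults` holding the beta map, the
barcodes and the two statistic maps.

:class:`GroupTopologyTest` is the second-level model: given one statistic map
per participant, ``fit()`` demeans each map, runs the sign-flip + TFCE
permutation test and returns :class:`GroupTopologyResults` with the corrected
p map, significance mask and ROI significance proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm as _glm
from .design import HRFKernel, Volume4D, double_gamma_hrf
from .errors import InvalidParameterError
from .inference import (
    GroupResult,
    TfceParams,
    demean_map,
    roi_significance_proportion,
    sign_flip_test,
)
from .persistence import Barcode, rips_barcode
from .searchlight import distance_matrix, extract_pattern, iter_searchlights, zscore_columns
from .stats import STATISTICS, StatMap, build_stat_maps

__all__ = [
    "SearchlightTopology",
    "SearchlightTopologyResults",
    "GroupTopologyTest",
    "GroupTopologyResults",
]


class SearchlightTopology:
    """First-level model: runs + event tables -> barcode statistic maps.

    Parameters
    ----------
    runs : list of Volume4D
        Simulated or loaded 4-D runs (already Z-scored if desired).
    run_events : list of DataFrame
        One event table per run (columns onset_s, duration_s, event_type).
    n_types : int
        Number of distinct event types N.
    mask : ndarray
        Brain mask; searchlights are centered on every in-mask voxel.
    hrf : HRFKernel, optional
        Defaults to the canonical double-gamma kernel.
    side : int
        Searchlight cube side (odd, default 3).
    metric : str
        'euclidean' (default) or 'correlation' column distance.
    centers : array-like, optional
        Restrict the sweep to these center voxels (e.g. ROI-only analyses).
    min_voxels : int
        Searchlights with fewer in-mask voxels get an empty barcode.
    """

    def __init__(
        self,
        runs,
        run_events,
        n_types: int,
        mask,
        hrf: HRFKernel = None,
        side: int = 3,
        metric: str = "euclidean",
        intercept: bool = True,
        linear_drift: bool = True,
        centers=None,
        min_voxels: int = 2,
    ):
        if len(runs) != len(run_events):
            raise InvalidParameterError("one event table per run is required")
        self.runs = list(runs)
        self.run_events = list(run_events)
        self.n_types = int(n_types)
        self.mask = np.asarray(mask, dtype=bool)
        self.hrf = hrf if hrf is not None else double_gamma_hrf()
        self.side = side
        self.metric = metric
        self.intercept = intercept
        self.linear_drift = linear_drift
        self.centers = centers
        self.min_voxels = int(min_voxels)

    def fit(self) -> "SearchlightTopologyResults":
        per_run = []
        for vol, events in zip(self.runs, self.run_events):
            design = _glm.build_design_matrix(
                events,
                self.hrf,
                vol.n_timepoints,
                vol.tr,
                n_types=self.n_types,
                intercept=self.intercept,
                linear_drift=self.linear_drift,
            )
            per_run.append(_glm.fit_glm(vol, design))
        betas = _glm.average_betas(per_run)

        barcodes = {}
        for sl in iter_searchlights(self.mask, side=self.side, centers=self.centers):
            if len(sl.voxels) < self.min_voxels:
                barcodes[sl.center] = Barcode(intervals=())
                continue
            pattern = zscore_columns(extract_pattern(betas, sl))
            dm = distance_matrix(pattern, metric=self.metric)
            barcodes[sl.center] = rips_barcode(dm)
        return SearchlightTopologyResults(model=self, beta_map=betas, barcodes=barcodes)


@dataclass
class SearchlightTopologyResults:
    model: SearchlightTopology
    beta_map: "_glm.BetaMap"
    barcodes: dict
    _stat_maps: dict = field(default_factory=dict)

    def stat_map(self, statistic: str) -> StatMap:
        """Whole-sweep map of one barcode statistic (cached)."""
        if statistic not in self._stat_maps:
            mask = self.model.mask
            if self.model.centers is not None:
                mask = np.zeros_like(mask)
                c = np.asarray(self.model.centers)
                mask[c[:, 0], c[:, 1], c[:, 2]] = True
                mask &= self.model.mask
            self._stat_maps[statistic] = build_stat_maps(
                self.barcodes, mask, statistic
            )
        return self._stat_maps[statistic]

    def roi_mean(self, statistic: str, roi_mask) -> float:
        """Mean of a statistic over ROI center voxels covered by the sweep."""
        roi_mask = np.asarray(roi_mask, dtype=bool)
        sm = self.stat_map(statistic)
        sel = roi_mask & sm.mask
        return float(sm.data[sel].mean())

    def summary(self) -> pd.DataFrame:
        rows = []
        for statistic in STATISTICS:
            sm = self.stat_map(statistic)
            vals = sm.data[sm.mask]
            rows.append(
                {
                    "statistic": statistic,
                    "n_searchlights": int(sm.mask.sum()),
                    "mean": float(vals.mean()),
                    "max": float(vals.max()),
                }
            )
        return pd.DataFrame(rows)


class GroupTopologyTest:
    """Second-level model: per-participant statistic maps -> corrected p map.

    Maps are whole-brain demeaned before testing, following the rationale that
    the barcode statistics have an arbitrary positive baseline under the null.
    """

    def __init__(
        self,
        stat_maps,
        mask,
        tfce: TfceParams = None,
        n_perm: int = 1000,
        alpha: float = 0.05,
        exhaustive_limit: int = 4096,
    ):
        self.stat_maps = list(stat_maps)
        self.mask = np.asarray(mask, dtype=bool)
        self.tfce = tfce if tfce is not None else TfceParams()
        self.n_perm = int(n_perm)
        self.alpha = float(alpha)
        self.exhaustive_limit = int(exhaustive_limit)

    def fit(self, rng: np.random.Generator = None) -> "GroupTopologyResults":
        demeaned = [
            demean_map(
                m if isinstance(m, StatMap) else StatMap(np.asarray(m, float), "stat", self.mask),
                self.mask,
            )
            for m in self.stat_maps
        ]
        result = sign_flip_test(
            demeaned,
            params=self.tfce,
            n_perm=self.n_perm,
            alpha=self.alpha,
            rng=rng,
            mask=self.mask,
            exhaustive_limit=self.exhaustive_limit,
        )
        return GroupTopologyResults(model=self, result=result)


@dataclass
class GroupTopologyResults:
    model: GroupTopologyTest
    result: GroupResult

    @property
    def p_map(self) -> np.ndarray:
        return self.result.p_map

    @property
    def sig_mask(self) -> np.ndarray:
        return self.result.sig_mask

    def roi_proportion(self, roi_mask) -> float:
        return roi_significance_proportion(self.result, roi_mask)

    def summary(self, rois: dict = None) -> pd.DataFrame:
        rows = [
            {
                "quantity": "n_significant_voxels",
                "value": float(self.sig_mask.sum()),
            },
            {"quantity": "alpha", "value": self.model.alpha},
            {"quantity": "n_permutations", "value": float(self.result.n_perm)},
        ]
        for name, roi in (rois or {}).items():
            rows.append(
                {
                    "quantity": f"significant_proportion[{name}]",
                    "value": self.roi_proportion(roi),
                }
            )
        return pd.DataFrame(rows)
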