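"""Mass-univariate GLM: per-run OLS on HRF-convolved regressors, beta averaging.

Each run is fit voxelwise by ordinary least squares against one HRF-convolved
boxcar regressor per event type plus confounds (intercept always; linear drift
by default).  Event-type coefficients are kept, confounds discarded, and the
per-run coefficient maps are averaged across runs to give one voxelwise
response pattern per event type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import HRFKernel, Volume4D, event_regressors
from .errors import (
    IncompatibleMapsError,
    InvalidScheduleError,
    SingularDesignError,
)

__all__ = ["DesignMatrix", "BetaMap", "build_design_matrix", "fit_glm", "average_betas"]


@dataclass(frozen=True)
class DesignMatrix:
    matrix: np.ndarray  # (T, n_types + n_confounds)
    n_types: int
    column_names: tuple

    @property
    def n_confounds(self) -> int:
        return self.matrix.shape[1] - self.n_types


@dataclass
class BetaMap:
    """X x Y x Z x N event-type coefficients; zero outside the mask."""

    data: np.ndarray
    mask: np.ndarray

    @property
    def n_types(self) -> int:
        return self.data.shape[-1]


def build_design_matrix(
    run_events: pd.DataFrame,
    hrf: HRFKernel,
    n_timepoints: int,
    tr: float,
    n_types: int = None,
    intercept: bool = True,
    linear_drift: bool = True,
) -> DesignMatrix:
    """One HRF-convolved regressor per event type, plus confound columns."""
    if n_types is None:
        n_types = int(run_events["event_type"].max()) + 1
    run_end = n_timepoints * tr
    last_end = float((run_events["onset_s"] + run_events["duration_s"]).max())
    if last_end > run_end:
        raise InvalidScheduleError(
            f"event ending at {last_end} s lies beyond the run end ({run_end} s)"
        )
    reg = event_regressors(run_events, hrf, n_timepoints, tr, n_types)
    if (np.abs(reg).max(axis=0) == 0).any():
        empty = np.where(np.abs(reg).max(axis=0) == 0)[0]
        raise InvalidScheduleError(f"event types {empty.tolist()} have no events")
    cols = [reg]
    names = [f"type_{k}" for k in range(n_types)]
    if intercept:
        cols.append(np.ones((n_timepoints, 1)))
        names.append("intercept")
    if linear_drift:
        drift = np.linspace(-1.0, 1.0, n_timepoints)[:, None]
        cols.append(drift)
        names.append("linear_drift")
    return DesignMatrix(
        matrix=np.hstack(cols), n_types=int(n_types), column_names=tuple(names)
    )


def fit_glm(run: Volume4D, design: DesignMatrix) -> BetaMap:
    """Voxelwise OLS; returns only the event-type coefficients.

    Raises ``SingularDesignError`` naming the collinear columns when the
    design is rank deficient.
    """
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # columns whose removal restores full rank relative to the rest
        _, r = np.linalg.qr(X)
        bad = np.where(np.abs(np.diag(r)) < 1e-10 * np.abs(np.diag(r)).max())[0]
        bad_names = [design.column_names[i] for i in bad]
        raise SingularDesignError(f"design is rank deficient; collinear: {bad_names}")
    mask = np.asarray(run.mask, dtype=bool)
    Y = run.data[mask].T  # (T, V)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out = np.zeros(mask.shape + (design.n_types,))
    out[mask] = coef[: design.n_types].T
    return BetaMap(data=out, mask=mask)


def average_betas(per_run: list) -> BetaMap:
    """Voxelwise arithmetic mean of per-run coefficient maps."""
    if len(per_run) == 0:
        raise IncompatibleMapsError("no beta maps to average")
    first = per_run[0]
    for b in per_run[1:]:
        if b.data.shape != first.data.shape or not np.array_equal(b.mask, first.mask):
            raise IncompatibleMapsError("beta maps differ in shape or mask")
    data = np.mean([b.data for b in per_run], axis=0)
    return BetaMap(data=data, mask=first.mask.copy())
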