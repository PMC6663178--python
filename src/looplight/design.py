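"""Event-related design simulation: schedules, HRF, noise, and full runs.

This is the synthetic-data generator.  It emulates the statistical structure
the downstream analysis assumes:

* a randomized event schedule (1-s events, inter-stimulus intervals drawn
  uniformly from {7, 9, 11} s, each event type repeated equally often in each
  of five runs),
* a double-gamma hemodynamic response convolved with per-voxel boxcar
  regressors on a fine time grid, then sampled at the repetition time,
* temporally autocorrelated (AR(1)), spatially smooth Gaussian noise with a
  slow sinusoidal drift, and
* per-voxel Z-scoring of each run over time.

Percent signal change is expressed relative to the baseline fluctuation scale:
the noise generator is normalized so that the in-mask temporal standard
deviation equals ``sigma_system`` (default 1), and signal patterns carry the
evoked amplitude in the same units, so ``psc = 0.5`` means the strongest
voxel's evoked response is half the baseline fluctuation SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import gamma as gamma_dist

from .errors import (
    InvalidDesignError,
    InvalidDurationError,
    InvalidMaskError,
    InvalidParameterError,
)
from .signal import SignalPatterns

logger = logging.getLogger(__name__)

__all__ = [
    "EventSchedule",
    "HRFParams",
    "HRFKernel",
    "NoiseParams",
    "Volume4D",
    "generate_schedule",
    "double_gamma_hrf",
    "generate_noise",
    "simulate_run",
]

#: simulation time step (s); events are 1 s and not TR-aligned, so runs are
#: built on this fine grid and then sampled at the TR
FINE_DT = 0.1


@dataclass(frozen=True)
class EventSchedule:
    """Onsets, types and run assignment for one simulated session."""

    events: pd.DataFrame  # columns: onset_s, duration_s, event_type, run
    n_runs: int
    run_duration: float  # seconds, common to all runs
    n_types: int

    def for_run(self, run: int) -> pd.DataFrame:
        return self.events[self.events["run"] == run].reset_index(drop=True)

    @property
    def session_duration(self) -> float:
        return self.n_runs * self.run_duration

    def to_tsv(self, path, run: int) -> None:
        """FSL-style 3-column timing file (onset, duration, event_type)."""
        self.for_run(run)[["onset_s", "duration_s", "event_type"]].to_csv(
            path, sep="\t", index=False, header=False
        )

    @staticmethod
    def read_run_tsv(path, run: int = 0) -> pd.DataFrame:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["onset_s", "duration_s", "event_type"]
        )
        df["event_type"] = df["event_type"].astype(int)
        df["run"] = run
        return df


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (seconds; ratio unitless)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0


@dataclass(frozen=True)
class HRFKernel:
    params: HRFParams
    dt: float
    samples: np.ndarray  # kernel values at multiples of dt, peak-normalized


@dataclass(frozen=True)
class NoiseParams:
    """Parametric fMRI noise: AR(1) + slow drift, spatially smoothed.

    ``sigma_system`` is the stationary temporal SD of the AR(1) component (the
    baseline-fluctuation scale percent signal change is defined against).
    """

    sigma_system: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 0.3
    drift_period_s: float = 128.0
    smooth_fwhm_mm: float = 4.0
    voxel_size_mm: float = 3.0

    def __post_init__(self):
        if self.sigma_system < 0:
            raise InvalidParameterError("sigma_system must be >= 0")
        if not (0 <= self.ar1_coef < 1):
            raise InvalidParameterError("ar1_coef must lie in [0, 1)")


@dataclass
class Volume4D:
    """An X x Y x Z x T volume with its binary mask and TR."""

    data: np.ndarray
    mask: np.ndarray
    tr: float

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]


def generate_schedule(
    n_types: int,
    repetitions: int,
    n_runs: int = 5,
    event_duration: float = 1.0,
    isi_choices=(7.0, 9.0, 11.0),
    rng: np.random.Generator = None,
    lead_in: float = 4.0,
    post_buffer: float = 20.0,
    isi_convention: str = "offset_to_onset",
) -> EventSchedule:
    """Randomized event schedule with equal per-run repetition counts.

    Each run holds ``repetitions / n_runs`` occurrences of every event type in
    a uniformly random order; consecutive events are separated by a gap drawn
    i.i.d. from ``isi_choices``.  Under the default ``offset_to_onset``
    convention the gap is measured from one event's offset to the next onset
    (an alternative ``onset_to_onset`` convention is available).  The common
    run duration covers the longest run's final event plus ``post_buffer``
    seconds so the hemodynamic tail is captured.
    """
    if rng is None:
        rng = np.random.default_rng()
    if repetitions % n_runs != 0:
        raise InvalidDesignError(
            f"repetitions ({repetitions}) must divide evenly over {n_runs} runs"
        )
    if n_types * repetitions < 1:
        raise InvalidDesignError("schedule would contain no events")
    if isi_convention not in ("offset_to_onset", "onset_to_onset"):
        raise InvalidParameterError(f"unknown ISI convention {isi_convention!r}")
    per_run = repetitions // n_runs
    isi_choices = np.asarray(sorted(isi_choices), dtype=float)
    rows = []
    longest_end = 0.0
    for run in range(n_runs):
        types = np.repeat(np.arange(n_types), per_run)
        rng.shuffle(types)
        gaps = rng.choice(isi_choices, size=len(types))
        t = lead_in
        for ev, gap in zip(types, gaps):
            rows.append((t, event_duration, int(ev), run))
            if isi_convention == "offset_to_onset":
                t += event_duration + gap
            else:
                t += max(gap, event_duration)
        longest_end = max(longest_end, rows[-1][0] + event_duration)
    run_duration = float(np.ceil(longest_end + post_buffer))
    events = pd.DataFrame(rows, columns=["onset_s", "duration_s", "event_type", "run"])
    return EventSchedule(
        events=events,
        n_runs=int(n_runs),
        run_duration=run_duration,
        n_types=int(n_types),
    )


def double_gamma_hrf(
    params: HRFParams = HRFParams(), dt: float = FINE_DT, duration: float = 32.0
) -> HRFKernel:
    """Canonical double-gamma HRF, sampled at ``dt`` and peak-normalized to 1.

    The kernel is the difference of two gamma densities: a positive response
    peaking near ``peak_delay`` seconds minus ``undershoot_ratio`` times an
    undershoot peaking near ``undershoot_delay`` seconds.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if duration < 20:
        raise InvalidParameterError("duration must cover the undershoot (>= 20 s)")
    if params.peak_dispersion <= 0 or params.undershoot_dispersion <= 0:
        raise InvalidParameterError("dispersions must be positive")
    t = np.arange(0.0, duration, dt)
    peak = gamma_dist.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = gamma_dist.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    h = peak - params.undershoot_ratio * under
    h = h / h.max()
    return HRFKernel(params=params, dt=float(dt), samples=h)


def _ar1_series(
    n_voxels: int, n_timepoints: int, sigma: float, phi: float, rng
) -> np.ndarray:
    """Stationary AR(1) series, shape (n_voxels, T), marginal SD = sigma."""
    out = np.empty((n_voxels, n_timepoints))
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    out[:, 0] = sigma * rng.standard_normal(n_voxels)
    for t in range(1, n_timepoints):
        out[:, t] = phi * out[:, t - 1] + innov_sd * rng.standard_normal(n_voxels)
    return out


def generate_noise(
    mask: np.ndarray,
    n_timepoints: int,
    noise: NoiseParams,
    rng: np.random.Generator,
    tr: float = 2.0,
) -> Volume4D:
    """Parametric noise volume: smoothed AR(1) plus slow sinusoidal drift.

    The AR(1) field is generated per voxel, spatially smoothed with a Gaussian
    of ``smooth_fwhm_mm``, and rescaled so the mean in-mask temporal SD equals
    ``sigma_system`` again (smoothing would otherwise shrink the fluctuation
    scale that percent signal change is defined against).  A cosine drift at
    ``drift_period_s`` with random per-voxel phase is added on top.  Voxels
    outside the mask are zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidMaskError("mask selects no voxels")
    if n_timepoints < 2:
        raise InvalidParameterError("need at least 2 time points")
    shape = mask.shape
    vol = np.zeros(shape + (n_timepoints,))
    if noise.sigma_system > 0:
        series = _ar1_series(
            int(np.prod(shape)), n_timepoints, noise.sigma_system, noise.ar1_coef, rng
        ).reshape(shape + (n_timepoints,))
        if noise.smooth_fwhm_mm > 0:
            sigma_vox = noise.smooth_fwhm_mm / (
                2.0 * np.sqrt(2.0 * np.log(2.0)) * noise.voxel_size_mm
            )
            series = gaussian_filter(series, sigma=(sigma_vox,) * 3 + (0.0,))
            sd = series[mask].std(axis=-1).mean()
            if sd > 0:
                series *= noise.sigma_system / sd
        vol += series
    if noise.drift_amplitude > 0:
        t = np.arange(n_timepoints) * tr
        phase = rng.uniform(0, 2 * np.pi, size=shape)
        vol += noise.drift_amplitude * np.cos(
            2 * np.pi * t / noise.drift_period_s + phase[..., None]
        )
    vol[~mask] = 0.0
    return Volume4D(data=vol, mask=mask, tr=float(tr))


def event_regressors(
    run_events: pd.DataFrame,
    hrf: HRFKernel,
    n_timepoints: int,
    tr: float,
    n_types: int,
) -> np.ndarray:
    """HRF-convolved unit-height boxcar regressors, one column per event type.

    Boxcars are built on the fine ``hrf.dt`` grid and sampled at TR onsets,
    so 1-s events need not align with the TR.  Shape (n_timepoints, n_types).
    Used both to inject signal during simulation and to build GLM design
    matrices — the forward model and the analysis model share the same
    convolution by construction.
    """
    dt = hrf.dt
    n_fine = int(np.ceil(n_timepoints * tr / dt)) + len(hrf.samples)
    reg = np.zeros((n_timepoints, n_types))
    sample_idx = np.round(np.arange(n_timepoints) * tr / dt).astype(int)
    for k in range(n_types):
        ev = run_events[run_events["event_type"] == k]
        if len(ev) == 0:
            continue
        box = np.zeros(n_fine)
        for onset, dur in zip(ev["onset_s"], ev["duration_s"]):
            i0 = int(np.round(onset / dt))
            i1 = int(np.round((onset + dur) / dt))
            box[i0:i1] += 1.0
        conv = np.convolve(box, hrf.samples)[:n_fine]
        reg[:, k] = conv[sample_idx]
    return reg


def zscore_time(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-score each in-mask voxel's time series (population SD).

    Constant series map to all zeros rather than dividing by zero.
    """
    out = np.zeros_like(data)
    m = np.asarray(mask, dtype=bool)
    x = data[m]
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    out[m] = np.where(sd > 0, (x - mu) / sd_safe, 0.0)
    return out


def simulate_run(
    run_events: pd.DataFrame,
    patterns: SignalPatterns,
    hrf: HRFKernel,
    noise: NoiseParams,
    mask: np.ndarray,
    tr: float = 2.0,
    run_duration: float = None,
    rng: np.random.Generator = None,
    zscore: bool = True,
) -> Volume4D:
    """Assemble one simulated run: signal convolution + noise + Z-scoring.

    Every ROI voxel receives a boxcar time series whose amplitude during an
    event equals that voxel's pattern value for the event's type, convolved
    with the HRF and sampled at the TR.  ROI voxels outside the brain mask are
    dropped with a warning (no signal is inserted there).
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(run_events) == 0:
        raise InvalidDesignError("run contains no events")
    mask = np.asarray(mask, dtype=bool)
    last_end = float((run_events["onset_s"] + run_events["duration_s"]).max())
    if run_duration is None:
        run_duration = last_end + 20.0
    if run_duration < last_end:
        raise InvalidDurationError(
            f"run duration {run_duration} s ends before the last event ({last_end} s)"
        )
    n_timepoints = int(np.ceil(run_duration / tr))
    vol = generate_noise(mask, n_timepoints, noise, rng, tr=tr).data

    if patterns.roi_voxels is not None and patterns.psc > 0:
        reg = event_regressors(run_events, hrf, n_timepoints, tr, patterns.n_types)
        flat_mask = mask.ravel()
        roi = np.asarray(patterns.roi_voxels)
        inside = flat_mask[roi]
        if not inside.all():
            logger.warning(
                "%d ROI voxels fall outside the brain mask; no signal inserted there",
                int((~inside).sum()),
            )
        keep = np.where(inside)[0]
        signal = reg @ patterns.patterns[:, keep]  # (T, V_kept)
        coords = np.unravel_index(roi[keep], mask.shape)
        vol[coords] += signal.T
    if zscore:
        vol = zscore_time(vol, mask)
    return Volume4D(data=vol, mask=mask, tr=float(tr))
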