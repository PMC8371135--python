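"""Raw ROI fluorescence -> trial-aligned dF/F tensors and reliability scores.

The stages mirror a standard calcium-imaging pipeline: slow-drift removal by
moving-average subtraction, dF/F normalization against the background-epoch
baseline, linear resampling of stimulus-locked epochs onto a common 10 Hz
grid, and a trial-reliability (response quality) index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .stimuli import InvalidConfigError

__all__ = [
    "RawRoiTrace",
    "NormalizedTrace",
    "TrialTensor",
    "QualityReport",
    "DegenerateTraceError",
    "UndefinedQualityError",
    "highpass_baseline",
    "delta_f_over_f",
    "epoch_and_resample",
    "response_quality_index",
    "QUALITY_THRESHOLD_DEFAULT",
    "QUALITY_THRESHOLD_DUAL_COLOR",
]

TARGET_HZ = 10.0

# response quality cutoffs: 0.5 for single-indicator recordings, 0.3 for
# dual-color data where the red indicator has lower signal-to-noise
QUALITY_THRESHOLD_DEFAULT = 0.5
QUALITY_THRESHOLD_DUAL_COLOR = 0.3


class DegenerateTraceError(ValueError):
    """Baseline so pathological that dF/F is undefined."""


class UndefinedQualityError(ValueError):
    """Quality index is 0/0 (all trials constant in time)."""


@dataclass
class RawRoiTrace:
    """A raw fluorescence time series for one ROI of one fly."""

    time: np.ndarray
    F: np.ndarray
    roi_id: str = "roi0"
    fly_id: str = "fly0"
    protocol: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if not np.all(np.isfinite(self.F)):
            raise InvalidConfigError("non-finite fluorescence")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidConfigError("time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(time=self.time, F=self.F, roi_id=self.roi_id, fly_id=self.fly_id)
        )


@dataclass
class NormalizedTrace:
    """dF/F trace together with the baseline bookkeeping."""

    time: np.ndarray
    dff: np.ndarray
    F0: float
    F_bar: float
    denominator_mode: str  # "plain" or "augmented"
    roi_id: str = "roi0"
    fly_id: str = "fly0"


@dataclass
class TrialTensor:
    """Trial x time (x condition) dF/F array on a common 10 Hz grid.

    ``data`` has shape (n_conditions, n_trials, n_time); ``conditions`` holds
    one label per leading-axis entry (bar position, (wavelength, temporal
    frequency) pair, or flash polarity), sorted.
    """

    data: np.ndarray
    time_rel: np.ndarray
    conditions: list
    condition_kind: str = ""
    roi_id: str = "roi0"
    fly_id: str = "fly0"

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def trial_average(self) -> np.ndarray:
        """Condition x time average across trials."""
        return self.data.mean(axis=1)


@dataclass
class QualityReport:
    Q_i: float
    n_trials: int
    threshold: float = QUALITY_THRESHOLD_DEFAULT

    @property
    def pass_threshold(self) -> bool:
        return self.Q_i >= self.threshold


def highpass_baseline(trace: RawRoiTrace, window_frames: int = 150) -> RawRoiTrace:
    """Remove slow baseline drift by centered moving-average subtraction.

    Subtracts the ``window_frames``-frame running mean and adds back the
    grand mean so the absolute fluorescence scale (needed for dF/F) is
    preserved. At ~10 Hz acquisition 150 frames corresponds to a cutoff
    period of roughly 15 s (~0.07 Hz).
    """
    if window_frames <= 1:
        raise InvalidConfigError("window_frames must be > 1")
    if len(trace.F) <= window_frames:
        raise InvalidConfigError("trace shorter than high-pass window")
    baseline = uniform_filter1d(trace.F, size=window_frames, mode="nearest")
    F = trace.F - baseline + trace.F.mean()
    return RawRoiTrace(trace.time, F, trace.roi_id, trace.fly_id, trace.protocol)


def _background_mask(time: np.ndarray, events: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(time), dtype=bool)
    bg = events[events["kind"] == "background"]
    for t0, t1 in zip(bg["t_start"], bg["t_end"]):
        mask |= (time >= t0) & (time < t1)
    return mask


def delta_f_over_f(
    trace: RawRoiTrace, events: pd.DataFrame, epsilon_ratio: float = 0.1
) -> NormalizedTrace:
    """Normalize fluorescence to dF/F against the background-epoch baseline.

    F0 is the mean fluorescence over all background epochs. Normally
    dF/F = (F - F0)/F0; when the baseline is close to zero
    (F0 < epsilon_ratio * mean(F)) the full-series mean is added to the
    denominator, (F - F0)/(F0 + F_bar), to avoid blow-up.
    """
    mask = _background_mask(trace.time, events)
    if not mask.any():
        raise InvalidConfigError("no background epoch overlaps the trace")
    F0 = float(trace.F[mask].mean())
    F_bar = float(trace.F.mean())
    if F0 < epsilon_ratio * F_bar:
        denom = F0 + F_bar
        mode = "augmented"
    else:
        denom = F0
        mode = "plain"
    if denom <= 0:
        raise DegenerateTraceError("non-positive dF/F denominator")
    dff = (trace.F - F0) / denom
    return NormalizedTrace(trace.time, dff, F0, F_bar, mode, trace.roi_id, trace.fly_id)


_CONDITION_COLS = {
    "bar_on": ("position",),
    "bar_off": ("position",),
    "grating": ("wavelength", "temporal_freq"),
    "flash_on": ("kind",),
    "flash_off": ("kind",),
}


def _event_condition(row: pd.Series) -> tuple:
    if row["kind"] not in _CONDITION_COLS:
        raise InvalidConfigError(
            f"epochs of kind {row['kind']!r} have no trial structure")
    cols = _CONDITION_COLS[row["kind"]]
    vals = tuple(row[c] for c in cols)
    return vals[0] if len(vals) == 1 else vals


def epoch_and_resample(
    trace: NormalizedTrace,
    events: pd.DataFrame,
    target_hz: float = TARGET_HZ,
    window_s: float | None = None,
) -> TrialTensor:
    """Cut stimulus epochs, align to onset, resample to a common grid.

    Epochs of every non-background kind are linearly interpolated onto a
    ``target_hz`` grid relative to epoch onset, grouped by condition label
    (un-shuffling the per-trial presentation order into sorted condition
    order). ``window_s`` overrides the analysis window length; by default
    the shortest epoch length is used. Epochs extending past the end of the
    trace are dropped with a warning.
    """
    stim = events[events["kind"] != "background"].copy()
    if stim.empty:
        raise InvalidConfigError("no stimulus epochs in event table")
    durations = (stim["t_end"] - stim["t_start"]).to_numpy()
    win = float(window_s) if window_s is not None else float(durations.min())
    n_samp = int(round(win * target_hz))
    time_rel = np.arange(n_samp) / target_hz

    stim["condition"] = stim.apply(_event_condition, axis=1)
    kinds = stim["kind"].unique()
    condition_kind = kinds[0] if len(kinds) == 1 else "mixed"

    t_max = trace.time[-1]
    per_condition: dict = {}
    for _, row in stim.sort_values("t_start").iterrows():
        grid = row["t_start"] + time_rel
        if grid[-1] > t_max + 1e-9:
            warnings.warn(
                f"epoch at t={row['t_start']:.2f}s extends past trace end; trial dropped",
                stacklevel=2,
            )
            continue
        vals = np.interp(grid, trace.time, trace.dff)
        per_condition.setdefault(row["condition"], []).append(vals)

    conditions = sorted(per_condition.keys())
    n_trials = min(len(v) for v in per_condition.values())
    data = np.stack(
        [np.stack(per_condition[c][:n_trials], axis=0) for c in conditions], axis=0
    )
    return TrialTensor(data, time_rel, conditions, condition_kind,
                       trace.roi_id, trace.fly_id)


def response_quality_index(
    tensor: TrialTensor, threshold: float = QUALITY_THRESHOLD_DEFAULT
) -> QualityReport:
    """Trial-reliability index: var over time of the trial average, divided
    by the trial average of the variances over time.

    Equals 1 for identical non-constant trials and ~1/n_trials for pure
    noise. Computed on the full (condition, time) response course of each
    trial, so it is independent of the stimulus structure.
    """
    if tensor.n_trials < 2:
        raise InvalidConfigError("quality index needs >= 2 trials")
    # trials x (condition*time)
    resp = np.transpose(tensor.data, (1, 0, 2)).reshape(tensor.n_trials, -1)
    within = resp.var(axis=1)
    if np.all(within == 0):
        raise UndefinedQualityError("all trials constant in time (0/0)")
    q = resp.mean(axis=0).var() / within.mean()
    return QualityReport(float(q), tensor.n_trials, threshold)
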