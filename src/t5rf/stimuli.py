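"""Visual stimulus protocols rendered as contrast fields with event tables.

Four protocols drive the whole pipeline: flashed ON/OFF bars (spatial
receptive fields), ternary bar noise (spatiotemporal receptive fields),
drifting sine gratings (spatiotemporal frequency tuning and the dendrite
model), and full-field flashes.

Contrast is signed about mid-gray: gray = 0, dark = -1, bright = +1, so
100% Michelson contrast maps to +/-1. Time grids are the 100 Hz stimulus
update grid. All shuffled protocols are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "StimulusTrace",
    "MovingGrating",
    "InvalidConfigError",
    "bar_positions",
    "build_bar_protocol",
    "build_ternary_noise",
    "build_grating_protocol",
    "build_flash_protocol",
    "DEFAULT_WAVELENGTHS_DEG",
    "DEFAULT_TEMPORAL_FREQS_HZ",
]

UPDATE_HZ = 100.0

DEFAULT_WAVELENGTHS_DEG = (2.0, 3.5, 6.0, 10.0, 18.0, 32.0)
DEFAULT_TEMPORAL_FREQS_HZ = (0.25, 0.5, 1.25, 3.0, 8.0, 16.0)


class InvalidConfigError(ValueError):
    """Raised when a protocol or model configuration is inconsistent."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Projection screen extent in degrees of visual angle.

    The default matches a square screen subtending roughly 60 x 60 degrees
    (azimuth x elevation).
    """

    azimuth_extent: float = 60.0
    elevation_extent: float = 60.0
    pixel_step: float = 1.0

    def __post_init__(self) -> None:
        if self.azimuth_extent <= 0 or self.elevation_extent <= 0:
            raise InvalidConfigError("screen extents must be positive")
        if self.pixel_step <= 0:
            raise InvalidConfigError("pixel_step must be positive")

    def extent(self, orientation: str) -> float:
        """Extent along the axis that a bar of this orientation sweeps."""
        # vertical bars vary along azimuth, horizontal bars along elevation
        if orientation == "vertical":
            return self.azimuth_extent
        if orientation == "horizontal":
            return self.elevation_extent
        raise InvalidConfigError(f"unknown orientation {orientation!r}")

    def pixel_centers(self, orientation: str) -> np.ndarray:
        ext = self.extent(orientation)
        n = int(round(ext / self.pixel_step))
        return (np.arange(n) + 0.5) * self.pixel_step


@dataclass
class StimulusTrace:
    """A rendered stimulus: contrast on a (time x space) grid plus events.

    ``space_grid`` holds element centers in degrees along the varying axis;
    ``pixel_width`` is the spatial width each element covers (pixel step for
    bar protocols, bar width for the noise stimulus). ``contrast`` has shape
    ``(len(time_grid), len(space_grid))`` with values in [-1, 1].

    The event table tiles [0, T] exactly with non-overlapping epochs.
    Columns: epoch_id, kind, trial, position, orientation, t_start, t_end
    plus protocol-specific parameter columns.
    """

    time_grid: np.ndarray
    space_grid: np.ndarray
    contrast: np.ndarray
    events: pd.DataFrame
    orientation: str = "vertical"
    pixel_width: float = 1.0

    def __post_init__(self) -> None:
        if np.abs(self.contrast).max(initial=0.0) > 1.0 + 1e-12:
            raise InvalidConfigError("contrast outside [-1, 1]")
        dt = np.diff(self.time_grid)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, dt[0])):
            raise InvalidConfigError("time grid must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    @property
    def duration(self) -> float:
        return float(self.time_grid[-1] + self.dt)

    def frame_at(self, t: float | np.ndarray) -> np.ndarray:
        """Contrast frame(s) at time t (frames held for one update period)."""
        idx = np.clip(
            np.searchsorted(self.time_grid, np.atleast_1d(t), side="right") - 1,
            0,
            len(self.time_grid) - 1,
        )
        return self.contrast[idx]

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Contrast at arbitrary times, shape (len(times), n_space)."""
        return self.frame_at(np.asarray(times, dtype=float))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_grid", data=self.time_grid)
            f.create_dataset("space_grid", data=self.space_grid)
            f.create_dataset("contrast", data=self.contrast)
            f.attrs["orientation"] = self.orientation
            f.attrs["pixel_width"] = self.pixel_width
        # events live next to the HDF5 file as CSV for portability
        self.events.to_csv(str(path) + ".events.csv", index=False)


def _check_event_tiling(events: pd.DataFrame, duration: float) -> None:
    ev = events.sort_values("t_start")
    starts = ev["t_start"].to_numpy()
    ends = ev["t_end"].to_numpy()
    if not np.all(ends > starts):
        raise InvalidConfigError("event with non-positive duration")
    if abs(starts[0]) > 1e-9 or abs(ends[-1] - duration) > 1e-9:
        raise InvalidConfigError("events do not span [0, T]")
    if not np.allclose(starts[1:], ends[:-1]):
        raise InvalidConfigError("events overlap or leave gaps")


def bar_positions(extent: float, bar_width: float = 5.0, step: float = 2.0) -> np.ndarray:
    """Centers of flashed-bar positions, bar kept fully on screen.

    First center sits at bar_width/2 from the screen edge and positions
    advance in ``step`` degree shifts: floor((extent - bar_width)/step) + 1
    positions in total.
    """
    if step <= 0:
        raise InvalidConfigError("step must be positive")
    if bar_width > extent:
        raise InvalidConfigError("screen too small for one bar")
    n = int(np.floor((extent - bar_width) / step + 1e-9)) + 1
    return bar_width / 2.0 + step * np.arange(n)


def build_bar_protocol(
    geometry: ScreenGeometry,
    polarity: str,
    orientation: str = "vertical",
    bar_width: float = 5.0,
    step: float = 2.0,
    flash_s: float = 1.0,
    isi_s: float = 1.0,
    n_trials: int = 4,
    seed: int = 0,
) -> StimulusTrace:
    """Flashed ON or OFF bars covering the screen in shuffled order.

    ON bars render +1 on a -1 background; OFF bars -1 on a +1 background.
    Each trial flashes every position once for ``flash_s`` seconds followed
    by ``isi_s`` of background, with positions shuffled per trial.
    """
    if polarity not in ("ON", "OFF"):
        raise InvalidConfigError("polarity must be 'ON' or 'OFF'")
    if bar_width < step:
        raise InvalidConfigError("bar_width must be >= step")
    if n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    positions = bar_positions(geometry.extent(orientation), bar_width, step)
    pixels = geometry.pixel_centers(orientation)
    bar_c, bg_c = (1.0, -1.0) if polarity == "ON" else (-1.0, 1.0)
    kind = "bar_on" if polarity == "ON" else "bar_off"

    rng = np.random.default_rng(seed)
    dt = 1.0 / UPDATE_HZ
    n_flash = int(round(flash_s * UPDATE_HZ))
    n_isi = int(round(isi_s * UPDATE_HZ))
    frames = []
    rows = []
    t = 0.0
    epoch_id = 0
    for trial in range(n_trials):
        order = rng.permutation(len(positions))
        for pos in positions[order]:
            frame = np.full(len(pixels), bg_c)
            frame[np.abs(pixels - pos) <= bar_width / 2.0] = bar_c
            frames.append(np.tile(frame, (n_flash, 1)))
            rows.append(
                dict(epoch_id=epoch_id, kind=kind, trial=trial, position=pos,
                     orientation=orientation, t_start=t, t_end=t + flash_s)
            )
            t += flash_s
            epoch_id += 1
            frames.append(np.full((n_isi, len(pixels)), bg_c))
            rows.append(
                dict(epoch_id=epoch_id, kind="background", trial=trial,
                     position=np.nan, orientation=orientation,
                     t_start=t, t_end=t + isi_s)
            )
            t += isi_s
            epoch_id += 1
    contrast = np.concatenate(frames, axis=0)
    time_grid = np.arange(contrast.shape[0]) * dt
    events = pd.DataFrame(rows)
    trace = StimulusTrace(time_grid, pixels, contrast, events,
                          orientation=orientation, pixel_width=geometry.pixel_step)
    _check_event_tiling(events, trace.duration)
    return trace


def build_ternary_noise(
    geometry: ScreenGeometry,
    orientation: str = "vertical",
    n_bars: int = 12,
    update_s: float = 0.1,
    duration_s: float = 600.0,
    lead_gray_s: float = 3.0,
    seed: int = 0,
) -> StimulusTrace:
    """Ternary bar noise: bars tiling the screen, contrast in {-1, 0, +1}.

    Each update, every bar independently takes black, gray or white with
    probability 1/3 each. A leading gray epoch precedes the noise.
    """
    if duration_s <= update_s:
        raise InvalidConfigError("duration_s must exceed update_s")
    extent = geometry.extent(orientation)
    bar_width = extent / n_bars
    if n_bars * bar_width > extent + 1e-9:
        raise InvalidConfigError("bars exceed screen")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s / update_s))
    n_lead = int(round(lead_gray_s / update_s))
    noise = rng.integers(-1, 2, size=(n_frames, n_bars)).astype(float)
    contrast = np.concatenate([np.zeros((n_lead, n_bars)), noise], axis=0)
    time_grid = np.arange(contrast.shape[0]) * update_s
    rows = [dict(epoch_id=0, kind="background", trial=0, position=np.nan,
                 orientation=orientation, t_start=0.0, t_end=lead_gray_s)]
    rows.append(dict(epoch_id=1, kind="noise_frame", trial=0, position=np.nan,
                     orientation=orientation, t_start=lead_gray_s,
                     t_end=lead_gray_s + duration_s))
    events = pd.DataFrame(rows)
    centers = (np.arange(n_bars) + 0.5) * bar_width
    trace = StimulusTrace(time_grid, centers, contrast, events,
                          orientation=orientation, pixel_width=bar_width)
    _check_event_tiling(events, trace.duration)
    return trace


def build_grating_protocol(
    geometry: ScreenGeometry,
    wavelengths_deg=DEFAULT_WAVELENGTHS_DEG,
    temporal_freqs_hz=DEFAULT_TEMPORAL_FREQS_HZ,
    direction: float = 0.0,
    present_s: float = 4.0,
    gap_s: float = 4.0,
    n_trials: int = 5,
    seed: int = 0,
) -> StimulusTrace:
    """Drifting sine gratings over a (wavelength x temporal frequency) grid.

    One epoch per condition pair per trial in pseudo-random order, separated
    by gray gaps. Contrast at projected coordinate u and epoch time t is
    sin(2*pi*(u/lambda - f*t)) (zero phase at u=0, t=0). The rendered field
    lives on the 1-D azimuth pixel grid (elevation = 0 slice); ``direction``
    is the motion direction in degrees, 0 = back-to-front.
    """
    wavelengths = np.asarray(wavelengths_deg, dtype=float)
    freqs = np.asarray(temporal_freqs_hz, dtype=float)
    if (wavelengths <= 0).any() or (freqs <= 0).any():
        raise InvalidConfigError("wavelengths and frequencies must be positive")
    rng = np.random.default_rng(seed)
    pixels = geometry.pixel_centers("vertical")
    u = pixels * np.cos(np.deg2rad(direction))
    dt = 1.0 / UPDATE_HZ
    n_on = int(round(present_s * UPDATE_HZ))
    n_gap = int(round(gap_s * UPDATE_HZ))
    conditions = [(lam, f) for lam in wavelengths for f in freqs]
    frames, rows = [], []
    t = 0.0
    epoch_id = 0
    for trial in range(n_trials):
        order = rng.permutation(len(conditions))
        for ci in order:
            lam, f = conditions[ci]
            rows.append(dict(epoch_id=epoch_id, kind="background", trial=trial,
                             position=np.nan, orientation="vertical",
                             wavelength=np.nan, temporal_freq=np.nan,
                             direction=np.nan, t_start=t, t_end=t + gap_s))
            frames.append(np.zeros((n_gap, len(pixels))))
            t += gap_s
            epoch_id += 1
            tt = (np.arange(n_on) * dt)[:, None]
            frames.append(np.sin(2 * np.pi * (u[None, :] / lam - f * tt)))
            rows.append(dict(epoch_id=epoch_id, kind="grating", trial=trial,
                             position=np.nan, orientation="vertical",
                             wavelength=lam, temporal_freq=f,
                             direction=direction, t_start=t, t_end=t + present_s))
            t += present_s
            epoch_id += 1
    contrast = np.concatenate(frames, axis=0)
    time_grid = np.arange(contrast.shape[0]) * dt
    events = pd.DataFrame(rows)
    trace = StimulusTrace(time_grid, pixels, contrast, events,
                          orientation="vertical", pixel_width=geometry.pixel_step)
    _check_event_tiling(events, trace.duration)
    return trace


def build_flash_protocol(
    geometry: ScreenGeometry,
    flash_s: float = 2.0,
    gap_s: float = 4.0,
    n_trials: int = 4,
) -> StimulusTrace:
    """Full-field ON and OFF flashes interleaved with gray background.

    Per trial: gray, full-field bright (+1), gray, full-field dark (-1).
    """
    if n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    pixels = geometry.pixel_centers("vertical")
    dt = 1.0 / UPDATE_HZ
    n_on = int(round(flash_s * UPDATE_HZ))
    n_gap = int(round(gap_s * UPDATE_HZ))
    frames, rows = [], []
    t = 0.0
    epoch_id = 0
    for trial in range(n_trials):
        for kind, level in (("flash_on", 1.0), ("flash_off", -1.0)):
            frames.append(np.zeros((n_gap, len(pixels))))
            rows.append(dict(epoch_id=epoch_id, kind="background", trial=trial,
                             position=np.nan, orientation="vertical",
                             t_start=t, t_end=t + gap_s))
            t += gap_s
            epoch_id += 1
            frames.append(np.full((n_on, len(pixels)), level))
            rows.append(dict(epoch_id=epoch_id, kind=kind, trial=trial,
                             position=np.nan, orientation="vertical",
                             t_start=t, t_end=t + flash_s))
            t += flash_s
            epoch_id += 1
    contrast = np.concatenate(frames, axis=0)
    time_grid = np.arange(contrast.shape[0]) * dt
    events = pd.DataFrame(rows)
    trace = StimulusTrace(time_grid, pixels, contrast, events,
                          orientation="vertical", pixel_width=geometry.pixel_step)
    _check_event_tiling(events, trace.duration)
    return trace


@dataclass(frozen=True)
class MovingGrating:
    """Analytic full-field drifting sine grating for the dendrite model.

    Contrast at point (az, el) and time t is
    sin(2*pi*(<x, u_hat>/wavelength - temporal_freq * t)), with u_hat the
    unit vector along ``direction`` (degrees, 0 = back-to-front motion,
    counter-clockwise positive). Defined for all t, so temporal filters can
    be warmed up by sampling t < 0.
    """

    wavelength: float = 24.0
    temporal_freq: float = 1.0
    direction: float = 0.0
    contrast_amp: float = 1.0

    def sample(self, points: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Contrast array of shape (len(times), n_points).

        ``points`` is (n_points, 2) of (azimuth, elevation) degrees.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        times = np.asarray(times, dtype=float)
        theta = np.deg2rad(self.direction)
        u = points[:, 0] * np.cos(theta) + points[:, 1] * np.sin(theta)
        phase = u[None, :] / self.wavelength - self.temporal_freq * times[:, None]
        return self.contrast_amp * np.sin(2 * np.pi * phase)
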