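"""Synthetic multi-fly calcium recordings with known ground-truth receptive
fields.

Every downstream stage (dF/F, tuning curves, Gaussian/DoG fits, reverse
correlation, nested statistics) gets a parameter-recovery test against data
from this module, with no external download.

Response model per ROI: the stimulus contrast field is passed through a
signed spatial kernel (difference-of-Gaussians integrated over each stimulus
element), an optional output nonlinearity (linear, OFF-rectified, or a
two-kernel ON/OFF combination), and a single-exponential calcium-indicator
low-pass filter. Fluorescence is baseline_F * (1 + r(t)) plus slow drift
(sinusoid + random walk) and white noise, sampled at the imaging frame rate.

The front end is adapted to the protocol's standing background: responses
are computed from the contrast deviation relative to the background frame
(photoreceptors and medulla interneurons adapt to standing luminance within
seconds, and the bar protocols hold their background for minutes). This
keeps the background-epoch baseline at baseline_F.

Sign conventions: contrast is bright-positive; ground-truth OFF amplitudes
(A_c > 0) are the dF/F response to a full-contrast dark bar flashed at the
receptive-field center against the protocol's bright background (the unit in
which empirical bar tuning curves are reported), so the spatial kernel is
negative at the center of an OFF receptive field. The ON component, when
present, has negative amplitudes (calcium decreases to bright bars).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .preprocess import RawRoiTrace
from .stimuli import InvalidConfigError, StimulusTrace

__all__ = [
    "DoGParams",
    "GroundTruthRF",
    "FlyCohort",
    "RFPopulation",
    "make_cohort",
    "simulate_recording",
    "bar_integral_profile",
    "spatial_kernel",
    "indicator_kernel",
    "indicator_step_attenuation",
    "expected_bar_tuning",
    "ground_truth_strf",
]

REFERENCE_BAR_WIDTH = 5.0  # degrees; the probe bar the amplitudes refer to
BAR_CONTRAST_SWING = 2.0  # bar against opposite-polarity background


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians receptive-field component.

    ``A_c`` is the response (dF/F) to the reference 5-degree bar centered on
    the receptive field; ``A_s`` the surround amplitude in the same units.
    """

    A_c: float
    A_s: float
    x0: float
    w_c: float
    w_s: float

    def __post_init__(self) -> None:
        if self.w_c <= 0 or self.w_s <= 0:
            raise InvalidConfigError("widths must be positive")
        if abs(self.A_c) <= abs(self.A_s):
            raise InvalidConfigError("|A_c| must exceed |A_s|")


@dataclass
class GroundTruthRF:
    """Ground truth for one ROI: OFF (and optional ON) receptive fields per
    bar orientation, indicator kinetics and baseline fluorescence."""

    off_v: DoGParams
    off_h: DoGParams
    on_v: DoGParams | None = None
    on_h: DoGParams | None = None
    indicator_tau: float = 0.4
    baseline_F: float = 100.0
    polarity: str = "linear"  # linear | off_rectified | on_off

    def off(self, orientation: str) -> DoGParams:
        return self.off_v if orientation == "vertical" else self.off_h

    def on(self, orientation: str) -> DoGParams | None:
        return self.on_v if orientation == "vertical" else self.on_h


@dataclass
class FlyCohort:
    """Per-fly lists of (roi_id, GroundTruthRF)."""

    flies: dict  # fly_id -> list of (roi_id, GroundTruthRF)

    def all_rois(self):
        for fly_id, rois in self.flies.items():
            for roi_id, rf in rois:
                yield fly_id, roi_id, rf

    def ground_truth_table(self):
        import pandas as pd

        rows = []
        for fly_id, roi_id, rf in self.all_rois():
            for ori in ("vertical", "horizontal"):
                p = rf.off(ori)
                rows.append(dict(fly_id=fly_id, roi_id=roi_id, orientation=ori,
                                 component="off", A_c=p.A_c, A_s=p.A_s, x0=p.x0,
                                 w_c=p.w_c, w_s=p.w_s,
                                 indicator_tau=rf.indicator_tau,
                                 polarity=rf.polarity))
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RFPopulation:
    """Distribution of ground-truth receptive-field parameters.

    Centers are normal with a fly-level random effect; widths and amplitudes
    are log-normal (fly effect on the log scale). Defaults emulate narrow OFF
    receptive fields whose 5-degree-bar tuning curves are ~7 degrees FWHM,
    positioned near the screen center.
    """

    x0_mean: float = 30.0
    x0_between_fly_sd: float = 5.0
    x0_within_fly_sd: float = 2.0
    w_c_mean: float = 4.5
    log_w_between_fly_sd: float = 0.15
    log_w_within_fly_sd: float = 0.10
    surround_width_ratio: float = 3.0
    surround_amp_ratio: float = 0.15
    A_c_mean: float = 1.0
    log_A_between_fly_sd: float = 0.2
    log_A_within_fly_sd: float = 0.15
    indicator_tau: float = 0.4
    baseline_F: float = 100.0
    polarity: str = "linear"
    on_width_scale: float = 2.5  # ON component width relative to OFF
    on_amp_scale: float = -0.4  # ON amplitude relative to A_c (negative)
    with_on_component: bool = False

    def __post_init__(self) -> None:
        for name in ("x0_between_fly_sd", "x0_within_fly_sd",
                     "log_w_between_fly_sd", "log_w_within_fly_sd",
                     "log_A_between_fly_sd", "log_A_within_fly_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if self.w_c_mean <= 0 or self.A_c_mean <= 0:
            raise InvalidConfigError("means must be positive")


def make_cohort(
    n_flies: int,
    rois_per_fly: int,
    population: RFPopulation | None = None,
    seed: int = 0,
) -> FlyCohort:
    """Draw a reproducible cohort of ground-truth receptive fields.

    Fly-level random effects shift every ROI of a fly together (supporting
    nested-statistics tests); within-fly dispersion is added per ROI.
    """
    if n_flies < 1 or rois_per_fly < 1:
        raise InvalidConfigError("need at least one fly and one ROI per fly")
    pop = population or RFPopulation()
    rng = np.random.default_rng(seed)
    flies: dict = {}
    for i in range(n_flies):
        fly_id = f"fly{i:03d}"
        fly_x0 = rng.normal(0.0, pop.x0_between_fly_sd) if pop.x0_between_fly_sd else 0.0
        fly_lw = rng.normal(0.0, pop.log_w_between_fly_sd) if pop.log_w_between_fly_sd else 0.0
        fly_la = rng.normal(0.0, pop.log_A_between_fly_sd) if pop.log_A_between_fly_sd else 0.0
        rois = []
        for j in range(rois_per_fly):
            roi_id = f"roi{j:03d}"
            w_c = pop.w_c_mean * np.exp(
                fly_lw + (rng.normal(0.0, pop.log_w_within_fly_sd)
                          if pop.log_w_within_fly_sd else 0.0))
            A_c = pop.A_c_mean * np.exp(
                fly_la + (rng.normal(0.0, pop.log_A_within_fly_sd)
                          if pop.log_A_within_fly_sd else 0.0))

            def draw_x0():
                return pop.x0_mean + fly_x0 + (
                    rng.normal(0.0, pop.x0_within_fly_sd)
                    if pop.x0_within_fly_sd else 0.0)

            def dog(x0):
                return DoGParams(A_c=A_c, A_s=pop.surround_amp_ratio * A_c,
                                 x0=x0, w_c=w_c,
                                 w_s=pop.surround_width_ratio * w_c)

            off_v, off_h = dog(draw_x0()), dog(draw_x0())
            on_v = on_h = None
            if pop.with_on_component:
                def dog_on(base: DoGParams):
                    return DoGParams(A_c=pop.on_amp_scale * A_c,
                                     A_s=pop.on_amp_scale * A_c * pop.surround_amp_ratio,
                                     x0=base.x0,
                                     w_c=pop.on_width_scale * base.w_c,
                                     w_s=pop.on_width_scale * base.w_s)
                on_v, on_h = dog_on(off_v), dog_on(off_h)
            rois.append((roi_id, GroundTruthRF(
                off_v=off_v, off_h=off_h, on_v=on_v, on_h=on_h,
                indicator_tau=pop.indicator_tau, baseline_F=pop.baseline_F,
                polarity=pop.polarity)))
        flies[fly_id] = rois
    return FlyCohort(flies)


def bar_integral_profile(
    positions: np.ndarray, x0: float, w: float, width: float
) -> np.ndarray:
    """Gaussian mass within a bar of ``width`` centered at each position,
    normalized to 1 for a bar centered on x0 (closed form via erf)."""
    positions = np.asarray(positions, dtype=float)
    half = width / 2.0

    def mass(p):
        return erf((p - x0 + half) / w) - erf((p - x0 - half) / w)

    return mass(positions) / mass(np.asarray(x0))


def spatial_kernel(dog: DoGParams, centers: np.ndarray, element_width: float) -> np.ndarray:
    """Signed contrast weights of the stimulus elements for one RF component.

    Calibrated so that the reference bar flashed at x0 against the
    opposite-polarity background (an adapted contrast step of magnitude 2)
    yields +A_c - A_s before any nonlinearity; contrast is bright-positive,
    hence the minus sign for an OFF receptive field.
    """
    def comp(A, w):
        half_el = element_width / 2.0
        half_ref = REFERENCE_BAR_WIDTH / 2.0
        el = erf((centers - dog.x0 + half_el) / w) - erf((centers - dog.x0 - half_el) / w)
        ref = erf(np.asarray(half_ref / w)) - erf(np.asarray(-half_ref / w))
        return A * el / (BAR_CONTRAST_SWING * ref)

    return -(comp(dog.A_c, dog.w_c) - comp(dog.A_s, dog.w_s))


def indicator_kernel(tau: float, dt: float, n_taus: float = 8.0) -> np.ndarray:
    """Unit-gain discrete exponential kernel of the calcium indicator."""
    if tau <= 0 or dt <= 0:
        raise InvalidConfigError("tau and dt must be positive")
    n = max(int(np.ceil(n_taus * tau / dt)), 1)
    k = np.exp(-np.arange(n) * dt / tau)
    return k / k.sum()


def indicator_step_attenuation(tau: float, dt: float, duration: float) -> float:
    """Peak of the discrete indicator filter's response to a unit step of the
    given duration (the attenuation a 1 s bar flash suffers)."""
    k = indicator_kernel(tau, dt)
    n = int(round(duration / dt))
    return float(np.cumsum(k)[min(n, len(k)) - 1]) if n < len(k) else 1.0


def _background_frame(stimulus: StimulusTrace) -> np.ndarray:
    """Contrast frame the front end is adapted to (the standing background)."""
    bg = stimulus.events[stimulus.events["kind"] == "background"]
    if bg.empty:
        return np.zeros(len(stimulus.space_grid))
    row = bg.iloc[0]
    t_mid = 0.5 * (row["t_start"] + row["t_end"])
    return stimulus.frame_at(t_mid)[0]


def _response_rate(rf: GroundTruthRF, stimulus: StimulusTrace) -> np.ndarray:
    """Noise-free dF/F-rate r(t) on the stimulus time grid."""
    s = stimulus.contrast - _background_frame(stimulus)[None, :]  # time x space
    k_off = spatial_kernel(rf.off(stimulus.orientation), stimulus.space_grid,
                           stimulus.pixel_width)
    r_off = s @ k_off
    if rf.polarity == "linear":
        r = r_off
    elif rf.polarity == "off_rectified":
        r = np.maximum(r_off, 0.0)
    elif rf.polarity == "on_off":
        on = rf.on(stimulus.orientation)
        if on is None:
            raise InvalidConfigError("on_off polarity requires an ON component")
        k_on = spatial_kernel(on, stimulus.space_grid, stimulus.pixel_width)
        r = np.maximum(r_off, 0.0) + np.minimum(s @ k_on, 0.0)
    else:
        raise InvalidConfigError(f"unknown polarity {rf.polarity!r}")
    h = indicator_kernel(rf.indicator_tau, stimulus.dt)
    return np.convolve(r, h)[: len(r)]


def simulate_recording(
    cohort: FlyCohort,
    stimulus: StimulusTrace,
    noise_sd: float = 0.05,
    drift_amplitude: float = 0.05,
    frame_rate_hz: float = 10.0,
    seed: int = 0,
) -> list[RawRoiTrace]:
    """Simulate raw fluorescence traces of every ROI in the cohort.

    F(t) = baseline_F * (1 + r(t) + white noise) + drift, with r(t) the
    indicator-filtered receptive-field response and drift a slow sinusoid
    plus a random walk, both scaled by ``drift_amplitude`` (dF/F units).
    Traces are sampled at ``frame_rate_hz`` (5-30 Hz).
    """
    if not 5.0 <= frame_rate_hz <= 30.0:
        raise InvalidConfigError("frame_rate_hz must be in [5, 30]")
    if noise_sd < 0 or drift_amplitude < 0:
        raise InvalidConfigError("noise_sd and drift_amplitude must be >= 0")
    lo = stimulus.space_grid.min() - stimulus.pixel_width
    hi = stimulus.space_grid.max() + stimulus.pixel_width
    for _, _, rf in cohort.all_rois():
        x0 = rf.off(stimulus.orientation).x0
        if not lo <= x0 <= hi:
            raise InvalidConfigError(
                f"RF center {x0:.1f} deg outside the rendered screen")
    rng = np.random.default_rng(seed)
    frame_t = np.arange(0.0, stimulus.duration - 1e-9, 1.0 / frame_rate_hz)
    traces = []
    for fly_id, roi_id, rf in cohort.all_rois():
        r = _response_rate(rf, stimulus)
        r_frames = np.interp(frame_t, stimulus.time_grid, r)
        drift = np.zeros_like(frame_t)
        if drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            period = rng.uniform(40.0, 90.0)
            walk = np.cumsum(rng.normal(0.0, 1.0, len(frame_t)))
            walk /= max(np.abs(walk).max(), 1e-12)
            drift = drift_amplitude * (
                np.sin(2 * np.pi * frame_t / period + phase) + walk
            )
        noise = rng.normal(0.0, noise_sd, len(frame_t)) if noise_sd > 0 else 0.0
        F = rf.baseline_F * (1.0 + r_frames + noise + drift)
        traces.append(RawRoiTrace(frame_t, F, roi_id=roi_id, fly_id=fly_id,
                                  protocol="synthetic"))
    return traces


def isi_mean_residue(
    tau: float, dt: float, flash_s: float, isi_s: float
) -> float:
    """Mean indicator response over the inter-stimulus interval following a
    unit-amplitude flash (the decay tail that contaminates background
    epochs), for the discrete exponential kernel."""
    h = indicator_kernel(tau, dt)
    n_flash = int(round(flash_s / dt))
    n_isi = int(round(isi_s / dt))
    u = np.zeros(n_flash + n_isi)
    u[:n_flash] = 1.0
    r = np.convolve(u, h)[: len(u)]
    return float(r[n_flash:].mean())


def expected_bar_tuning(
    rf: GroundTruthRF,
    positions: np.ndarray,
    polarity: str = "OFF",
    orientation: str = "vertical",
    bar_width: float = 5.0,
    flash_s: float = 1.0,
    stimulus_dt: float = 0.01,
    isi_s: float | None = None,
    peak_time: float | None = None,
) -> np.ndarray:
    """Closed-form noiseless bar tuning curve for a *linear* ROI.

    With the background-adapted front end, the tuning curve is the
    bar-integrated difference-of-Gaussians profile attenuated by the
    indicator's response to a ``flash_s`` step. The 5-degree probe bar
    broadens the curve relative to the underlying receptive field: the
    recoverable ground-truth width is that of this bar-convolved profile.

    When ``isi_s`` is given, the prediction also accounts for the indicator
    decay tail that contaminates the inter-stimulus background epochs: a
    1 s interval does not let a tau = 0.4 s indicator return to baseline,
    which inflates F0 by a predictable few percent and rescales/offsets the
    measured dF/F curve (real recordings carry the same bias). ``peak_time``
    caps the step attenuation at the last within-flash sample of the
    resampled trial tensor (stacking of residues across consecutive flashes,
    a second-order effect, is ignored).
    """
    if rf.polarity != "linear":
        raise InvalidConfigError("closed-form tuning curve assumes a linear ROI")
    dog = rf.off(orientation)
    prof = (
        dog.A_c * bar_integral_profile(positions, dog.x0, dog.w_c, bar_width)
        - dog.A_s * bar_integral_profile(positions, dog.x0, dog.w_s, bar_width)
    )
    att = indicator_step_attenuation(
        rf.indicator_tau, stimulus_dt, peak_time if peak_time is not None else flash_s
    )
    sign = 1.0 if polarity == "OFF" else -1.0
    curve = sign * prof * att
    if isi_s is None:
        return curve
    residue = isi_mean_residue(rf.indicator_tau, stimulus_dt, flash_s, isi_s)
    f0_bias = float(np.mean(sign * prof)) * residue
    return (curve - f0_bias) / (1.0 + f0_bias)


def ground_truth_strf(
    rf: GroundTruthRF,
    stimulus: StimulusTrace,
    lags: np.ndarray,
) -> np.ndarray:
    """Ground-truth space-time kernel (lag x position) of a linear ROI under
    the ternary-noise stimulus, on the given response lags; unit norm."""
    dog = rf.off(stimulus.orientation)
    k_space = spatial_kernel(dog, stimulus.space_grid, stimulus.pixel_width)
    dt = float(lags[1] - lags[0])
    h = indicator_kernel(rf.indicator_tau, dt)
    h_lags = np.zeros(len(lags))
    n = min(len(h), len(lags))
    h_lags[:n] = h[:n]
    k = np.outer(h_lags, k_space)
    return k / np.linalg.norm(k)
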