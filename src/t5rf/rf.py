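"""Receptive-field extraction and fitting.

Spatial tuning curves from flashed bars, single-Gaussian and
difference-of-Gaussians (center-surround) fits, spatiotemporal receptive
fields by reverse correlation against ternary noise, spatiotemporal
frequency tuning maps from drifting gratings, Cartesian-product 2-D
receptive-field maps, and cross-correlation alignment of populations of
curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from .preprocess import NormalizedTrace, TrialTensor
from .stimuli import InvalidConfigError, StimulusTrace

__all__ = [
    "TuningCurve",
    "GaussianFit",
    "DoGFit",
    "FitRejection",
    "Strf",
    "FreqTuningMap",
    "CartesianRFMap",
    "fwhm_from_w",
    "bar_tuning_curve",
    "fit_gaussian",
    "fit_difference_of_gaussians",
    "strf_reverse_correlation",
    "freq_tuning_map",
    "fourier_amplitude",
    "cartesian_rf_map",
    "align_by_crosscorr",
    "apply_shift",
]


def fwhm_from_w(w: float) -> float:
    """Full width at half maximum of exp(-(x-x0)^2 / w^2): 2*w*sqrt(log 2)."""
    return 2.0 * w * np.sqrt(np.log(2.0))


@dataclass
class TuningCurve:
    """Signed response amplitude per bar position."""

    positions: np.ndarray
    amplitudes: np.ndarray
    orientation: str = "vertical"
    polarity: str = ""
    summary_mode: str = "max_abs"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise InvalidConfigError("positions must be strictly increasing")
        if len(self.positions) != len(self.amplitudes):
            raise InvalidConfigError("one amplitude per position required")


@dataclass
class GaussianFit:
    """f(x) = A * exp(-(x - x0)^2 / w^2)."""

    A: float
    x0: float
    w: float
    r2: float

    @property
    def fwhm(self) -> float:
        return fwhm_from_w(self.w)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.A * np.exp(-((np.asarray(x) - self.x0) ** 2) / self.w**2)


@dataclass
class DoGFit:
    """f(x) = sign * [A_c exp(-(x-x0)^2/w_c^2) - A_s exp(-(x-x0)^2/w_s^2)].

    Center and surround share the location x0. Amplitudes are reported as
    magnitudes with A_c > A_s >= 0; ``sign`` is -1 when the curve extremum is
    negative (ON receptive fields measured as calcium decreases).
    """

    A_c: float
    A_s: float
    x0: float
    w_c: float
    w_s: float
    r2: float
    sign: float = 1.0

    @property
    def fwhm_c(self) -> float:
        return fwhm_from_w(self.w_c)

    @property
    def fwhm_s(self) -> float:
        return fwhm_from_w(self.w_s)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        return self.sign * (
            self.A_c * np.exp(-((x - self.x0) ** 2) / self.w_c**2)
            - self.A_s * np.exp(-((x - self.x0) ** 2) / self.w_s**2)
        )


@dataclass
class FitRejection:
    reason: str
    r2: float = np.nan


def bar_tuning_curve(tensor: TrialTensor, summary_mode: str = "max_abs") -> TuningCurve:
    """Collapse a bar-protocol trial tensor into a position tuning curve.

    Trials are averaged first; each position's amplitude is the signed
    extremum of the trial-averaged response within the flash window
    (``max_abs``), or the window mean (``epoch_mean``, used for flash
    response amplitudes).
    """
    if tensor.condition_kind not in ("bar_on", "bar_off", "mixed", ""):
        raise InvalidConfigError("tensor conditions are not bar positions")
    avg = tensor.trial_average()  # condition x time
    if summary_mode == "max_abs":
        idx = np.argmax(np.abs(avg), axis=1)
        amps = avg[np.arange(avg.shape[0]), idx]
    elif summary_mode == "epoch_mean":
        amps = avg.mean(axis=1)
    else:
        raise InvalidConfigError(f"unknown summary mode {summary_mode!r}")
    positions = np.asarray(tensor.conditions, dtype=float)
    polarity = {"bar_on": "ON", "bar_off": "OFF"}.get(tensor.condition_kind, "")
    return TuningCurve(positions, amps, polarity=polarity, summary_mode=summary_mode)


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return 1.0 - np.sum(resid**2) / ss_tot


def fit_gaussian(curve: TuningCurve, r2_min: float = 0.2) -> GaussianFit | FitRejection:
    """Least-squares single-Gaussian fit of a tuning curve.

    Initialization: x0 at the absolute extremum, A the signed extremum, w an
    empirical half-width. The amplitude sign is free, so one call fits both
    OFF (positive) and ON (negative) curves. Fits with r^2 below ``r2_min``
    are rejected.
    """
    x, y = curve.positions, curve.amplitudes
    if len(x) < 4:
        return FitRejection("fewer than 4 points")
    i_peak = int(np.argmax(np.abs(y)))
    a0 = y[i_peak]
    if a0 == 0:
        return FitRejection("all-zero curve", r2=0.0)
    above = np.abs(y) >= np.abs(a0) / 2
    w0 = max((x[above].max() - x[above].min()) / fwhm_from_w(1.0), np.diff(x).min())
    span = x.max() - x.min()

    model = lmfit.Model(lambda x, A, x0, w: A * np.exp(-((x - x0) ** 2) / w**2))
    params = model.make_params(A=a0, x0=x[i_peak], w=w0)
    params["w"].set(min=1e-3, max=10 * span)
    params["x0"].set(min=x.min() - span, max=x.max() + span)
    try:
        res = model.fit(y, params, x=x)
    except Exception as exc:  # lmfit raises on pathological inputs
        return FitRejection(f"optimizer failure: {exc}")
    if not res.success:
        return FitRejection("optimizer did not converge")
    r2 = _r_squared(y, res.residual)
    if r2 < r2_min:
        return FitRejection(f"r2={r2:.3f} below threshold {r2_min}", r2=r2)
    p = res.params
    return GaussianFit(float(p["A"]), float(p["x0"]), abs(float(p["w"])), r2)


def _dog_model(x, A_c, rho, x0, w_c, w_s):
    return A_c * np.exp(-((x - x0) ** 2) / w_c**2) - rho * A_c * np.exp(
        -((x - x0) ** 2) / w_s**2
    )


def fit_difference_of_gaussians(
    curve: TuningCurve, r2_min: float = 0.2
) -> DoGFit | FitRejection:
    """Bounded least-squares difference-of-Gaussians (center-surround) fit.

    Constraints: center and surround share x0, A_c > A_s >= 0 (enforced by
    fitting A_s = rho * A_c with rho in [0, 1)), and both amplitudes stay
    below twice the amplitude range of the data. A failed first attempt is
    re-initialized once with a wider surround before rejection.
    """
    x, y = curve.positions, curve.amplitudes
    if len(x) < 6:
        return FitRejection("fewer than 6 points")
    i_peak = int(np.argmax(np.abs(y)))
    sign = 1.0 if y[i_peak] >= 0 else -1.0
    yy = sign * y
    rng_amp = y.max() - y.min()
    if rng_amp == 0:
        return FitRejection("all-constant curve", r2=0.0)
    above = yy >= yy[i_peak] / 2
    w0 = max((x[above].max() - x[above].min()) / fwhm_from_w(1.0), np.diff(x).min())
    span = x.max() - x.min()

    model = lmfit.Model(_dog_model)

    def attempt(w_s_factor: float):
        params = model.make_params(
            A_c=yy[i_peak], rho=0.2, x0=x[i_peak], w_c=w0, w_s=w_s_factor * w0
        )
        params["A_c"].set(min=1e-12, max=2 * rng_amp)
        params["rho"].set(min=0.0, max=1.0 - 1e-6)
        params["x0"].set(min=x.min() - span, max=x.max() + span)
        params["w_c"].set(min=1e-3, max=10 * span)
        params["w_s"].set(min=1e-3, max=20 * span)
        try:
            return model.fit(yy, params, x=x)
        except Exception:
            return None

    res = attempt(3.0)
    if res is None or not res.success:
        res = attempt(6.0)
    if res is None or not res.success:
        return FitRejection("optimizer did not converge after re-initialization")
    r2 = _r_squared(yy, res.residual)
    if r2 < r2_min:
        return FitRejection(f"r2={r2:.3f} below threshold {r2_min}", r2=r2)
    p = res.params
    a_c = float(p["A_c"])
    return DoGFit(
        A_c=a_c,
        A_s=float(p["rho"]) * a_c,
        x0=float(p["x0"]),
        w_c=abs(float(p["w_c"])),
        w_s=abs(float(p["w_s"])),
        r2=r2,
        sign=sign,
    )


@dataclass
class Strf:
    """Spatiotemporal receptive field k(x, tau) with unit Euclidean norm."""

    k: np.ndarray  # lag x position
    lags: np.ndarray
    positions: np.ndarray
    spatial_fit: GaussianFit | FitRejection | None = None

    @property
    def peak_index(self) -> tuple[int, int]:
        return np.unravel_index(np.argmax(np.abs(self.k)), self.k.shape)

    @property
    def spatial_slice(self) -> np.ndarray:
        return self.k[self.peak_index[0], :]

    @property
    def temporal_slice(self) -> np.ndarray:
        return self.k[:, self.peak_index[1]]


def strf_reverse_correlation(
    response: NormalizedTrace,
    stimulus: StimulusTrace,
    max_lag_s: float = 2.0,
    fit_spatial: bool = True,
    r2_min: float = 0.2,
    normalize: bool = True,
) -> Strf:
    """Estimate the linear spatiotemporal filter by reverse correlation.

    k(x, tau) = 1/(T - tau) * sum_{t >= tau} r(t) * s(x, t - tau): the
    fluorescence-weighted average stimulus, computed on the response time
    grid (each 100 ms noise frame held constant between updates). The result
    is normalized to unit Euclidean norm (``normalize=False`` keeps the raw
    scale, useful for noise-floor diagnostics), and 1-D spatial/temporal
    slices are taken through the point of maximum |k|; the spatial slice is
    fitted with a single Gaussian.
    """
    t = response.time
    dt = np.median(np.diff(t))
    n_lags = int(round(max_lag_s / dt)) + 1
    if n_lags >= len(t):
        raise InvalidConfigError("max_lag_s exceeds record length")
    s = stimulus.sample(t)  # time x space
    r = response.dff
    n = len(t)
    k = np.empty((n_lags, s.shape[1]))
    for j in range(n_lags):
        # r(t) weighted average of the stimulus j samples earlier
        k[j] = r[j:] @ s[: n - j] / (n - j)
    if normalize:
        norm = np.linalg.norm(k)
        if norm > 0:
            k = k / norm
    lags = np.arange(n_lags) * dt
    strf = Strf(k, lags, stimulus.space_grid)
    if fit_spatial:
        curve = TuningCurve(stimulus.space_grid, strf.spatial_slice)
        strf.spatial_fit = fit_gaussian(curve, r2_min=r2_min)
    return strf


def fourier_amplitude(trace: np.ndarray, rate_hz: float, freq_hz: float) -> float:
    """Amplitude of the Fourier component of ``trace`` at ``freq_hz``.

    Amplitude-normalized convention (2/N one-sided), so a unit sinusoid at
    ``freq_hz`` yields 1. The mean is removed first, making the measure
    invariant to constant offsets. Computed as a direct projection onto
    exp(-2*pi*i*f*t), so ``freq_hz`` need not be a DFT bin.
    """
    x = np.asarray(trace, dtype=float)
    x = x - x.mean()
    n = len(x)
    tt = np.arange(n) / rate_hz
    coef = np.sum(x * np.exp(-2j * np.pi * freq_hz * tt))
    return float(2.0 * np.abs(coef) / n)


@dataclass
class FreqTuningMap:
    """Response amplitude on the (wavelength x temporal frequency) grid."""

    amplitudes: np.ndarray  # wavelength x temporal frequency
    wavelengths: np.ndarray
    temporal_freqs: np.ndarray
    scaled: bool = False

    def scale_by_max(self) -> "FreqTuningMap":
        m = np.nanmax(self.amplitudes)
        if m <= 0:
            raise InvalidConfigError("cannot scale an all-zero map")
        return FreqTuningMap(
            self.amplitudes / m, self.wavelengths, self.temporal_freqs, scaled=True
        )

    def flatten_valid(self) -> np.ndarray:
        vals = self.amplitudes.ravel()
        return vals[np.isfinite(vals)]


def freq_tuning_map(tensor: TrialTensor, rate_hz: float = 10.0) -> FreqTuningMap:
    """Spatiotemporal frequency tuning from a grating trial tensor.

    For every (wavelength, temporal frequency) condition, the amplitude of
    the Fourier component of the trial-averaged response at the grating's
    temporal frequency over the presentation window. Conditions whose
    frequency cannot be resolved (less than one full cycle in the window, or
    at/above the Nyquist frequency of the response grid) are flagged NaN.
    """
    if tensor.condition_kind != "grating":
        raise InvalidConfigError("tensor conditions are not gratings")
    conds = tensor.conditions
    wavelengths = np.array(sorted({c[0] for c in conds}))
    freqs = np.array(sorted({c[1] for c in conds}))
    avg = tensor.trial_average()
    window = tensor.time_rel[-1] + 1.0 / rate_hz
    amps = np.full((len(wavelengths), len(freqs)), np.nan)
    for ci, (lam, f) in enumerate(conds):
        i = np.searchsorted(wavelengths, lam)
        j = np.searchsorted(freqs, f)
        if f * window < 1.0 or f >= rate_hz / 2.0:
            continue  # unresolvable condition stays NaN
        amps[i, j] = fourier_amplitude(avg[ci], rate_hz, f)
    return FreqTuningMap(amps, wavelengths, freqs)


@dataclass
class CartesianRFMap:
    """Outer product of two orthogonal 1-D receptive fields.

    ``category`` labels each cell by the sign pair of its factors:
    both_positive, both_negative, or mixed_sign (zero where either factor
    vanishes).
    """

    values: np.ndarray
    category: np.ndarray
    h_positions: np.ndarray
    v_positions: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def cartesian_rf_map(
    rf_h: np.ndarray, rf_v: np.ndarray,
    h_positions: np.ndarray | None = None,
    v_positions: np.ndarray | None = None,
) -> CartesianRFMap:
    """2-D receptive-field visualization as the Cartesian product of two
    orthogonal 1-D profiles: value(i, j) = rf_h(i) * rf_v(j)."""
    rf_h = np.asarray(rf_h, dtype=float)
    rf_v = np.asarray(rf_v, dtype=float)
    values = np.outer(rf_h, rf_v)
    sh = np.sign(rf_h)[:, None]
    sv = np.sign(rf_v)[None, :]
    category = np.full(values.shape, "mixed_sign", dtype=object)
    category[(sh > 0) & (sv > 0)] = "both_positive"
    category[(sh < 0) & (sv < 0)] = "both_negative"
    category[(sh == 0) | (sv == 0)] = "zero"
    if h_positions is None:
        h_positions = np.arange(len(rf_h), dtype=float)
    if v_positions is None:
        v_positions = np.arange(len(rf_v), dtype=float)
    return CartesianRFMap(values, category, np.asarray(h_positions),
                          np.asarray(v_positions))


def apply_shift(curve: np.ndarray, shift: int) -> np.ndarray:
    """Shift a curve by ``shift`` samples with zero padding (non-circular)."""
    out = np.zeros_like(np.asarray(curve, dtype=float))
    n = len(out)
    if shift >= 0:
        out[shift:] = curve[: n - shift]
    else:
        out[:shift] = curve[-shift:]
    return out


def _best_shift(template: np.ndarray, curve: np.ndarray) -> int:
    """Integer shift s maximizing corr(template, apply_shift(curve, s))."""
    xc = np.correlate(template, curve, mode="full")
    # lag index l corresponds to shift s = l - (n - 1)
    return int(np.argmax(xc)) - (len(curve) - 1)


def align_by_crosscorr(curves: list[np.ndarray]) -> list[int]:
    """Integer shifts aligning curves by maximizing cross-correlation.

    The first curve seeds a running template; each subsequent curve is
    shifted to best match the template (zero-padded, non-circular), then
    folded into the template as the mean of the aligned curves so far.
    All-zero curves get shift 0 with a warning.
    """
    if len(curves) < 2:
        raise InvalidConfigError("alignment needs at least 2 curves")
    n = len(curves[0])
    if any(len(c) != n for c in curves):
        raise InvalidConfigError("curves must share a common grid")
    template = np.asarray(curves[0], dtype=float).copy()
    shifts = [0]
    aligned = [template.copy()]
    for c in curves[1:]:
        c = np.asarray(c, dtype=float)
        if not np.any(c):
            warnings.warn("all-zero curve in alignment; shift set to 0", stacklevel=2)
            shifts.append(0)
            aligned.append(c)
        else:
            s = _best_shift(template, c)
            shifts.append(s)
            aligned.append(apply_shift(c, s))
        template = np.mean(aligned, axis=0)
    return shifts
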