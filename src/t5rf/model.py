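"""Passive-dendrite model of the T5 direction-selective cell.

A hexagonal array of visual sampling points (one ommatidium column plus six
neighbors, 5 degrees apart) feeds linear-nonlinear (LN) front ends standing
for the medulla input neurons Tm9, Tm1, Tm2, Tm4 (cholinergic, excitatory)
and CT1 (GABAergic, inhibitory). Each LN front end is a spatial
difference-of-Gaussians, a temporal low- or high-pass filter, an alpha
synapse, an output nonlinearity (linear or OFF-rectified) and a fixed offset
keeping conductances in [0, 1]. The conductances drive a passive cable
(the T5 dendrite): Tm9 from the trailing column near the tip, Tm1/Tm2/Tm4
from the central column at the center, CT1 from the leading column near the
base. Voltage is read out at the dendrite base; calcium is modelled as the
squared positively-rectified voltage deflection. Direction selectivity is
the normalized vector sum of response amplitudes over motion directions.

The OFF-positive sign convention holds throughout the LN stage: the
pre-nonlinearity signal is positive for dark (OFF) contrast, so
OFF-rectification is max(., 0).

Temporal filter shapes and spatial widths of the input neurons are not fully
constrained by published measurements; the defaults here are plausible
placeholders and are fully configurable. Qualitative model behaviour
(direction selectivity of all variants; contrast opponency only with linear
inputs) is what the defaults are expected to support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import lapack, solve_banded
from scipy.signal import fftconvolve

from .stimuli import InvalidConfigError, MovingGrating
from .rf import fourier_amplitude

__all__ = [
    "HexArray",
    "CellTypeSpec",
    "CableParams",
    "ModelConfig",
    "SimResult",
    "VARIANTS",
    "default_config",
    "temporal_filter_kernel",
    "alpha_kernel",
    "ln_front_end",
    "assemble_drives",
    "simulate_dendrite",
    "cable_steady_state",
    "calcium_transform",
    "response_amplitude",
    "direction_sweep",
    "dsi",
]

E_EXC_MV = 0.0
E_INH_MV = -70.0
G_AMP_EXC_US = 2.49e-5
G_AMP_INH_US = 4.98e-4


@dataclass(frozen=True)
class HexArray:
    """Central visual sampling point plus six neighbors at ``spacing``.

    The preferred-direction (PD) axis runs along ``pd_direction`` (degrees);
    the trailing column sits opposite the PD vector (the grating reaches it
    first for PD motion), the leading column along it.
    """

    spacing: float = 5.0
    pd_direction: float = 0.0

    @property
    def points(self) -> np.ndarray:
        angles = np.deg2rad(self.pd_direction + 60.0 * np.arange(6))
        ring = self.spacing * np.stack([np.cos(angles), np.sin(angles)], axis=1)
        return np.vstack([[0.0, 0.0], ring])

    def column(self, label: str) -> np.ndarray:
        theta = np.deg2rad(self.pd_direction)
        u = np.array([np.cos(theta), np.sin(theta)])
        if label == "central":
            return np.zeros(2)
        if label == "leading":
            return self.spacing * u
        if label == "trailing":
            return -self.spacing * u
        raise InvalidConfigError(f"unknown column {label!r}")


@dataclass(frozen=True)
class CellTypeSpec:
    """LN front end plus synapse for one input neuron type."""

    name: str
    temporal_kind: str  # low_pass | high_pass
    tau_filter: float
    output_fn: str  # linear | off_rectified
    synapse_sign: str  # excitatory | inhibitory
    weight: float  # synaptic-count proportion
    site: str  # tip | center | base
    column: str  # trailing | central | leading
    dog_center_w: float = 3.0  # deg, exp(-d^2/w^2); FWHM ~5 deg
    dog_surround_w: float = 9.0
    dog_surround_amp: float = 0.1  # relative to center amplitude 1
    offset: float = 0.5  # conductance fraction added after the nonlinearity
    gain: float = 0.5  # scales the unit-bounded LN signal before the offset
    alpha_rise: float = 0.001  # s
    alpha_decay: float = 0.010  # s

    def __post_init__(self) -> None:
        if self.tau_filter <= 0:
            raise InvalidConfigError("tau_filter must be positive")
        if self.weight < 0:
            raise InvalidConfigError("weight must be >= 0")
        if not 0.0 <= self.offset <= 1.0:
            raise InvalidConfigError("offset must lie in [0, 1]")

    @property
    def E_rev(self) -> float:
        return E_EXC_MV if self.synapse_sign == "excitatory" else E_INH_MV

    @property
    def g_amp(self) -> float:
        return G_AMP_EXC_US if self.synapse_sign == "excitatory" else G_AMP_INH_US


@dataclass(frozen=True)
class CableParams:
    """Passive cable of the T5 dendrite (sealed ends)."""

    length_um: float = 13.3
    diameter_um: float = 0.2
    Ra_ohm_cm: float = 100.0
    Cm_uF_cm2: float = 1.0
    g_m_S_cm2: float = 1.03e-4
    E_leak_mV: float = -65.0
    n_compartments: int = 101
    tip_fraction: float = 0.95
    center_fraction: float = 0.5
    base_fraction: float = 0.05
    readout_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.length_um, self.diameter_um, self.Ra_ohm_cm,
               self.Cm_uF_cm2, self.g_m_S_cm2) <= 0:
            raise InvalidConfigError("cable physical parameters must be positive")
        for f in (self.tip_fraction, self.center_fraction, self.base_fraction,
                  self.readout_fraction):
            if not 0.0 <= f <= 1.0:
                raise InvalidConfigError("site fractions must lie in [0, 1]")

    def compartment_of(self, fraction: float) -> int:
        return min(int(fraction * self.n_compartments), self.n_compartments - 1)

    @property
    def site_compartments(self) -> dict:
        return {
            "tip": self.compartment_of(self.tip_fraction),
            "center": self.compartment_of(self.center_fraction),
            "base": self.compartment_of(self.base_fraction),
        }

    # membrane/axial conductances in uS, capacitance in uF
    @property
    def compartment_area_cm2(self) -> float:
        L_cm = self.length_um * 1e-4
        d_cm = self.diameter_um * 1e-4
        return np.pi * d_cm * L_cm / self.n_compartments

    @property
    def g_leak_uS(self) -> float:
        return self.g_m_S_cm2 * self.compartment_area_cm2 * 1e6

    @property
    def c_uF(self) -> float:
        return self.Cm_uF_cm2 * self.compartment_area_cm2

    @property
    def g_axial_uS(self) -> float:
        d_cm = self.diameter_um * 1e-4
        dx_cm = self.length_um * 1e-4 / self.n_compartments
        return (np.pi * d_cm**2 / 4.0) / (self.Ra_ohm_cm * dx_cm) * 1e6


def _default_cell_types() -> tuple[CellTypeSpec, ...]:
    # weights follow the proportions of synaptic counts onto T5: Tm9 is the
    # most numerous input, CT1 carries all the inhibition
    return (
        CellTypeSpec("Tm9", "low_pass", 0.2, "off_rectified", "excitatory",
                     0.35, "tip", "trailing"),
        CellTypeSpec("Tm1", "high_pass", 0.06, "off_rectified", "excitatory",
                     0.25, "center", "central"),
        CellTypeSpec("Tm2", "high_pass", 0.06, "off_rectified", "excitatory",
                     0.20, "center", "central"),
        CellTypeSpec("Tm4", "high_pass", 0.06, "off_rectified", "excitatory",
                     0.20, "center", "central"),
        # CT1 is the slowest element of the OFF pathway; its time constant is
        # set so the leading-site inhibition arrives coincident with the
        # central excitation (null suppression) rather than in the ON
        # half-cycle at the modelled grating speed
        CellTypeSpec("CT1", "low_pass", 0.8, "off_rectified", "inhibitory",
                     1.0, "base", "leading"),
    )


VARIANTS = {
    "all_rectified": (),
    "tm9_linear": ("Tm9",),
    "tm9_tm2_linear": ("Tm9", "Tm2"),
    "all_three_linear": ("Tm9", "Tm2", "CT1"),
}


@dataclass
class ModelConfig:
    """Full dendrite-model specification."""

    cell_types: tuple[CellTypeSpec, ...] = field(default_factory=_default_cell_types)
    cable: CableParams = field(default_factory=CableParams)
    hex_array: HexArray = field(default_factory=HexArray)
    IE_ratio: float = 55.0
    ie_mode: str = "multiplier"  # multiplier | raw
    dt: float = 1e-4  # solver step, s
    dt_ln: float = 1e-3  # LN front-end grid, s
    variant_name: str = "all_rectified"

    def __post_init__(self) -> None:
        if self.IE_ratio <= 0:
            raise InvalidConfigError("IE_ratio must be positive")
        if self.dt > 5e-4:
            raise InvalidConfigError("solver dt must be <= 0.5 ms")
        sites = {c.site for c in self.cell_types}
        if sites != {"tip", "center", "base"}:
            raise InvalidConfigError("all three sites (tip/center/base) must be populated")


def default_config(variant: str = "all_rectified", **overrides) -> ModelConfig:
    """Named model variants: which inputs use a linear output function."""
    if variant not in VARIANTS:
        raise InvalidConfigError(f"unknown variant {variant!r}")
    linear = VARIANTS[variant]
    cells = tuple(
        replace(c, output_fn="linear" if c.name in linear else "off_rectified")
        for c in _default_cell_types()
    )
    return ModelConfig(cell_types=cells, variant_name=variant, **overrides)


def temporal_filter_kernel(kind: str, tau: float, time_grid: np.ndarray) -> np.ndarray:
    """Pointwise temporal filters of the input neurons.

    Low-pass  f_LP(t) = 2 tau^(-3/2) t e^(-t/tau); high-pass
    f_HP(t) = 2 tau^(-3/2) (tau - t) e^(-t/tau). The kernel is truncated
    where it falls below 1e-6 of its peak magnitude.
    """
    if tau <= 0:
        raise InvalidConfigError("tau must be positive")
    t = np.asarray(time_grid, dtype=float)
    if t[0] != 0:
        raise InvalidConfigError("time grid must start at 0")
    if kind == "low_pass":
        k = 2.0 * tau**-1.5 * t * np.exp(-t / tau)
    elif kind == "high_pass":
        k = 2.0 * tau**-1.5 * (tau - t) * np.exp(-t / tau)
    else:
        raise InvalidConfigError(f"unknown temporal kind {kind!r}")
    peak = np.abs(k).max()
    if peak > 0:
        nz = np.nonzero(np.abs(k) >= 1e-6 * peak)[0]
        k = k[: nz[-1] + 1]
    return k


def alpha_kernel(rise: float, decay: float, dt: float) -> np.ndarray:
    """Two-time-constant (alpha) synaptic kernel, normalized to unit area."""
    if not 0 < rise < decay:
        raise InvalidConfigError("need 0 < rise < decay")
    t = np.arange(0.0, 8.0 * decay, dt)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / (k.sum() * 1.0)


def _dog_weights(spec: CellTypeSpec, location: np.ndarray):
    """Spatial DoG sampling grid and weights around a hex-array point,
    normalized to unit absolute mass (keeps the spatial signal in [-1, 1])."""
    step = min(1.0, spec.dog_center_w / 3.0)
    span = 3.0 * spec.dog_surround_w
    ax = np.arange(-span, span + step / 2, step)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    d2 = gx**2 + gy**2
    w = np.exp(-d2 / spec.dog_center_w**2) - spec.dog_surround_amp * np.exp(
        -d2 / spec.dog_surround_w**2
    )
    pts = np.stack([gx.ravel() + location[0], gy.ravel() + location[1]], axis=1)
    w = w.ravel()
    w = w / np.abs(w).sum()
    keep = np.abs(w) > 1e-6 * np.abs(w).max()  # prune negligible samples
    return pts[keep], w[keep]


def ln_front_end(
    stimulus,
    spec: CellTypeSpec,
    location: np.ndarray,
    times: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Conductance fraction in [0, 1] of one LN input neuron.

    Pipeline: DoG spatial integral at ``location`` -> temporal filter
    (L1-normalized) -> alpha synapse (unit area) -> sign flip to the
    OFF-positive convention -> output nonlinearity -> gain and offset.
    ``stimulus`` is anything with ``sample(points, times)`` (an analytic
    moving grating, or a rendered trace via an adapter). The temporal
    convolution is warmed up by sampling the stimulus before ``times[0]``,
    so the returned trace has no onset edge artifact.
    """
    times = np.asarray(times, dtype=float)
    k_t = temporal_filter_kernel(spec.temporal_kind, spec.tau_filter,
                                 np.arange(0.0, 20 * spec.tau_filter, dt))
    k_t = k_t / np.abs(k_t).sum()  # L1 norm: |filtered| <= |input|
    k_a = alpha_kernel(spec.alpha_rise, spec.alpha_decay, dt)
    n_hist = len(k_t) + len(k_a) - 2
    t_ext = times[0] + dt * np.arange(-n_hist, 0)
    pts, w = _dog_weights(spec, np.asarray(location, dtype=float))
    t_all = np.concatenate([t_ext, times])
    if isinstance(stimulus, MovingGrating):
        # spatial integral of a sinusoid is a sinusoid: collapse the DoG sum
        # into one complex weight (exact, avoids the dense space-time sample)
        theta = np.deg2rad(stimulus.direction)
        u = pts[:, 0] * np.cos(theta) + pts[:, 1] * np.sin(theta)
        z = np.sum(w * np.exp(2j * np.pi * u / stimulus.wavelength))
        sig = stimulus.contrast_amp * np.imag(
            z * np.exp(-2j * np.pi * stimulus.temporal_freq * t_all)
        )
    else:
        s = stimulus.sample(pts, t_all)  # time x points
        sig = s @ w  # spatial signal in [-1, 1]
    sig = fftconvolve(fftconvolve(sig, k_t), k_a)[n_hist: n_hist + len(times)]
    sig = -sig  # OFF-positive: dark contrast drives the signal positive
    if spec.output_fn == "off_rectified":
        sig = np.maximum(sig, 0.0)
    elif spec.output_fn != "linear":
        raise InvalidConfigError(f"unknown output_fn {spec.output_fn!r}")
    g = spec.offset + spec.gain * sig
    if g.min() < -1e-9 or g.max() > 1.0 + 1e-9:
        import warnings

        warnings.warn("LN conductance clipped to [0, 1]", stacklevel=2)
    return np.clip(g, 0.0, 1.0)


@dataclass
class DriveSet:
    """Per-site synaptic drives plus the inhibition scaling used."""

    by_site: dict  # site -> [(g_uS trace, E_rev_mV), ...]
    inh_scale: float = 1.0


def assemble_drives(
    config: ModelConfig, stimulus, times: np.ndarray
) -> DriveSet:
    """Weighted synaptic conductance drives for every dendritic site.

    Each cell type's LN output is scaled by its synaptic weight and the
    fixed conductance amplitude (2.49e-5 uS excitatory, 4.98e-4 uS
    inhibitory). In ``multiplier`` mode the total inhibitory drive is then
    rescaled so that its peak equals IE_ratio times the peak total
    excitatory conductance over this simulation — the
    inhibition-to-excitation ratio is the model's one free parameter. In
    ``raw`` mode the printed amplitudes are used as-is.
    """
    exc, inh = [], []
    for spec in config.cell_types:
        if spec.weight == 0:
            g = np.zeros(len(times))
        else:
            loc = config.hex_array.column(spec.column)
            g = ln_front_end(stimulus, spec, loc, times, config.dt_ln) * (
                spec.weight * spec.g_amp
            )
        (exc if spec.synapse_sign == "excitatory" else inh).append((spec, g))
    peak_exc = np.sum([g for _, g in exc], axis=0).max() if exc else 0.0
    peak_inh = np.sum([g for _, g in inh], axis=0).max() if inh else 0.0
    if config.ie_mode == "multiplier" and peak_inh > 0 and peak_exc > 0:
        scale = config.IE_ratio * peak_exc / peak_inh
    elif config.ie_mode in ("multiplier", "raw"):
        scale = 1.0
    else:
        raise InvalidConfigError(f"unknown ie_mode {config.ie_mode!r}")
    by_site: dict = {"tip": [], "center": [], "base": []}
    for spec, g in exc:
        by_site[spec.site].append((g, spec.E_rev))
    for spec, g in inh:
        by_site[spec.site].append((g * scale, spec.E_rev))
    return DriveSet(by_site, scale)


def _banded_matrices(cable: CableParams):
    n = cable.n_compartments
    g_a = cable.g_axial_uS
    diag = np.full(n, cable.g_leak_uS)
    diag[1:-1] += 2 * g_a
    diag[0] += g_a
    diag[-1] += g_a  # sealed ends: one axial neighbor at the boundaries
    off = np.full(n - 1, -g_a)
    return diag, off


def cable_steady_state(cable: CableParams, point_conductances) -> np.ndarray:
    """Steady-state voltage profile under constant point conductances.

    ``point_conductances`` is a list of (compartment_index, g_uS, E_rev_mV).
    Solves the tridiagonal resting system directly.
    """
    n = cable.n_compartments
    diag, off = _banded_matrices(cable)
    diag = diag.copy()
    rhs = np.full(n, cable.g_leak_uS * cable.E_leak_mV)
    for idx, g, e in point_conductances:
        diag[idx] += g
        rhs[idx] += g * e
    ab = np.zeros((3, n))
    ab[0, 1:] = off
    ab[1] = diag
    ab[2, :-1] = off
    return solve_banded((1, 1), ab, rhs)


def simulate_dendrite(
    cable: CableParams,
    drives: dict,
    times: np.ndarray,
    dt: float = 1e-4,
    v_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the passive cable under time-varying point conductances.

    Implicit (backward-Euler) stepping — unconditionally stable for this
    stiff shunting regime. ``drives`` maps site name to a list of
    (g_uS trace on ``times``, E_rev) pairs; traces are linearly interpolated
    onto the solver grid. Returns (solver time grid, voltage at the readout
    compartment in mV).
    """
    if isinstance(drives, DriveSet):
        drives = drives.by_site
    times = np.asarray(times, dtype=float)
    t_solver = np.arange(times[0], times[-1] + dt / 2, dt)
    n = cable.n_compartments
    site_comp = cable.site_compartments
    comp_drives = []  # (compartment, g on solver grid, E)
    for site, lst in drives.items():
        for g, e in lst:
            g = np.asarray(g, dtype=float)
            if not np.all(np.isfinite(g)):
                raise InvalidConfigError("non-finite drive")
            comp_drives.append(
                (site_comp[site], np.interp(t_solver, times, g), float(e))
            )
    # aggregate drives sharing a compartment: the solver only needs the total
    # conductance G(t) and conductance-weighted reversal G(t)*E per site
    agg: dict = {}
    for comp, g, e in comp_drives:
        G, GE = agg.setdefault(comp, (np.zeros(len(t_solver)), np.zeros(len(t_solver))))
        G += g
        GE += g * e
    comps = np.array(sorted(agg.keys()), dtype=int)
    G_mat = np.stack([agg[c][0] for c in comps]) if len(comps) else np.zeros((0, len(t_solver)))
    GE_mat = np.stack([agg[c][1] for c in comps]) if len(comps) else np.zeros((0, len(t_solver)))

    diag0, off = _banded_matrices(cable)
    c_dt = cable.c_uF / dt
    diag_base = diag0 + c_dt
    if v_init is None:
        init = [(c, g[0], e) for c, g, e in comp_drives]
        v = cable_steady_state(cable, init)
    else:
        v = np.asarray(v_init, dtype=float).copy()
    readout = cable.compartment_of(cable.readout_fraction)
    out = np.empty(len(t_solver))
    out[0] = v[readout]
    base_rhs = cable.g_leak_uS * cable.E_leak_mV
    dgtsv = lapack.dgtsv
    for k in range(1, len(t_solver)):
        d = diag_base.copy()
        d[comps] += G_mat[:, k]
        rhs = c_dt * v
        rhs += base_rhs
        rhs[comps] += GE_mat[:, k]
        _, _, _, v, info = dgtsv(off, d, off, rhs,
                                 overwrite_dl=0, overwrite_d=1,
                                 overwrite_du=0, overwrite_b=1)
        if info != 0:
            raise InvalidConfigError("tridiagonal solve failed")
        out[k] = v[readout]
    return t_solver, out


def calcium_transform(v: np.ndarray, v_rest: float) -> np.ndarray:
    """Calcium proxy: squared positively-rectified voltage deflection."""
    return np.maximum(np.asarray(v, dtype=float) - v_rest, 0.0) ** 2


def response_amplitude(
    trace: np.ndarray,
    readout: str,
    f_stim: float,
    rate_hz: float,
    discard_s: float = 1.0,
) -> float:
    """Scalar response per readout over the post-transient analysis window.

    F1: Fourier amplitude at the stimulus frequency of the voltage
    deflection; V_max: its maximum; Ca_mean: time-mean of the calcium trace.
    """
    n0 = int(round(discard_s * rate_hz))
    win = np.asarray(trace, dtype=float)[n0:]
    if len(win) < rate_hz / f_stim:
        raise InvalidConfigError("analysis window shorter than one stimulus period")
    if readout == "F1":
        return fourier_amplitude(win, rate_hz, f_stim)
    if readout == "V_max":
        return float(win.max())
    if readout == "Ca_mean":
        return float(win.mean())
    raise InvalidConfigError(f"unknown readout {readout!r}")


@dataclass
class SimResult:
    """Direction sweep output: per-direction responses and DSIs."""

    directions: np.ndarray
    v_rest: float
    time: np.ndarray
    delta_v: dict  # direction -> voltage deflection trace (solver grid)
    f1: np.ndarray
    v_max: np.ndarray
    ca_mean: np.ndarray
    dsi_f1: float
    dsi_v_max: float
    dsi_ca_mean: float
    variant_name: str = ""

    def min_delta_v(self) -> float:
        """Most negative voltage deflection across directions (post-transient).

        Negative values mean the dendrite hyperpolarizes below rest during
        part of the grating cycle — the signature of contrast opponency.
        """
        return min(float(dv.min()) for dv in self.delta_v.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(direction=self.directions, F1=self.f1,
                                 V_max=self.v_max, Ca_mean=self.ca_mean,
                                 variant=self.variant_name))


def on_phase_mean_deflection(
    result: SimResult,
    direction: float | None = None,
    wavelength: float = 24.0,
    temporal_freq: float = 1.0,
) -> float:
    """Mean voltage deflection while the grating at the RF center is bright.

    The modelled cell's signature of contrast opponency is hyperpolarization
    to the ON component of the grating: with a periodic stimulus this is the
    phase-averaged deflection over the bright half-cycle at the central
    column, for the preferred direction by default. Rectified-only models
    sit silent (deflection >= 0) during that half-cycle; models with a
    linear input are pulled below rest.
    """
    if direction is None:
        direction = float(result.directions[int(np.argmax(result.f1))])
    dv = result.delta_v[direction]
    grating = MovingGrating(wavelength, temporal_freq, direction)
    central = grating.sample(np.array([[0.0, 0.0]]), result.time)[:, 0]
    return float(dv[central > 0].mean())


def dsi(amplitudes: np.ndarray, directions: np.ndarray) -> float:
    """Direction-selectivity index: |sum of amplitude-weighted direction
    vectors| / sum of amplitudes; 0 for an all-zero response by convention."""
    a = np.asarray(amplitudes, dtype=float)
    th = np.deg2rad(np.asarray(directions, dtype=float))
    if np.any(a < 0):
        raise InvalidConfigError("amplitudes must be non-negative")
    if len(np.unique(th)) != len(th):
        raise InvalidConfigError("directions must be distinct")
    total = a.sum()
    if total == 0:
        return 0.0
    vx = np.sum(a * np.cos(th))
    vy = np.sum(a * np.sin(th))
    return float(np.hypot(vx, vy) / total)


def direction_sweep(
    config: ModelConfig,
    wavelength: float = 24.0,
    temporal_freq: float = 1.0,
    n_directions: int = 16,
    duration_s: float = 6.0,
    discard_s: float = 1.0,
) -> SimResult:
    """Simulate grating motion in ``n_directions`` directions and score DSI.

    Defaults follow the modelled experiment: 1/24 cycles per degree, 1 Hz,
    6 s of motion, 16 directions, response quantified after discarding the
    first second. Voltage deflections are measured relative to the resting
    state under offset-only conductances (zero-contrast steady state).
    """
    directions = 360.0 * np.arange(n_directions) / n_directions
    times = np.arange(0.0, duration_s + config.dt_ln / 2, config.dt_ln)
    rate = 1.0 / config.dt
    n0 = int(round(discard_s * rate))
    f1, vmax, camean = [], [], []
    delta_v = {}
    t_solver = None
    v_rest = np.nan
    for th in directions:
        grating = MovingGrating(wavelength, temporal_freq, th)
        drives = assemble_drives(config, grating, times)
        v_rest = resting_voltage(config, drives.inh_scale)
        t_solver, v = simulate_dendrite(config.cable, drives, times, dt=config.dt)
        dv = v - v_rest
        delta_v[th] = dv[n0:]
        f1.append(response_amplitude(dv, "F1", temporal_freq, rate, discard_s))
        vmax.append(response_amplitude(dv, "V_max", temporal_freq, rate, discard_s))
        camean.append(
            response_amplitude(calcium_transform(v, v_rest), "Ca_mean",
                               temporal_freq, rate, discard_s)
        )
    f1 = np.array(f1)
    vmax = np.array(vmax)
    camean = np.array(camean)
    return SimResult(
        directions=directions,
        v_rest=v_rest,
        time=t_solver[n0:],
        delta_v=delta_v,
        f1=f1,
        v_max=vmax,
        ca_mean=camean,
        dsi_f1=dsi(f1, directions),
        dsi_v_max=dsi(np.maximum(vmax, 0.0), directions),
        dsi_ca_mean=dsi(camean, directions),
        variant_name=config.variant_name,
    )


def resting_voltage(config: ModelConfig, inh_scale: float = 1.0) -> float:
    """Readout voltage of the zero-contrast steady state.

    Under a gray screen every LN output sits exactly at its offset; the
    inhibitory offsets are scaled by the same multiplier as the simulation
    whose rest state is being computed.
    """
    site_comp = config.cable.site_compartments
    pcs = []
    for c in config.cell_types:
        g0 = c.offset * c.weight * c.g_amp
        if c.synapse_sign == "inhibitory":
            g0 *= inh_scale
        pcs.append((site_comp[c.site], g0, c.E_rev))
    prof = cable_steady_state(config.cable, pcs)
    return float(prof[config.cable.compartment_of(config.cable.readout_fraction)])
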