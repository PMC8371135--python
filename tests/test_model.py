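import numpy as np
import pytest
from dataclasses import replace

from t5rf import model
from t5rf.model import (
    CableParams,
    CellTypeSpec,
    HexArray,
    ModelConfig,
    alpha_kernel,
    assemble_drives,
    cable_steady_state,
    calcium_transform,
    default_config,
    direction_sweep,
    dsi,
    ln_front_end,
    response_amplitude,
    simulate_dendrite,
    temporal_filter_kernel,
)
from t5rf.stimuli import InvalidConfigError, MovingGrating


def analytic_cable_voltage(cable, frac_syn, g_uS, E_syn_mV, frac_read):
    """Sealed-end finite cable with one point conductance, solved in closed
    form via the cable Green's function and the self-consistent synapse
    voltage (the independent oracle for the compartmental solver)."""
    L = cable.length_um * 1e-4
    d = cable.diameter_um * 1e-4
    r_m = 1.0 / (cable.g_m_S_cm2 * np.pi * d)  # Ohm * cm
    r_a = 4.0 * cable.Ra_ohm_cm / (np.pi * d**2)  # Ohm / cm
    lam = np.sqrt(r_m / r_a)
    xs, xr = frac_syn * L, frac_read * L

    def transfer_res(x_a, x_b):
        xlo, xhi = min(x_a, x_b), max(x_a, x_b)
        return r_a * lam * np.cosh(xlo / lam) * np.cosh((L - xhi) / lam) / np.sinh(L / lam)

    g = g_uS * 1e-6
    R_ss = transfer_res(xs, xs)
    v_syn = (cable.E_leak_mV + g * E_syn_mV * R_ss) / (1 + g * R_ss)
    return cable.E_leak_mV + g * (E_syn_mV - v_syn) * transfer_res(xr, xs)


class TestTemporalFilters:
    def test_low_pass_zero_at_origin(self):
        t = np.arange(0.0, 2.0, 1e-3)
        k = temporal_filter_kernel("low_pass", 0.2, t)
        assert k[0] == 0.0

    def test_high_pass_zero_at_tau(self):
        tau = 0.06
        t = np.arange(0.0, 1.0, 1e-3)
        k = temporal_filter_kernel("high_pass", tau, t)
        i = int(round(tau / 1e-3))
        assert abs(k[i]) < 1e-10

    def test_low_pass_peak_location_and_value(self):
        tau = 0.2
        t = np.arange(0.0, 4.0, 1e-4)
        k = temporal_filter_kernel("low_pass", tau, t)
        assert t[np.argmax(k)] == pytest.approx(tau, abs=2e-4)
        assert k.max() == pytest.approx(2 * tau**-0.5 * np.exp(-1), rel=1e-6)

    def test_exact_formula_values(self):
        tau = 0.1
        t = np.array([0.0, 0.05, 0.1, 0.3])
        lp = temporal_filter_kernel("low_pass", tau, t)
        np.testing.assert_allclose(lp, 2 * tau**-1.5 * t * np.exp(-t / tau))
        hp = temporal_filter_kernel("high_pass", tau, t)
        np.testing.assert_allclose(hp, 2 * tau**-1.5 * (tau - t) * np.exp(-t / tau))


class TestLNFrontEnd:
    def spec(self, **kw):
        base = dict(name="Tm9", temporal_kind="low_pass", tau_filter=0.2,
                    output_fn="linear", synapse_sign="excitatory", weight=1.0,
                    site="tip", column="trailing")
        base.update(kw)
        return CellTypeSpec(**base)

    def test_zero_contrast_gives_offset(self):
        class Gray:
            def sample(self, pts, t):
                return np.zeros((len(np.atleast_1d(t)), np.atleast_2d(pts).shape[0]))

        t = np.arange(0.0, 1.0, 1e-3)
        g = ln_front_end(Gray(), self.spec(), np.zeros(2), t, 1e-3)
        np.testing.assert_allclose(g, 0.5, atol=1e-12)

    def test_linear_superposition(self):
        t = np.arange(0.0, 3.0, 1e-3)
        spec = self.spec()
        a = MovingGrating(24.0, 1.0, 0.0, contrast_amp=0.4)
        b = MovingGrating(18.0, 0.5, 90.0, contrast_amp=0.4)

        class Sum:
            def sample(self, pts, tt):
                return a.sample(pts, tt) + b.sample(pts, tt)

        ga = ln_front_end(a, spec, np.zeros(2), t, 1e-3) - spec.offset
        gb = ln_front_end(b, spec, np.zeros(2), t, 1e-3) - spec.offset
        gs = ln_front_end(Sum(), spec, np.zeros(2), t, 1e-3) - spec.offset
        np.testing.assert_allclose(gs, ga + gb, atol=1e-9)

    def test_rectified_silent_for_pure_on_drive(self):
        # a steady bright field drives the OFF-positive signal negative;
        # the rectified output stays pinned at the offset
        class Bright:
            def sample(self, pts, t):
                return np.ones((len(np.atleast_1d(t)), np.atleast_2d(pts).shape[0]))

        t = np.arange(0.0, 1.0, 1e-3)
        g = ln_front_end(Bright(), self.spec(output_fn="off_rectified"),
                         np.zeros(2), t, 1e-3)
        np.testing.assert_allclose(g, 0.5, atol=1e-12)

    def test_conductance_in_unit_range(self):
        t = np.arange(0.0, 3.0, 1e-3)
        for fn in ("linear", "off_rectified"):
            g = ln_front_end(MovingGrating(24.0, 1.0, 0.0),
                             self.spec(output_fn=fn), np.zeros(2), t, 1e-3)
            assert g.min() >= 0.0 and g.max() <= 1.0


class TestAssembleDrives:
    def test_zero_weights_zero_drive(self):
        cfg = default_config()
        cells = tuple(replace(c, weight=0.0) for c in cfg.cell_types)
        cfg = replace(cfg, cell_types=cells)
        t = np.arange(0.0, 1.0, 1e-3)
        ds = assemble_drives(cfg, MovingGrating(), t)
        for site, lst in ds.by_site.items():
            for g, _ in lst:
                np.testing.assert_array_equal(g, 0.0)

    def test_doubling_weights_doubles_drives(self):
        cfg = default_config()
        t = np.arange(0.0, 2.0, 1e-3)
        ds1 = assemble_drives(cfg, MovingGrating(), t)
        cfg2 = replace(cfg, cell_types=tuple(replace(c, weight=2 * c.weight)
                                             for c in cfg.cell_types))
        ds2 = assemble_drives(cfg2, MovingGrating(), t)
        for site in ds1.by_site:
            for (g1, _), (g2, _) in zip(ds1.by_site[site], ds2.by_site[site]):
                np.testing.assert_allclose(g2, 2 * g1, rtol=1e-9)

    def test_peak_inhibition_excitation_ratio(self):
        cfg = default_config()
        t = np.arange(0.0, 4.0, 1e-3)
        ds = assemble_drives(cfg, MovingGrating(), t)
        exc = np.sum([g for site in ds.by_site.values() for g, e in site if e == 0.0],
                     axis=0)
        inh = np.sum([g for site in ds.by_site.values() for g, e in site if e < 0.0],
                     axis=0)
        assert inh.max() / exc.max() == pytest.approx(cfg.IE_ratio, rel=0.01)


class TestCableSolver:
    def test_zero_input_rests_at_leak_potential(self):
        v = cable_steady_state(CableParams(), [])
        np.testing.assert_allclose(v, -65.0, atol=1e-6)

    @pytest.mark.parametrize("frac,g,E", [
        (0.5, 2.49e-5, 0.0),
        (0.95, 2.49e-5, 0.0),
        (0.05, 4.98e-4, -70.0),
    ])
    def test_steady_state_matches_analytic_cable(self, frac, g, E):
        cable = CableParams()
        comp = cable.compartment_of(frac)
        frac_c = (comp + 0.5) / cable.n_compartments
        read = cable.compartment_of(cable.readout_fraction)
        frac_r = (read + 0.5) / cable.n_compartments
        v_num = cable_steady_state(cable, [(comp, g, E)])[read]
        v_an = analytic_cable_voltage(cable, frac_c, g, E, frac_r)
        assert abs(v_num - v_an) < 0.01 * abs(v_an - cable.E_leak_mV) + 1e-9

    def test_constant_drive_converges_to_steady_state(self):
        cable = CableParams()
        comp = cable.compartment_of(0.5)
        t = np.arange(0.0, 0.2, 1e-3)
        drives = {"center": [(np.full(len(t), 2.49e-5), 0.0)],
                  "tip": [], "base": []}
        v0 = np.full(cable.n_compartments, cable.E_leak_mV)
        _, v = simulate_dendrite(cable, drives, t, dt=1e-4, v_init=v0)
        target = cable_steady_state(cable, [(comp, 2.49e-5, 0.0)])
        assert v[-1] == pytest.approx(target[cable.compartment_of(0.0)], abs=1e-3)

    def test_inhibition_bounded_by_reversals(self):
        cable = CableParams()
        t = np.arange(0.0, 0.1, 1e-3)
        drives = {"base": [(np.full(len(t), 4.98e-4), -70.0)],
                  "tip": [], "center": []}
        v0 = np.full(cable.n_compartments, cable.E_leak_mV)
        _, v = simulate_dendrite(cable, drives, t, dt=1e-4, v_init=v0)
        assert np.all(v <= -65.0 + 1e-9)
        assert np.all(v >= -70.0 - 1e-9)
        assert np.all(np.diff(v) <= 1e-9)  # monotone approach

    def test_non_finite_drive_rejected(self):
        cable = CableParams()
        t = np.arange(0.0, 0.01, 1e-3)
        g = np.full(len(t), np.nan)
        with pytest.raises(InvalidConfigError):
            simulate_dendrite(cable, {"tip": [(g, 0.0)], "center": [], "base": []}, t)


class TestReadouts:
    def test_calcium_transform(self):
        v = np.array([-66.0, -65.0, -63.0])
        np.testing.assert_allclose(calcium_transform(v, -65.0), [0.0, 0.0, 4.0])
        np.testing.assert_allclose(calcium_transform(2 * (v + 65) - 65, -65.0),
                                   4 * calcium_transform(v, -65.0))

    def test_f1_and_vmax_of_sinusoid(self):
        rate, f = 1000.0, 2.0
        t = np.arange(0.0, 4.0, 1 / rate)
        tr = 0.8 * np.sin(2 * np.pi * f * t)
        assert response_amplitude(tr, "F1", f, rate) == pytest.approx(0.8, abs=1e-3)
        assert response_amplitude(tr, "V_max", f, rate) == pytest.approx(0.8, abs=1e-6)

    def test_constant_trace_f1_zero(self):
        t = np.arange(0.0, 4.0, 1e-3)
        assert response_amplitude(np.ones(len(t)), "F1", 1.0, 1000.0) == \
            pytest.approx(0.0, abs=1e-12)


class TestDSI:
    def test_uniform_responses_zero(self):
        d = 360.0 * np.arange(16) / 16
        assert dsi(np.ones(16), d) == pytest.approx(0.0, abs=1e-12)

    def test_single_direction_one(self):
        d = 360.0 * np.arange(16) / 16
        a = np.zeros(16)
        a[3] = 2.0
        assert dsi(a, d) == pytest.approx(1.0)

    def test_opposite_pair_cancels(self):
        assert dsi(np.array([1.0, 1.0]), np.array([0.0, 180.0])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_all_zero_by_convention(self):
        assert dsi(np.zeros(4), np.array([0.0, 90.0, 180.0, 270.0])) == 0.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidConfigError):
            dsi(np.array([-1.0, 1.0]), np.array([0.0, 180.0]))


class TestDirectionSweep:
    def test_single_point_sampler_not_selective(self):
        cfg = default_config()
        cells = tuple(replace(c, weight=0.0 if c.name != "Tm9" else c.weight)
                      for c in cfg.cell_types)
        cfg = replace(cfg, cell_types=cells)
        res = direction_sweep(cfg, n_directions=8, duration_s=3.0)
        # an isotropic DoG at one location responds identically to every
        # motion direction (up to a phase), so the vector sum cancels
        assert res.dsi_f1 < 0.01
        assert np.ptp(res.f1) < 0.01 * res.f1.max()

    def test_rotation_equivariance(self):
        base = direction_sweep(default_config(), n_directions=6, duration_s=3.0)
        rot = direction_sweep(
            default_config(hex_array=HexArray(pd_direction=60.0)),
            n_directions=6, duration_s=3.0)
        # rotating the sampling array by one hex step permutes the direction
        # tuning cyclically
        np.testing.assert_allclose(rot.f1, np.roll(base.f1, 1), rtol=1e-3)
        assert rot.dsi_f1 == pytest.approx(base.dsi_f1, rel=1e-3)

    def test_voltage_bounds(self):
        res = direction_sweep(default_config("all_three_linear"),
                              n_directions=4, duration_s=3.0)
        for dv in res.delta_v.values():
            v = dv + res.v_rest
            assert np.all(v >= -70.0 - 1e-9) and np.all(v <= 0.0)

    def test_grid_convergence(self):
        cfg = default_config()
        t = np.arange(0.0, 3.0, cfg.dt_ln)
        g = MovingGrating(24.0, 1.0, 0.0)
        ds = assemble_drives(cfg, g, t)
        _, v1 = simulate_dendrite(cfg.cable, ds, t, dt=1e-4)
        fine_cable = replace(cfg.cable, n_compartments=201)
        _, v2 = simulate_dendrite(fine_cable, ds, t, dt=5e-5)
        f1_coarse = response_amplitude(v1 - v1[0], "F1", 1.0, 1e4)
        f1_fine = response_amplitude(v2 - v2[0], "F1", 1.0, 2e4)
        assert abs(f1_fine - f1_coarse) / f1_fine < 0.01
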