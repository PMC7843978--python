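import numpy as np
import pytest

from ppgsim.grid import GridSpec
from ppgsim.optical_properties import DEFAULT_SCENARIOS, MelaninSetting
from ppgsim.ppg_waveform import (
    PPGWaveform,
    SimulationSettings,
    ac_dc_ratio,
    baseline_change,
    ratio_under_absorption_change,
    register_measured_trace,
    simulate_waveform,
    waveform_metrics,
)
from ppgsim.pulse_geometry import PulseShape
from ppgsim.tissue_volume import lumen_axis_depth
from ppgsim.vessel_mechanics import VesselSpec


def synthetic_waveform(detected, outside=None, y=None) -> PPGWaveform:
    detected = np.asarray(detected, float)
    n = len(detected)
    if y is None:
        y = np.linspace(-1.5, 1.5, n)
    if outside is None:
        outside = np.zeros(n, bool)
        outside[:3] = outside[-3:] = True
    return PPGWaveform(
        y_positions=y, detected=detected, stderr=np.zeros(n),
        outside=np.asarray(outside, bool), wavelength=660,
        scenario=DEFAULT_SCENARIOS[0], melanin=MelaninSetting(0.0),
        n_photons=1, n_trials=1, seed=0,
    )


class TestMetrics:
    def test_flat_waveform_has_zero_ratio(self):
        wf = synthetic_waveform(np.full(89, 2e-5))
        assert ac_dc_ratio(wf) == pytest.approx(0.0, abs=1e-9)

    def test_known_dip_recovered(self):
        y = np.linspace(-1.5, 1.5, 89)
        dc = 1e-5
        dip = dc * (1 - 0.08 * np.exp(-(y**2) / 0.1))  # 8% smooth dip
        wf = synthetic_waveform(dip)
        m = waveform_metrics(wf)
        assert m.dc == pytest.approx(dc, rel=1e-3)
        assert m.ac_dc_ratio_pct == pytest.approx(8.0, abs=0.2)
        assert abs(y[m.extremum_index]) < 0.1

    def test_dc_from_outside_positions_only(self):
        v = np.full(89, 1.0)
        v[:3] = v[-3:] = 2.0  # outside positions carry the baseline
        wf = synthetic_waveform(v)
        assert waveform_metrics(wf).dc == pytest.approx(2.0)

    def test_zero_dc_rejected(self):
        wf = synthetic_waveform(np.zeros(89))
        with pytest.raises(ValueError):
            waveform_metrics(wf)

    def test_baseline_change_identities(self):
        a = synthetic_waveform(np.full(89, 2e-5))
        b = synthetic_waveform(np.full(89, 1e-5))
        assert baseline_change(a, a) == 0.0
        assert baseline_change(a, b) == pytest.approx(50.0)
        assert baseline_change(b, a) == pytest.approx(-100.0)


class TestRatioUnderAbsorptionChange:
    def test_no_shift_returns_reference(self):
        assert ratio_under_absorption_change(8.1, 0.0, 0.0) == pytest.approx(8.1)

    def test_uniform_scaling_leaves_ratio_unchanged(self):
        for eps in (-0.3, -0.01, 0.05, 0.8):
            assert ratio_under_absorption_change(8.1, eps, eps) == pytest.approx(8.1)

    def test_matches_direct_computation(self):
        # build dc/dip pairs explicitly and compare against the closed form
        dc, r = 2e-5, 0.085
        dip = dc * (1 - r)
        eps_dc, eps_dip = -0.04, -0.025
        dc2, dip2 = dc * (1 + eps_dc), dip * (1 + eps_dip)
        direct = 100.0 * (dc2 - dip2) / dc2
        assert ratio_under_absorption_change(100 * r, eps_dc, eps_dip) == (
            pytest.approx(direct, rel=1e-12)
        )

    def test_dip_deepening_raises_ratio(self):
        # absorbing the dip harder than the baseline increases pulsatility
        assert ratio_under_absorption_change(8.1, 0.0, -0.02) > 8.1
        assert ratio_under_absorption_change(8.1, -0.02, 0.0) < 8.1


class TestSimulateWaveform:
    def test_degenerate_shape_gives_exactly_flat_waveform(self):
        # without dilation every position builds the identical volume, and
        # identical volumes reuse identical photon substreams
        vessel = VesselSpec()
        sc = DEFAULT_SCENARIOS[0]
        d = lumen_axis_depth(sc, vessel)
        shape = PulseShape(IDx=vessel.inner_diameter_cm, IDxd=vessel.inner_diameter_cm,
                           pwd1=0.45, pwd2=0.65, pL1=0.0, pL2=-0.35, d=d)
        st = SimulationSettings(n_photons=4_000, n_trials=2, n_positions=15, seed=3)
        wf = simulate_waveform(sc, MelaninSetting(0.0), shape, settings=st)
        assert np.ptp(wf.detected) == 0.0
        assert ac_dc_ratio(wf) == pytest.approx(0.0, abs=1e-9)

    def test_waveform_reproducible_and_errors_populated(self):
        st = SimulationSettings(n_photons=3_000, n_trials=3, n_positions=9, seed=5)
        sc = DEFAULT_SCENARIOS[0]
        a = simulate_waveform(sc, MelaninSetting(0.0), settings=st)
        b = simulate_waveform(sc, MelaninSetting(0.0), settings=st)
        assert np.array_equal(a.detected, b.detected)
        assert np.all(a.stderr[~np.isnan(a.stderr)] >= 0)
        assert a.outside[0] and a.outside[-1]

    def test_position_subset_fills_rest_with_nan(self):
        st = SimulationSettings(n_photons=2_000, n_trials=1, n_positions=11, seed=5)
        sc = DEFAULT_SCENARIOS[0]
        wf = simulate_waveform(sc, MelaninSetting(0.0), settings=st,
                               position_indices=np.array([0, 5, 6]))
        assert np.isnan(wf.detected[1])
        assert not np.isnan(wf.detected[5])
        m = waveform_metrics(wf)
        assert m.dc > 0


class TestRegistration:
    def test_anchors_map_exactly_and_self_registration_is_identity(self):
        y = np.linspace(-1.5, 1.5, 89)
        dc = 1e-5
        sim = synthetic_waveform(dc * (1 - 0.08 * np.exp(-(y**2) / 0.05)))
        # measured trace: the simulated waveform read back as a time series
        t = np.linspace(0.0, 1.0, 89)
        measured = sim.normalized()
        yy, meas_on_y, sim_norm = register_measured_trace(t, measured, sim)
        assert np.allclose(meas_on_y, sim_norm, atol=1e-12)

    def test_round_trip_under_monotone_time_warp(self):
        # a piecewise-linear warp with its kink at the peak is exactly the
        # class of time maps the anchor registration can invert
        y = np.linspace(-1.5, 1.5, 201)
        dc = 1e-5
        sim = synthetic_waveform(dc * (1 - 0.08 * np.exp(-(y**2) / 0.05)),
                                 y=y, outside=np.abs(y) > 1.3)
        sim_norm = sim.normalized()
        y_pk = y[int(np.argmax(sim_norm))]
        t_lin = np.linspace(0.0, 1.0, 201)
        t_pk = 0.35
        y_of_t = np.where(
            t_lin <= t_pk,
            y[0] + (y_pk - y[0]) * t_lin / t_pk,
            y_pk + (y[-1] - y_pk) * (t_lin - t_pk) / (1 - t_pk),
        )
        measured = np.interp(y_of_t, y, sim_norm)
        yy, meas_on_y, out_norm = register_measured_trace(t_lin, measured, sim)
        assert meas_on_y[0] == pytest.approx(out_norm[0], abs=1e-9)
        assert meas_on_y[-1] == pytest.approx(out_norm[-1], abs=1e-9)
        assert int(np.argmax(meas_on_y)) == int(np.argmax(out_norm))
        assert np.max(np.abs(meas_on_y - out_norm)) < 0.02

    def test_no_peak_rejected(self):
        y = np.linspace(-1.5, 1.5, 89)
        sim = synthetic_waveform(np.full(89, 1e-5) * (1 + 0.1 * np.linspace(0, 1, 89)))
        flat = np.zeros(89)
        with pytest.raises(ValueError):
            register_measured_trace(np.linspace(0, 1, 89), flat, sim)
        ramp = np.linspace(0, 1, 89)  # peak at the end: not a pulse
        with pytest.raises(ValueError):
            register_measured_trace(np.linspace(0, 1, 89), ramp, sim)
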