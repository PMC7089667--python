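"""AP detection criteria, AP properties, firing curves, passive properties."""

from __future__ import annotations

import numpy as np
import pytest

import epikit as ek

DT = 0.02  # ms


def _triangle_spike(
    dt=0.01, baseline=-70.0, kink=-40.0, peak=20.0, rise=60.0, slow=10.0
):
    """Slow ramp to the kink, then a symmetric fast triangle to the peak.

    The fast limbs run at ``rise`` mV/ms, so the detector's 20 mV/ms backward
    search stops at the kink: detected threshold = ``kink``, base width of the
    fast triangle = 2 (peak - kink) / rise.
    """
    segs = [
        np.full(int(5 / dt), baseline),
        np.linspace(baseline, kink, int((kink - baseline) / slow / dt)),
        np.linspace(kink, peak, int((peak - kink) / rise / dt)),
        np.linspace(peak, kink, int((peak - kink) / rise / dt)),
        np.linspace(kink, baseline, int((kink - baseline) / slow / dt)),
        np.full(int(5 / dt), baseline),
    ]
    return np.concatenate(segs), dt


class TestDetectAps:
    def test_subthreshold_charging_has_no_events(self):
        t = np.arange(0, 300, DT)
        v = -70.0 + 3.0 * (1 - np.exp(-t / 15.0))
        assert ek.detect_aps(v, DT) == []

    def test_model_cell_spikes_recovered_within_1ms(self, default_cell):
        proto = ek.StepProtocol(n_steps=25)
        sweeps, truth = ek.generate_current_clamp_sweeps(
            proto, default_cell, noise_rms_mv=0.2
        )
        for k, amp in enumerate(proto.amplitudes_pa()):
            events = ek.detect_aps(
                sweeps.voltages[k], sweeps.dt_ms, injected_current_pa=amp
            )
            true_times = truth.spike_times_ms[k]
            assert len(events) == true_times.size
            for ev, t_true in zip(events, true_times):
                assert abs(ev.peak_time_ms - t_true) <= 1.0

    def test_slow_ramp_crossing_rejected(self):
        # crosses 0 mV at 5 mV/ms: fails the >20 mV/ms rising-slope criterion
        v = np.concatenate(
            [np.full(500, -70.0), np.arange(-70.0, 20.0, 5.0 * DT), np.full(500, -70.0)]
        )
        assert ek.detect_aps(v, DT) == []

    def test_current_out_of_range_ineligible(self, default_cell):
        sweeps, truth = ek.generate_current_clamp_sweeps(
            ek.StepProtocol(start_amplitude_pa=510.0, n_steps=1),
            default_cell, noise_rms_mv=0.0,
        )
        assert truth.spike_times_ms[0].size > 0
        assert ek.detect_aps(sweeps.voltages[0], DT, injected_current_pa=510.0) == []

    def test_coarse_dt_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            ek.detect_aps(np.full(100, -70.0), 0.2)

    def test_nonfinite_rejected(self):
        v = np.full(100, -70.0)
        v[3] = np.inf
        with pytest.raises(ValueError):
            ek.detect_aps(v, DT)


class TestHalfWidth:
    def test_symmetric_triangle_geometry(self):
        """Threshold −40, peak +20, 2 ms fast base → half-width 1 ms."""
        v, dt = _triangle_spike()
        events = ek.detect_aps(v, dt)
        assert len(events) == 1
        ev = events[0]
        assert ev.threshold_v_mv == pytest.approx(-40.0, abs=0.5)
        assert ev.half_width_ms == pytest.approx(1.0, rel=0.02)

    def test_refinement_convergence(self):
        widths = []
        for dt in (0.02, 0.01):
            v, _ = _triangle_spike(dt=dt)
            widths.append(ek.detect_aps(v, dt)[0].half_width_ms)
        assert abs(widths[1] - widths[0]) / widths[1] < 0.02

    def test_offset_invariance(self):
        v, dt = _triangle_spike()
        w1 = ek.detect_aps(v, dt)[0].half_width_ms
        w2 = ek.detect_aps(v + 5.0, dt)[0].half_width_ms
        assert w2 == pytest.approx(w1, rel=0.01)

    def test_repolarization_rate_shrinks_width(self):
        widths = []
        for rate in (60.0, 120.0, 240.0):
            cell = ek.ModelCellParams(repolarization_rate=rate)
            sweeps, _ = ek.generate_current_clamp_sweeps(
                ek.StepProtocol(start_amplitude_pa=250.0, n_steps=1),
                cell, noise_rms_mv=0.0,
            )
            ev = ek.detect_aps(sweeps.voltages[0], sweeps.dt_ms)[0]
            widths.append(ev.half_width_ms)
        assert widths[0] > widths[1] > widths[2]

    def test_malformed_event_rejected(self):
        v, dt = _triangle_spike()
        ev = ek.detect_aps(v, dt)[0]
        ev.peak_v_mv = ev.threshold_v_mv - 1.0
        with pytest.raises(ValueError, match="malformed"):
            ek.ap_half_width(v, ev, dt)


class TestFiringCurve:
    def test_rate_is_count_over_step_duration(self, default_sweeps):
        sweeps, truth = default_sweeps
        fc = ek.firing_curve(sweeps)
        for rate, spikes in zip(fc.rates_hz, truth.spike_times_ms):
            assert rate == pytest.approx(spikes.size / 0.25)

    def test_rheobase_within_one_increment(self, default_sweeps):
        sweeps, truth = default_sweeps
        fc = ek.firing_curve(sweeps)
        assert abs(fc.current_threshold_pa - truth.rheobase_pa) <= 10.0

    def test_all_subthreshold_protocol(self, default_cell):
        sweeps, _ = ek.generate_current_clamp_sweeps(
            ek.StepProtocol(n_steps=5), default_cell, noise_rms_mv=0.0
        )
        fc = ek.firing_curve(sweeps)
        assert fc.max_rate_hz == 0.0
        assert fc.current_threshold_pa is None


class TestPassiveProperties:
    def test_ohmic_example(self, default_sweeps):
        sweeps, _ = default_sweeps
        pp = ek.passive_properties(sweeps)
        assert pp.input_resistance_mohm == pytest.approx(150.0, rel=0.01)
        assert pp.tau_ms == pytest.approx(15.0, rel=0.02)
        assert pp.capacitance_pf == pytest.approx(100.0, rel=0.03)
        assert pp.resting_potential_mv == pytest.approx(-70.0, abs=0.1)

    @pytest.mark.parametrize("noise,tol_scale", [(0.0, 1.0), (0.2, 2.0)])
    def test_recovery_grid(self, noise, tol_scale):
        """3x3 (R, tau) grid within 1%/2%/3% tolerances (doubled with noise)."""
        for r_true in (100.0, 150.0, 200.0):
            for tau_true in (10.0, 15.0, 20.0):
                cell = ek.ModelCellParams(
                    input_resistance=r_true, membrane_tau=tau_true, seed=11
                )
                sweeps, _ = ek.generate_current_clamp_sweeps(
                    ek.StepProtocol(n_steps=4), cell, noise_rms_mv=noise
                )
                pp = ek.passive_properties(sweeps)
                c_true = tau_true / r_true * 1e3
                assert pp.input_resistance_mohm == pytest.approx(
                    r_true, rel=0.01 * tol_scale
                )
                assert pp.tau_ms == pytest.approx(tau_true, rel=0.02 * tol_scale)
                assert pp.capacitance_pf == pytest.approx(
                    c_true, rel=0.03 * tol_scale
                )

    def test_resistance_scale_invariance(self):
        """Doubling both ΔV and ΔI (via R and amplitudes) fixes R's ratio role."""
        base = ek.ModelCellParams(input_resistance=120.0, seed=0)
        sweeps, _ = ek.generate_current_clamp_sweeps(
            ek.StepProtocol(n_steps=4), base, noise_rms_mv=0.0
        )
        doubled = ek.SweepSet(
            voltages=-70.0 + 2.0 * (sweeps.voltages + 70.0),
            currents=2.0 * sweeps.currents,
            dt_ms=sweeps.dt_ms,
            protocol=sweeps.protocol,
        )
        r1 = ek.passive_properties(sweeps).input_resistance_mohm
        r2 = ek.passive_properties(doubled).input_resistance_mohm
        assert r2 == pytest.approx(r1, rel=1e-6)

    def test_missing_hyperpolarizing_steps_rejected(self, default_cell):
        sweeps, _ = ek.generate_current_clamp_sweeps(
            ek.StepProtocol(start_amplitude_pa=10.0, n_steps=3),
            default_cell, noise_rms_mv=0.0,
        )
        with pytest.raises(ValueError, match="hyperpolarizing"):
            ek.passive_properties(sweeps)


class TestResamplingInvariance:
    def test_ap_count_stable_under_finer_dt(self, default_cell):
        proto = ek.StepProtocol(start_amplitude_pa=250.0, n_steps=1)
        counts = []
        for dt in (0.02, 0.01):
            sweeps, _ = ek.generate_current_clamp_sweeps(
                proto, default_cell, noise_rms_mv=0.0, dt_ms=dt
            )
            counts.append(len(ek.detect_aps(sweeps.voltages[0], dt)))
        assert counts[0] == counts[1] > 0


class TestSweepIO:
    def test_hdf5_round_trip(self, default_sweeps, tmp_path):
        sweeps, _ = default_sweeps
        path = tmp_path / "sweeps.h5"
        ek.write_sweeps(sweeps, path)
        back = ek.read_sweeps(path)
        assert np.array_equal(back.voltages, sweeps.voltages)
        assert np.array_equal(back.currents, sweeps.currents)
        assert back.dt_ms == sweeps.dt_ms
        assert back.protocol == sweeps.protocol
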