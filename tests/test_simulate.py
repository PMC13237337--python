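import numpy as np
import pytest

from sweptmemr import (
    DiscreteScheduleSpec,
    MiddleEarParams,
    NoiseParams,
    ReflexParams,
    SweptScheduleSpec,
    bin_session,
    eardrum_impedance,
    reflex_activation_trajectory,
    relative_pressure_change,
    round_trip_delay,
    simulate_binned_session,
    simulate_click_waveforms,
)


class TestImpedance:
    def test_resonance_is_purely_resistive(self, me_default):
        f0 = me_default.resonance_hz
        z = eardrum_impedance(f0, me_default.stiffness, me_default)
        assert z.imag == pytest.approx(0.0, abs=1e-6 * abs(z))
        assert z.real == pytest.approx(me_default.damping)

    def test_resonance_scales_with_sqrt_stiffness(self, me_default):
        f0 = np.sqrt(me_default.stiffness / me_default.mass) / (2 * np.pi)
        k2 = 1.21 * me_default.stiffness
        f2 = np.sqrt(k2 / me_default.mass) / (2 * np.pi)
        assert f2 / f0 == pytest.approx(1.1)
        z = eardrum_impedance(f2, k2, me_default)
        assert abs(z.imag) < 1e-6 * abs(z)

    def test_stiffness_dominates_at_low_frequency(self, me_default):
        f = 10.0
        z = eardrum_impedance(f, me_default.stiffness, me_default)
        k_term = me_default.stiffness / (2 * np.pi * f)
        assert abs(z) == pytest.approx(k_term, rel=0.01)

    def test_nonpositive_frequency_rejected(self, me_default):
        with pytest.raises(ValueError):
            eardrum_impedance(0.0, me_default.stiffness, me_default)


class TestRelativePressureChange:
    def test_identity_at_zero_activation(self, me_default):
        f = np.arange(500.0, 1501.0, 100.0)
        r = relative_pressure_change(f, 0.0, me_default)
        assert np.allclose(r, 1.0 + 0.0j)

    def test_spl_rises_below_resonance(self, me_default):
        assert abs(relative_pressure_change(500.0, 0.8, me_default)) > 1.0

    def test_spl_falls_above_resonance(self, me_default):
        assert abs(relative_pressure_change(1500.0, 0.95, me_default)) < 1.0

    def test_nonmonotonic_growth_near_resonance(self, me_default):
        # slightly above baseline resonance the magnitude first falls
        # toward the origin, then curves back out as stiffness keeps rising
        a = np.linspace(0.0, 1.0, 101)
        mag = np.abs(relative_pressure_change(1100.0, a, me_default))
        d = np.diff(mag)
        assert (d < 0).any() and (d > 0).any()


class TestActivationDynamics:
    def test_subthreshold_stays_at_zero(self, rf_default):
        levels = np.full(100, rf_default.l50 - 80.0)
        a = reflex_activation_trajectory(levels, rf_default)
        assert np.all(a < 1e-6)

    def test_step_matches_first_order_closed_form(self):
        rf = ReflexParams(l50=80.0, slope=1.5, delay=0.1, tau_attack=0.2, tau_release=0.8)
        levels = np.concatenate([np.zeros(20), np.full(120, 140.0)])
        t = np.arange(levels.size) / 20.0
        a = reflex_activation_trajectory(levels, rf, oversample=50)
        # once the delayed drive has fully stepped (a_inf = 1), the approach
        # is the first-order closed form from the state at that click
        i1 = 20 + int(rf.delay * 20) + 2
        expected = 1.0 - (1.0 - a[i1]) * np.exp(-(t[i1:] - t[i1]) / rf.tau_attack)
        assert np.max(np.abs(a[i1:] - expected)) < 1e-3
        assert np.all(a[: 20 + int(rf.delay * 20)] < 1e-12)

    def test_triangle_sweep_shows_hysteresis(self, rf_default, swept_spec):
        t = np.arange(160) / 20.0
        from sweptmemr import elicitor_level_at_time

        levels = elicitor_level_at_time(swept_spec, t)
        a = reflex_activation_trajectory(levels, rf_default)
        probe = 90.0
        i_up = np.argmin(np.abs(levels[:80] - probe))
        i_down = 80 + np.argmin(np.abs(levels[80:] - probe))
        assert a[i_down] > a[i_up]

    def test_bounded_and_step_refinement_stable(self, rf_default, swept_spec):
        from sweptmemr import elicitor_level_at_time

        levels = elicitor_level_at_time(swept_spec, np.arange(160) / 20.0)
        a1 = reflex_activation_trajectory(levels, rf_default, oversample=10)
        a2 = reflex_activation_trajectory(levels, rf_default, oversample=20)
        assert np.all((a1 >= 0) & (a1 <= 1))
        assert np.max(np.abs(a1 - a2)) < 1e-4

    def test_empty_input_rejected(self, rf_default):
        with pytest.raises(ValueError):
            reflex_activation_trajectory([], rf_default)


class TestBinnedSession:
    def test_no_reflex_no_noise_is_identity(self, swept_spec):
        me = MiddleEarParams(dk_max=0.0)
        nz = NoiseParams(sigma=0.0, drift_amplitude=0.0)
        mat, _ = simulate_binned_session(swept_spec, me, ReflexParams(), nz)
        assert np.allclose(mat.values, 1.0 + 0.0j, atol=1e-9)

    def test_first_click_of_every_sweep_is_baseline(self, noiseless_session):
        mat, truth = noiseless_session
        assert np.allclose(truth.activation[:, 0], 0.0)
        assert np.allclose(mat.values[:, 0, :], 1.0 + 0.0j, atol=1e-9)

    def test_fixed_seed_is_bit_identical(self, swept_spec, model_default):
        nz = NoiseParams(seed=77)
        m1, _ = simulate_binned_session(swept_spec, model=model_default, nz=nz)
        m2, _ = simulate_binned_session(swept_spec, model=model_default, nz=nz)
        assert np.array_equal(m1.values, m2.values)

    def test_discrete_residual_activation_carries_over(self, me_default, rf_default):
        spec = DiscreteScheduleSpec()
        nz = NoiseParams(sigma=0.0, drift_amplitude=0.0)
        _, truth = simulate_binned_session(spec, me_default, rf_default, nz)
        # click1 of sequences following loud bursts retains residual activation
        late = truth.activation[150:160, 0]
        early = truth.activation[0, 0]
        assert early == 0.0
        assert late.max() > 0.01


class TestWaveformPath:
    def test_round_trip_delay_value(self):
        assert round_trip_delay(1.4, 344.0) == pytest.approx(82e-6, rel=0.01)

    def test_no_reflex_renders_identical_clicks(self, rf_default):
        spec = SweptScheduleSpec(n_sweeps=2)
        me = MiddleEarParams(dk_max=0.0)
        nz = NoiseParams(sigma=0.0, drift_amplitude=0.0)
        _, truth = simulate_binned_session(spec, me, rf_default, nz)
        rec = simulate_click_waveforms(truth)
        fs = int(rec.fs)
        step = fs // 20
        first = rec.samples[:step]
        for k in (1, 50, 200):
            np.testing.assert_allclose(rec.samples[k * step : (k + 1) * step], first, atol=1e-7)

    def test_reflex_changes_only_after_incident_wave(self, swept_spec, me_default, rf_default, model_default):
        spec = SweptScheduleSpec(n_sweeps=1)
        nz = NoiseParams(sigma=0.0, drift_amplitude=0.0)
        _, truth = simulate_binned_session(spec, me_default, rf_default, nz, model=model_default)
        rec = simulate_click_waveforms(truth, model=model_default)
        fs = int(rec.fs)
        step = fs // 20
        clicks = rec.samples[: 160 * step].reshape(160, step)
        diff = clicks[80] - clicks[0]  # strongly activated minus baseline click
        peak = np.argmax(np.abs(clicks[0]))
        rt = int(round(round_trip_delay() * fs))
        pre_incident = np.abs(diff[: peak + rt // 2]).max()
        post = np.abs(diff[peak:]).max()
        assert post > 100 * max(pre_incident, 1e-12)

    def test_waveform_and_binned_paths_agree(self, me_default, rf_default, model_default):
        spec = SweptScheduleSpec(n_sweeps=2)
        nz = NoiseParams(sigma=0.0, drift_amplitude=0.0)
        mat, truth = simulate_binned_session(spec, me_default, rf_default, nz, model=model_default)
        rec = simulate_click_waveforms(truth, model=model_default)
        mat2 = bin_session(rec, spec)
        assert not mat2.flags.any()
        rel = mat2.values / mat2.values[0, 0][None, None, :]
        err = np.abs(rel - mat.values) / np.abs(mat.values)
        assert err.max() < 1e-3
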