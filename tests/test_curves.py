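import numpy as np
import pytest

from sweptmemr import (
    BinnedResponseMatrix,
    ComplexTrajectory,
    NoiseParams,
    PipelineConfig,
    average_and_smooth,
    compute_artifact_weights,
    compute_lgf,
    detrend_bins,
    mean_lgf,
    normalize_baseline,
    simulate_binned_session,
    smoother_cutoff,
    total_change,
    total_change_arclength,
    total_change_db,
)
from sweptmemr.curves import smoothing_spline

BINS = np.arange(500.0, 1501.0, 100.0)


def make_matrix(values, click_rate=20.0):
    values = np.asarray(values, dtype=complex)
    n_g, n_c, _ = values.shape
    t = (np.arange(n_g)[:, None] * n_c + np.arange(n_c)[None, :]) / click_rate
    levels = np.tile(np.linspace(40, 110, n_c), (n_g, 1))
    return BinnedResponseMatrix(
        values=values, bin_centers=BINS[: values.shape[2]], time_s=t, levels_db=levels
    )


def make_traj(z, bin_hz=1000.0):
    z = np.asarray(z, dtype=complex)
    t = np.arange(z.size) / 20.0
    return ComplexTrajectory(z=z, t=t, levels_db=np.linspace(40, 110, z.size), bin_hz=bin_hz)


class TestSmoothingSpline:
    def test_constant_preserved(self):
        y = np.full(200, 3.7)
        assert np.allclose(smoothing_spline(y, 1e-9), y)

    def test_p_one_interpolates(self):
        y = np.random.default_rng(0).standard_normal(50)
        assert np.allclose(smoothing_spline(y, 1.0), y)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            smoothing_spline(np.ones(10), 0.0)
        with pytest.raises(ValueError):
            smoother_cutoff(1.0, 20.0)

    def test_near_unity_p_passes_high_frequencies(self):
        # interpolating limit: cutoff approaches Nyquist
        c = smoother_cutoff(1 - 1e-9, 20.0, n=2000)
        assert c > 0.4 * 20.0


class TestDetrend:
    def test_constant_series_unchanged(self):
        vals = np.full((15, 160, 11), 2.0 - 0.5j)
        out = detrend_bins(make_matrix(vals))
        assert np.allclose(out.values, vals)

    def test_preserves_band_removes_drift(self):
        # linear drift plus a 0.125-Hz sinusoid (inside the reflex band)
        n_g, n_c = 15, 160
        t = np.arange(n_g * n_c) / 20.0
        sig = 0.2 * np.sin(2 * np.pi * 0.125 * t)
        drift = 0.5 * t / t.max()
        series = 1.0 + sig + drift
        vals = np.tile(series.reshape(n_g, n_c)[:, :, None], (1, 1, 11))
        out = detrend_bins(make_matrix(vals))
        resid = out.values[:, :, 0].reshape(-1).real
        # recovered sinusoid amplitude within 2% (equivalent-filter gain ~1)
        sl = slice(800, 1600)
        basis = np.column_stack(
            [np.sin(2 * np.pi * 0.125 * t[sl]), np.cos(2 * np.pi * 0.125 * t[sl]), np.ones(800)]
        )
        coef, *_ = np.linalg.lstsq(basis, resid[sl], rcond=None)
        assert np.hypot(coef[0], coef[1]) == pytest.approx(0.2, rel=0.02)

    def test_slow_component_strongly_attenuated(self):
        n_g, n_c = 15, 160
        t = np.arange(n_g * n_c) / 20.0
        slow = 0.5 * np.sin(2 * np.pi * 0.005 * t)
        vals = np.tile((1.0 + slow).reshape(n_g, n_c)[:, :, None], (1, 1, 11))
        out = detrend_bins(make_matrix(vals))
        resid = out.values[:, :, 0].reshape(-1).real - 1.0
        sl = slice(800, 1600)
        basis = np.column_stack(
            [np.sin(2 * np.pi * 0.005 * t[sl]), np.cos(2 * np.pi * 0.005 * t[sl]), np.ones(800)]
        )
        coef, *_ = np.linalg.lstsq(basis, resid[sl], rcond=None)
        assert np.hypot(coef[0], coef[1]) < 0.05  # > 90% removed

    def test_single_sweep_rejected(self):
        with pytest.raises(ValueError):
            detrend_bins(make_matrix(np.ones((1, 160, 11))))


class TestWeights:
    def test_clean_session_all_ones(self, noisy_session):
        mat, _ = noisy_session
        w = compute_artifact_weights(mat)
        assert w.shape == (15, 160)
        assert np.all(w == 1.0)

    def test_single_artifact_zeroed(self, noisy_session):
        mat, _ = noisy_session
        vals = mat.values.copy()
        vals[4, 33, :] += 10.0 * (1 + 1j)
        corrupted = BinnedResponseMatrix(
            values=vals,
            bin_centers=mat.bin_centers,
            time_s=mat.time_s,
            levels_db=mat.levels_db,
        )
        w = compute_artifact_weights(corrupted)
        assert w[4, 33] == 0.0
        assert w.sum() == w.size - 1


class TestAverageAndSmooth:
    def test_identical_sweeps_average_to_single_sweep(self, noiseless_session):
        mat, _ = noiseless_session
        trajs = average_and_smooth(mat)
        assert len(trajs) == 11
        assert trajs[0].z.size == 160
        # averaging identical sweeps is exact; smoothing barely moves the
        # quiet pre-reflex plateau (the decaying tail at the sweep end is
        # not a plateau and shows the spline's boundary relaxation)
        single = mat.values[0, :, 0]
        assert np.max(np.abs(trajs[0].z[:25] - single[:25])) < 1e-3
        assert np.max(np.abs(trajs[0].z - single)) < 2e-2

    def test_smoothing_contracts_noise(self):
        rng = np.random.default_rng(4)
        vals = 1.0 + 0.1 * (rng.standard_normal((15, 160, 11)) + 1j * rng.standard_normal((15, 160, 11)))
        trajs = average_and_smooth(make_matrix(vals))
        avg = vals.mean(axis=0)
        var_in = np.var(avg[:, 0])
        var_out = np.var(trajs[0].z)
        assert var_out < 0.5 * var_in


class TestNormalize:
    def test_constant_becomes_unity(self):
        out = normalize_baseline(make_traj(np.full(160, 2.0 + 1.0j)))
        assert np.allclose(out.z, 1.0)

    def test_plateau_ratio(self):
        z = np.full(20, 3.0 + 0j)
        z[:3] = 2.0
        z[-3:] = 2.0
        out = normalize_baseline(make_traj(z))
        assert np.allclose(out.z[5:15], 1.5)

    def test_baseline_points_average_to_unity(self, noiseless_session):
        mat, _ = noiseless_session
        tr = normalize_baseline(average_and_smooth(mat)[3])
        ref = np.concatenate([tr.z[:3], tr.z[-3:]])
        assert ref.mean() == pytest.approx(1.0 + 0.0j, abs=1e-12)

    def test_zero_baseline_rejected(self):
        z = np.ones(20, dtype=complex)
        z[:3] = 1.0
        z[-3:] = -1.0  # first/last average cancels to ~0
        with pytest.raises(ValueError):
            normalize_baseline(make_traj(z))


class TestTotalChange:
    @pytest.mark.parametrize(
        "z,expected",
        [(1.0 + 0.0j, 0.0), (0.9 + 0.1j, np.sqrt(0.02))],
    )
    def test_closed_form(self, z, expected):
        tr = make_traj(np.full(8, z))
        assert total_change(tr)[0] == pytest.approx(expected)

    def test_unit_circle_chord_length(self):
        theta = np.linspace(0, np.pi / 2, 50)
        tr = make_traj(np.exp(1j * theta))
        assert np.allclose(total_change(tr), 2 * np.sin(theta / 2))

    def test_db_expression(self):
        assert total_change_db(0.0) == 0.0
        assert total_change_db(1.0) == pytest.approx(20 * np.log10(2))

    def test_invariant_to_global_complex_gain(self, noiseless_session):
        mat, _ = noiseless_session
        lgf1 = compute_lgf(mat)
        scaled = BinnedResponseMatrix(
            values=mat.values * (0.3 - 1.7j),
            bin_centers=mat.bin_centers,
            time_s=mat.time_s,
            levels_db=mat.levels_db,
        )
        lgf2 = compute_lgf(scaled)
        np.testing.assert_allclose(lgf1.tc, lgf2.tc, atol=1e-12)


class TestArcLength:
    def test_stationary_trajectory(self):
        arc = total_change_arclength(make_traj(np.full(50, 1.0 + 0.0j)))
        assert np.all(arc == 0)

    def test_straight_excursion_and_return(self):
        out = np.linspace(1.0, 0.8, 26)
        z = np.concatenate([out, out[::-1][1:]])
        arc = total_change_arclength(make_traj(z))
        assert arc.max() == pytest.approx(0.2, abs=1e-12)
        assert arc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_up_then_down(self, noiseless_session):
        mat, _ = noiseless_session
        tr = normalize_baseline(average_and_smooth(mat)[5])
        arc = total_change_arclength(tr)
        pk = np.argmax(np.abs(tr.z - 1))
        assert np.all(np.diff(arc[: pk + 1]) >= 0)
        assert np.all(np.diff(arc[pk:]) <= 0)


class TestMeanLGF:
    def test_identical_bins(self):
        trajs = [make_traj(np.full(20, 0.9 + 0.1j), bin_hz=b) for b in BINS]
        lgf = mean_lgf(trajs)
        assert np.allclose(lgf.tc, np.sqrt(0.02))

    def test_two_value_average(self):
        z1 = np.full(20, 1.1 + 0j)
        trajs = []
        for b in BINS:
            z = z1 if b < 1000 else 1 + 2 * (z1 - 1)
            trajs.append(make_traj(z, bin_hz=b))
        lgf = mean_lgf(trajs)
        per_bin = np.array([0.1] * 5 + [0.2] * 6)
        assert np.allclose(lgf.tc, per_bin.mean())

    def test_missing_bin_rejected(self):
        trajs = [make_traj(np.ones(20), bin_hz=b) for b in BINS[:-1]]
        with pytest.raises(ValueError):
            mean_lgf(trajs)

    def test_mean_lgf_less_variable_than_single_bin(self, swept_spec, me_default, rf_default, model_default):
        # repeat the simulation; across-repeat variance of the band average
        # is below that of a single bin's magnitude response
        peaks_mean, peaks_bin = [], []
        for s in range(4):
            mat, _ = simulate_binned_session(
                swept_spec, me_default, rf_default, NoiseParams(seed=300 + s), model=model_default
            )
            lgf = compute_lgf(mat)
            peaks_mean.append(lgf.tc.max())
            peaks_bin.append(lgf.per_bin_tc[0].max())
        assert np.var(peaks_mean) < np.var(peaks_bin)


class TestRecoveryCorrelation:
    def test_recovered_tc_tracks_true_activation(self, noisy_session):
        mat, truth = noisy_session
        lgf = compute_lgf(mat)
        r = np.corrcoef(lgf.tc, truth.activation[0])[0, 1]
        assert r > 0.95


class TestPipelineConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(p_detrend=0.0)
        with pytest.raises(ValueError):
            PipelineConfig(n_baseline=0)
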