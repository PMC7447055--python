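import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musicphys import sigproc as sp
from musicphys import synth
from musicphys.errors import ConfigError, DomainError, InsufficientDataError

FS = 500.0


class TestBateman:
    def test_zero_at_origin(self):
        assert sp.bateman_irf(0.0, 2.0, 0.75) == 0.0

    def test_peak_location_matches_closed_form(self):
        t = np.linspace(0, 20, 200001)
        k = sp.bateman_irf(t, 2.0, 0.75)
        assert t[np.argmax(k)] == pytest.approx(sp.bateman_peak_time(2.0, 0.75), abs=1e-3)

    def test_normalized_peak_is_one(self):
        t = np.linspace(0, 20, 20001)
        assert sp.bateman_irf(t, 2.0, 0.75, normalize=True).max() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("tau1, tau2", [(0.75, 0.75), (0.5, 2.0), (2.0, -1.0)])
    def test_invalid_time_constants(self, tau1, tau2):
        with pytest.raises(DomainError):
            sp.bateman_irf(1.0, tau1, tau2)


class TestEmgEnvelope:
    def test_zero_input_gives_zero_envelope(self):
        env = sp.emg_envelope(np.zeros(5000), FS)
        assert env.shape == (5000,)
        assert np.allclose(env, 0.0)

    def test_in_band_tone_amplitude_recovered(self):
        t = np.arange(0, 20, 1 / FS)
        env = sp.emg_envelope(np.sin(2 * np.pi * 100 * t), FS)
        core = env[int(FS):-int(FS)]
        assert np.abs(core - 1.0).max() < 0.02

    def test_below_band_tone_suppressed(self):
        t = np.arange(0, 20, 1 / FS)
        env = sp.emg_envelope(np.sin(2 * np.pi * 5 * t), FS)
        assert env[int(FS):-int(FS)].max() <= 0.05

    def test_envelope_non_negative(self, rng):
        env = sp.emg_envelope(rng.standard_normal(10000), FS)
        assert (env >= 0).all()

    def test_infeasible_band(self):
        with pytest.raises(ConfigError):
            sp.emg_envelope(np.zeros(1000), 100.0)  # 249 Hz edge above Nyquist


class TestConditionPulsatile:
    def test_constant_removed(self):
        out = sp.condition_pulsatile(np.full(int(60 * FS), 3.7), FS)
        assert np.abs(out).max() < 1e-6

    def test_passband_preserved_drift_removed(self):
        t = np.arange(0, 120, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t) + 0.05 * t  # 1 Hz + linear drift
        out = sp.condition_pulsatile(x, FS)
        core = out[int(20 * FS):-int(20 * FS)]
        amp = (core.max() - core.min()) / 2
        assert amp == pytest.approx(1.0, rel=0.05)
        # drift gone: local means near zero
        assert np.abs(core.reshape(-1, int(FS)).mean(axis=1)).max() < 0.05

    def test_60hz_attenuated_20db(self):
        t = np.arange(0, 100, 1 / FS)
        out = sp.condition_pulsatile(np.sin(2 * np.pi * 60 * t), FS)
        core = slice(int(20 * FS), -int(20 * FS))
        # quadrature projection isolates the 60 Hz component
        c = np.cos(2 * np.pi * 60 * t[core])
        s = np.sin(2 * np.pi * 60 * t[core])
        amp = 2 * np.hypot(np.mean(out[core] * c), np.mean(out[core] * s))
        assert 20 * np.log10(1.0 / amp) >= 20


class TestDetectPeaks:
    def test_sine_peaks_at_known_times(self):
        t = np.arange(0, 10, 1 / FS)
        pk = sp.detect_peaks(np.sin(2 * np.pi * t), FS, min_interval=0.5)
        assert len(pk) == 10
        assert np.allclose(pk, 0.25 + np.arange(10), atol=2 / FS)

    def test_merged_bumps_keep_larger(self):
        t = np.arange(0, 2, 1 / FS)
        x = 1.0 * np.exp(-((t - 0.9) ** 2) / 0.002) + 0.6 * np.exp(-((t - 1.05) ** 2) / 0.002)
        pk = sp.detect_peaks(x, FS, min_interval=0.5)
        assert len(pk) == 1
        assert pk[0] == pytest.approx(0.9, abs=0.02)

    def test_flat_signal_no_peaks(self):
        assert sp.detect_peaks(np.ones(1000), FS, 0.5).size == 0

    def test_invalid_interval(self):
        with pytest.raises(DomainError):
            sp.detect_peaks(np.ones(10), FS, 0.0)


class TestRateFromPeaks:
    def test_unit_intervals(self):
        rs = sp.rate_from_peaks([0.0, 1.0, 2.0, 3.0])
        assert np.allclose(rs.rates, [1.0, 1.0, 1.0])
        assert np.allclose(rs.times, [0.5, 1.5, 2.5])

    def test_mixed_intervals(self):
        rs = sp.rate_from_peaks([0.0, 0.5, 1.5])
        assert np.allclose(rs.rates, [2.0, 1.0])
        assert np.allclose(rs.times, [0.25, 1.0])

    def test_single_peak_insufficient(self):
        with pytest.raises(InsufficientDataError):
            sp.rate_from_peaks([0.0])

    @settings(derandomize=True, max_examples=200)
    @given(
        diffs=st.lists(
            st.floats(min_value=0.1, max_value=5.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_pairwise_reciprocal_oracle(self, diffs):
        """Exact agreement with an explicit loop over consecutive pairs."""
        peaks = np.concatenate([[0.0], np.cumsum(diffs)])
        rs = sp.rate_from_peaks(peaks)
        expected_rates = [1.0 / (peaks[k + 1] - peaks[k]) for k in range(len(peaks) - 1)]
        expected_times = [(peaks[k + 1] + peaks[k]) / 2.0 for k in range(len(peaks) - 1)]
        assert np.array_equal(rs.rates, np.array(expected_rates))
        assert np.array_equal(rs.times, np.array(expected_times))


class TestResampleRate:
    def test_constant_rate_stays_constant(self):
        rs = sp.rate_from_peaks(np.arange(11.0))
        _, vals = sp.resample_rate(rs, 10.0, (0.0, 10.0))
        assert np.allclose(vals, 1.0)

    def test_linear_interpolation_by_hand(self):
        rs = sp.RateSeries(times=np.array([0.25, 1.0]), rates=np.array([2.0, 1.0]))
        grid, vals = sp.resample_rate(rs, 8.0, (0.625, 0.625 + 0.01))
        assert vals[0] == pytest.approx(1.5)

    def test_edge_hold(self):
        rs = sp.RateSeries(times=np.array([2.0, 3.0]), rates=np.array([1.5, 1.0]))
        _, vals = sp.resample_rate(rs, 10.0, (0.0, 1.0))
        assert np.allclose(vals, 1.5)


class TestDecomposeSC:
    def test_constant_signal(self):
        d = sp.decompose_sc(np.full(int(60 * FS), 2.5), FS)
        assert np.allclose(d.tonic, 2.5, atol=1e-6)
        assert d.driver_mass < 1e-6
        assert np.abs(d.phasic).max() < 1e-6

    def test_single_response_round_trip(self):
        n = int(60 * FS)
        sig, _ = synth.sc_from_events([20.0], [0.8], n, FS, 2.0, 0.75, tonic=2.0)
        d = sp.decompose_sc(sig, FS)
        assert (d.driver >= 0).all()
        assert d.driver_mass == pytest.approx(0.8, rel=0.10)
        assert d.times[np.argmax(d.driver)] == pytest.approx(20.0, abs=1.0)
        # tonic + phasic + residual reconstructs the (decimated) input
        y, _ = sp._decimate_to(sig, FS, d.fs)
        assert np.allclose(d.tonic + d.phasic + d.residual, y, atol=1e-10)
        assert d.residual.std() < 0.05 * sig.std()

    def test_two_overlapping_responses_resolved(self):
        from scipy.signal import find_peaks

        n = int(60 * FS)
        sig, _ = synth.sc_from_events([20.0, 22.0], [0.5, 0.5], n, FS, 2.0, 0.75, tonic=2.0)
        d = sp.decompose_sc(sig, FS)
        modes, _ = find_peaks(d.driver, height=0.05 * d.driver.max())
        mode_times = d.times[modes]
        assert any(abs(mt - 20.0) <= 1.0 for mt in mode_times)
        assert any(abs(mt - 22.0) <= 1.0 for mt in mode_times)

    def test_too_short_signal(self):
        with pytest.raises(InsufficientDataError):
            sp.decompose_sc(np.ones(int(2 * FS)), FS, tau1=2.0)


class TestMeanPhasic:
    @staticmethod
    def _decomp_with_phasic(phasic, fs):
        n = phasic.size
        z = np.zeros(n)
        return sp.SCDecomposition(
            times=np.arange(n) / fs, fs=fs, tonic=z, driver=z,
            phasic=phasic, residual=z, tau1=2.0, tau2=0.75,
        )

    def test_zero_phasic(self):
        d = self._decomp_with_phasic(np.zeros(301), 10.0)
        assert sp.mean_phasic(d, (0.0, 30.0)) == 0.0

    def test_unit_area_kernel_in_30s_window(self):
        fs = 10.0
        t = np.arange(0, 30, 1 / fs)
        k = sp.bateman_irf(t, 2.0, 0.75)
        k = k / np.trapezoid(k, t)  # unit area
        d = self._decomp_with_phasic(k, fs)
        assert sp.mean_phasic(d, (0.0, 29.9)) == pytest.approx(1 / 29.9, rel=0.02)

    def test_half_covered_window_matches_trapezoid_oracle(self):
        fs = 10.0
        t = np.arange(0, 30, 1 / fs)
        phasic = sp.bateman_irf(np.clip(t - 14.0, 0, None), 2.0, 0.75)
        d = self._decomp_with_phasic(phasic, fs)
        m = (t >= 10.0) & (t <= 20.0)
        oracle = np.trapezoid(phasic[m], t[m]) / (t[m][-1] - t[m][0])
        assert sp.mean_phasic(d, (10.0, 20.0)) == pytest.approx(oracle)

    def test_empty_window(self):
        d = self._decomp_with_phasic(np.zeros(301), 10.0)
        with pytest.raises(DomainError):
            sp.mean_phasic(d, (5.0, 5.0))
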