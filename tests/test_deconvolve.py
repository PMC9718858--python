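"""Thresholded AR1 deconvolution: parameters, noise estimation, solver, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calcohort import (
    Ar1Model,
    InvalidInputError,
    InvalidParameterError,
    brute_force_oracle,
    deconvolve_ar1_thresholded,
    estimate_noise_sigma,
    gamma_from_decay,
)

from conftest import GAMMA_5HZ, ar1_response


class TestGammaFromDecay:
    def test_study_parameters(self):
        assert gamma_from_decay(1.25, 5.0) == pytest.approx(np.exp(-0.16))

    def test_decay_equal_to_frame_interval(self):
        assert gamma_from_decay(0.2, 5.0) == pytest.approx(np.exp(-1.0))

    def test_long_decay_approaches_one(self):
        assert gamma_from_decay(1e6, 5.0) == pytest.approx(1.0, abs=1e-5)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            gamma_from_decay(0.0, 5.0)
        with pytest.raises(InvalidParameterError):
            gamma_from_decay(1.25, -1.0)


class TestNoiseEstimation:
    def test_constant_trace_has_zero_noise(self):
        assert estimate_noise_sigma(np.full(500, 3.0), 5.0) == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_sd_recovered(self, rng):
        x = rng.normal(0, 0.1, 20_000)
        assert estimate_noise_sigma(x, 5.0) == pytest.approx(0.1, rel=0.1)

    def test_slow_sinusoid_below_band_ignored(self, rng):
        x = rng.normal(0, 0.1, 20_000)
        t = np.arange(x.size) / 5.0
        drift = 0.5 * np.sin(2 * np.pi * 0.05 * t)  # 0.05 Hz << 1.25 Hz band edge
        a = estimate_noise_sigma(x, 5.0)
        b = estimate_noise_sigma(x + drift, 5.0)
        assert b == pytest.approx(a, rel=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_noise_sigma(np.zeros(7), 5.0)


class TestModelValidation:
    def test_gamma_bounds(self):
        with pytest.raises(InvalidParameterError):
            Ar1Model(gamma=1.0, noise_sigma=0.1)
        with pytest.raises(InvalidParameterError):
            Ar1Model(gamma=0.5, noise_sigma=-0.1)

    def test_s_min_is_multiplier_times_sigma(self, model_5hz):
        assert model_5hz.s_min == pytest.approx(0.25)


class TestGreedyDeconvolution:
    def test_silent_trace(self, model_5hz):
        train = deconvolve_ar1_thresholded(np.zeros(100), model_5hz)
        assert train.event_count == 0
        assert np.allclose(train.denoised, 0.0)

    def test_single_noiseless_kernel_recovered(self, model_5hz):
        amp = 10 * model_5hz.noise_sigma
        y = ar1_response([30], 120, amplitude=amp)
        train = deconvolve_ar1_thresholded(y, model_5hz)
        assert np.array_equal(train.event_frames, [30])
        assert train.event_amplitudes[30] == pytest.approx(amp, rel=1e-6)

    def test_subthreshold_pulse_suppressed(self, model_5hz):
        y = ar1_response([30], 120, amplitude=0.5 * model_5hz.s_min)
        train = deconvolve_ar1_thresholded(y, model_5hz)
        assert train.event_count == 0

    def test_nan_input_rejected(self, model_5hz):
        y = np.zeros(50)
        y[3] = np.nan
        with pytest.raises(InvalidInputError):
            deconvolve_ar1_thresholded(y, model_5hz)

    def test_shift_equivariance(self, model_5hz, rng):
        amp = 10 * model_5hz.noise_sigma
        noise = rng.normal(0, model_5hz.noise_sigma, 80)
        base = ar1_response([20, 50], 80, amplitude=amp) + noise
        shifted = np.concatenate([np.zeros(5), base])[:85]
        f_base = deconvolve_ar1_thresholded(base, model_5hz).event_frames
        f_shift = deconvolve_ar1_thresholded(shifted, model_5hz).event_frames
        assert np.array_equal(f_shift, f_base + 5)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_invariants_on_random_traces(self, seed):
        """Reconstruction identity and hard threshold hold for any input."""
        model_5hz = Ar1Model(gamma=GAMMA_5HZ, noise_sigma=0.1, frame_rate_hz=5.0)
        rng = np.random.default_rng(seed)
        n = 60
        spikes = rng.integers(0, n, rng.integers(0, 5))
        y = ar1_response(spikes, n, amplitude=1.0) + rng.normal(0, 0.1, n)
        train = deconvolve_ar1_thresholded(y, model_5hz)
        s, c = train.event_amplitudes, train.denoised
        recon = np.empty_like(c)
        recon[0] = s[0]
        for t in range(1, n):
            recon[t] = model_5hz.gamma * c[t - 1] + s[t]
        assert np.allclose(c, recon, atol=1e-9)
        assert np.all(c >= 0)
        assert not np.any((s > 0) & (s < train.s_min))

    def test_high_snr_isolated_spike_recovery(self, model_5hz, rng):
        # isolated 10-sigma spikes >= 3 s apart: exact count recovery
        exact = 0
        for _ in range(20):
            frames = np.sort(rng.choice(np.arange(10, 290, 16), 5, replace=False))
            y = ar1_response(frames, 300, amplitude=1.0)
            y += rng.normal(0, 0.1, 300)
            model = Ar1Model(
                gamma=GAMMA_5HZ,
                noise_sigma=estimate_noise_sigma(y, 5.0),
                frame_rate_hz=5.0,
            )
            exact += deconvolve_ar1_thresholded(y, model).event_count == 5
        assert exact >= 18


class TestBruteForceOracle:
    def test_silent_trace(self, model_5hz):
        assert brute_force_oracle(np.zeros(10), model_5hz).event_count == 0

    def test_long_trace_refused(self, model_5hz):
        with pytest.raises(InvalidParameterError):
            brute_force_oracle(np.zeros(21), model_5hz)

    def test_oracle_dominates_greedy(self, model_5hz, rng):
        """The enumerated global optimum is never worse than the heuristic."""
        for _ in range(30):
            spikes = rng.integers(0, 10, rng.integers(0, 3))
            y = ar1_response(spikes, 10, amplitude=1.0) + rng.normal(0, 0.1, 10)
            o = brute_force_oracle(y, model_5hz)
            g = deconvolve_ar1_thresholded(y, model_5hz)
            assert o.objective <= g.objective + 1e-9
            assert not np.any(
                (o.event_amplitudes > 0) & (o.event_amplitudes < model_5hz.s_min - 1e-9)
            )

    def test_exact_recovery_of_clean_kernel(self, model_5hz):
        y = ar1_response([4], 12, amplitude=1.0)
        o = brute_force_oracle(y, model_5hz)
        assert np.array_equal(o.event_frames, [4])
        assert o.objective == pytest.approx(0.0, abs=1e-15)
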