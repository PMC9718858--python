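"""Synthetic cohort generator: spike trains, modulation, rendering, cohorts."""

import numpy as np
import pytest

from calcohort import (
    InvalidParameterError,
    SimulationConfig,
    plaque_modulated_rate,
    render_trace,
    simulate_cohort,
    simulate_spike_train,
)
from calcohort.deconvolve import Ar1Model, deconvolve_ar1_thresholded

from conftest import GAMMA_5HZ


class TestSpikeTrain:
    def test_zero_rate_gives_empty_train(self, rng):
        assert simulate_spike_train(0.0, 100.0, 5.0, rng).size == 0

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            simulate_spike_train(-0.1, 100.0, 5.0, rng)

    def test_support_bounded_by_frame_count(self, rng):
        frames = simulate_spike_train(1.0, 100.0, 5.0, rng)
        assert frames.min() >= 0 and frames.max() < 500

    def test_poisson_mean_count(self, rng):
        # 0.05 Hz x 100 s over many replicates -> mean 5 within MC error
        counts = [simulate_spike_train(0.05, 100.0, 5.0, rng).size for _ in range(10_000)]
        se = np.sqrt(5.0 / 10_000)
        assert abs(np.mean(counts) - 5.0) < 5 * se


class TestPlaqueModulation:
    def test_no_modulation_returns_base(self):
        assert plaque_modulated_rate(0.05, 37.0, 0.0, 40.0) == pytest.approx(0.05)

    def test_asymptote_far_from_plaque(self):
        assert plaque_modulated_rate(0.05, 1e9, 2.0, 40.0) == pytest.approx(0.05)

    def test_value_at_plaque_center(self):
        # base 0.032, A 2, at d = 0 -> 0.032 * 3 = 0.096
        assert plaque_modulated_rate(0.032, 0.0, 2.0, 40.0) == pytest.approx(0.096)

    def test_monotone_nonincreasing_in_distance(self):
        d = np.linspace(0, 200, 50)
        r = [plaque_modulated_rate(0.05, x, 2.0, 40.0) for x in d]
        assert np.all(np.diff(r) <= 0)

    def test_invalid_length_scale(self):
        with pytest.raises(InvalidParameterError):
            plaque_modulated_rate(0.05, 10.0, 2.0, 0.0)


class TestRenderTrace:
    def test_silent_noiseless_neuron_is_flat_baseline(self, rng):
        roi = render_trace(np.array([], dtype=int), 50, 1.25, 1.0, 100.0, 0.0,
                           None, 5.0, rng)
        assert np.allclose(roi.soma_f, 100.0)

    def test_single_spike_decays_geometrically(self, rng):
        roi = render_trace(np.array([10]), 60, 1.25, 1.0, 100.0, 0.0, None, 5.0, rng)
        rel = roi.soma_f / 100.0 - 1.0
        ratios = rel[12:30] / rel[11:29]
        assert np.allclose(ratios, GAMMA_5HZ, atol=1e-9)

    def test_empty_time_axis_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            render_trace(np.array([], dtype=int), 0, 1.25, 1.0, 100.0, 0.0, None, 5.0, rng)

    def test_deterministic_under_fixed_seed(self):
        a = render_trace(np.array([3]), 40, 1.25, 1.0, 100.0, 0.1, None, 5.0,
                         np.random.default_rng(9))
        b = render_trace(np.array([3]), 40, 1.25, 1.0, 100.0, 0.1, None, 5.0,
                         np.random.default_rng(9))
        assert np.array_equal(a.soma_f, b.soma_f)
        assert np.array_equal(a.neuropil_f, b.neuropil_f)

    def test_noiseless_transient_count_matches_ground_truth(self, rng):
        # spikes in the same frame merge; rendered transients = unique frames
        spikes = np.array([5, 5, 20, 40])
        roi = render_trace(spikes, 60, 1.25, 1.0, 100.0, 0.0, None, 5.0, rng)
        dff = roi.soma_f / 100.0 - 1.0
        model = Ar1Model(gamma=GAMMA_5HZ, noise_sigma=0.01, frame_rate_hz=5.0)
        train = deconvolve_ar1_thresholded(dff, model)
        assert np.array_equal(train.event_frames, np.unique(spikes))


class TestSimulateCohort:
    def test_minimal_cohort_has_one_roi(self):
        cfg = SimulationConfig(cell_types=("EX",), n_animals_per_group=1,
                               n_fov_per_animal=1, n_neurons_per_fov=1,
                               duration_s=100.0, seed=1)
        cohort, truth = simulate_cohort(cfg)
        # one animal per genotype, one FOV, one neuron each
        assert cohort.n_neurons == 2
        assert len(truth.neurons) == 2

    def test_bit_reproducible_for_fixed_seed(self, small_cohort):
        cfg, cohort, truth = small_cohort
        cohort2, truth2 = simulate_cohort(cfg)
        for f1, f2 in zip(cohort.fovs, cohort2.fovs):
            for r1, r2 in zip(f1.rois, f2.rois):
                assert np.array_equal(r1.soma_f, r2.soma_f)
        assert truth.neurons.equals(truth2.neurons)

    def test_true_rate_is_spike_count_over_duration(self, small_cohort):
        cfg, cohort, truth = small_cohort
        for row in truth.neurons.itertuples():
            n_spikes = truth.spikes[(row.fov_id, row.roi_id)].size
            assert row.true_rate_hz == pytest.approx(n_spikes / cfg.duration_s)

    def test_group_rates_converge_to_configured(self):
        # law of large numbers: >= 500 neurons, 5% tolerance
        cfg = SimulationConfig(cell_types=("SOM",), n_animals_per_group=4,
                               n_fov_per_animal=5, n_neurons_per_fov=13,
                               duration_s=400.0, seed=5)
        _, truth = simulate_cohort(cfg)
        t = truth.neurons
        assert len(t) >= 500
        wt = t[t.genotype == "WT"].true_rate_hz.mean()
        app = t[t.genotype == "APP"].true_rate_hz.mean()
        assert wt == pytest.approx(0.032, rel=0.05)
        assert app == pytest.approx(0.032 * 2.7, rel=0.05)

    def test_null_generator_is_symmetric(self):
        cfg = SimulationConfig(
            cell_types=("SOM",),
            genotype_fold_change={"SOM": 1.0, "PV": 1.0, "EX": 1.0},
            plaque_modulation_amplitude=0.0,
            n_animals_per_group=4, n_fov_per_animal=3, n_neurons_per_fov=10,
            duration_s=300.0, seed=21,
        )
        _, truth = simulate_cohort(cfg)
        t = truth.neurons
        wt = t[t.genotype == "WT"].true_rate_hz.mean()
        app = t[t.genotype == "APP"].true_rate_hz.mean()
        assert app / wt == pytest.approx(1.0, abs=0.15)

    def test_app_fovs_carry_single_plaque(self, small_cohort):
        _, cohort, _ = small_cohort
        for fov in cohort.fovs:
            if fov.genotype == "APP":
                assert fov.plaque_xy is not None
            else:
                assert fov.plaque_xy is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationConfig(n_animals_per_group=0)
        with pytest.raises(InvalidParameterError):
            SimulationConfig(n_neurons_per_fov=0)
        with pytest.raises(InvalidParameterError):
            SimulationConfig(duration_s=100.3)  # non-integer frame count
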