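import numpy as np
import pytest
from dataclasses import replace

from calrecruit import (
    SimulationConfig,
    SpikeTrain,
    make_layout,
    render_movie,
    render_trace,
    simulate_experiment_set,
    simulate_spike_trains,
    simulate_session,
)
from calrecruit.errors import ConfigError, LayoutError
from calrecruit.pipeline import default_recruitment_design
from calrecruit.synthetic import FOURAP, firing_rates, recruited_mask, silent_mask


class TestSpikeTrains:
    def test_zero_rate_gives_empty_trains(self):
        cfg = SimulationConfig(n_neurons=20, basal_rate_hz=0.0, silent_fraction=0.0, seed=1)
        assert all(t.n_spikes == 0 for t in simulate_spike_trains(cfg, "basal"))

    def test_poisson_mean_count_matches_rate_times_duration(self):
        # 0.05 Hz x 600 s = 30 expected spikes; check within 3 standard errors
        cfg = SimulationConfig(
            n_neurons=200, duration_s=600.0, basal_rate_hz=0.05, silent_fraction=0.0, seed=2
        )
        counts = [t.n_spikes for t in simulate_spike_trains(cfg, "basal")]
        se = np.sqrt(30.0 / 200)
        assert abs(np.mean(counts) - 30.0) < 3 * se

    def test_forced_recruitment_activates_every_neuron(self):
        cfg = SimulationConfig(
            n_neurons=40, duration_s=600.0, silent_fraction=0.5, recruitment_prob=1.0, seed=3
        )
        trains = simulate_spike_trains(cfg, "fourap")
        assert all(t.n_spikes > 0 for t in trains)

    def test_silent_neurons_have_no_basal_spikes(self):
        cfg = SimulationConfig(n_neurons=30, silent_fraction=0.5, seed=4)
        silent = silent_mask(cfg)
        trains = simulate_spike_trains(cfg, "basal")
        assert all(trains[i].n_spikes == 0 for i in np.nonzero(silent)[0])
        assert int(silent.sum()) == 15

    def test_fourap_rates_multiply_and_recruit(self):
        cfg = SimulationConfig(n_neurons=50, silent_fraction=0.4, recruitment_prob=0.5, seed=5)
        rates = firing_rates(cfg, FOURAP)
        silent, rec = silent_mask(cfg), recruited_mask(cfg)
        boosted = cfg.basal_rate_hz * cfg.fourap_rate_multiplier
        assert np.allclose(rates[~silent], boosted)
        assert np.allclose(rates[rec], boosted)
        assert np.allclose(rates[silent & ~rec], 0.0)

    def test_determinism_same_config_same_trains(self):
        cfg = SimulationConfig(n_neurons=10, seed=6)
        a = simulate_spike_trains(cfg, "fourap")
        b = simulate_spike_trains(cfg, "fourap")
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.spike_times_s, y.spike_times_s)

    def test_poisson_dispersion_near_one(self):
        # variance/mean of spike counts over >= 500 neurons within [0.8, 1.2]
        cfg = SimulationConfig(
            n_neurons=600, duration_s=600.0, basal_rate_hz=0.05, silent_fraction=0.0, seed=7
        )
        counts = np.array([t.n_spikes for t in simulate_spike_trains(cfg, "basal")])
        ratio = counts.var() / counts.mean()
        assert 0.8 < ratio < 1.2

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(duration_s=0.0)

    @pytest.mark.parametrize(
        "bad",
        [dict(recruitment_prob=1.5), dict(silent_fraction=-0.1), dict(frame_rate_hz=0.0),
         dict(basal_rate_hz=-1.0), dict(n_neurons=-1)],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            SimulationConfig(**bad)


class TestRenderTrace:
    def quiet(self, **kw):
        base = dict(n_neurons=1, duration_s=60.0, noise_sd=0.0, drift_amplitude=0.0, seed=0)
        base.update(kw)
        return SimulationConfig(**base)

    def test_no_spikes_no_noise_gives_constant_baseline(self):
        cfg = self.quiet()
        tr = render_trace(SpikeTrain(0, np.array([]), 20.0), cfg)
        np.testing.assert_allclose(tr.values, cfg.baseline_level)

    def test_single_spike_peak_is_amplitude_percent_of_baseline(self):
        cfg = self.quiet()
        tr = render_trace(SpikeTrain(0, np.array([10.0]), 20.0), cfg)
        peak_frame = 200  # 10 s at 20 Hz, frame-aligned spike
        excess = tr.values[peak_frame] - cfg.baseline_level
        assert excess == pytest.approx(cfg.transient.amplitude_pct / 100 * cfg.baseline_level)

    def test_two_spike_superposition_closed_form(self):
        # value just after the second of two spikes 1 s apart:
        # baseline * (1 + (A/100) * (1 + exp(-1/tau)))
        cfg = self.quiet()
        tr = render_trace(SpikeTrain(0, np.array([10.0, 11.0]), 20.0), cfg)
        A, tau = cfg.transient.amplitude_pct, cfg.transient.decay_s
        expected = cfg.baseline_level * (1 + (A / 100) * (1 + np.exp(-1 / tau)))
        assert tr.values[220] == pytest.approx(expected)

    def test_superposition_equals_kernel_convolution(self):
        # frame-aligned spikes, no noise/drift: rendering must equal the
        # discrete convolution of the spike impulse train with the kernel
        cfg = self.quiet(duration_s=120.0)
        frames = np.array([100, 400, 405, 1200])
        spikes = SpikeTrain(0, frames / 20.0, 20.0)
        tr = render_trace(spikes, cfg)
        n = tr.n_frames
        impulses = np.zeros(n)
        for f in frames:
            impulses[f] += 1.0
        t = np.arange(n) / 20.0
        kernel = cfg.transient.amplitude_pct * np.exp(-t / cfg.transient.decay_s)
        sig = np.convolve(impulses, kernel)[:n]
        expected = cfg.baseline_level * (1 + sig / 100)
        np.testing.assert_allclose(tr.values, expected, atol=1e-12)

    def test_drift_is_sinusoidal_with_given_amplitude(self):
        cfg = self.quiet(drift_amplitude=5.0, duration_s=300.0)
        tr = render_trace(SpikeTrain(0, np.array([]), 20.0), cfg)
        drift_pct = 100 * (tr.values / cfg.baseline_level - 1)
        assert drift_pct.max() == pytest.approx(5.0, abs=0.01)
        assert drift_pct.min() == pytest.approx(-5.0, abs=0.01)


class TestRenderMovie:
    def test_zero_neurons_gives_pure_background(self):
        mov = render_movie([], np.zeros((0, 3)), (32, 32), background=7.0)
        np.testing.assert_allclose(mov.frames, 7.0)

    def test_three_high_contrast_somata_make_three_blobs(self, small_config):
        cfg = replace(small_config, n_neurons=3, duration_s=5.0, noise_sd=0.0,
                      drift_amplitude=0.0)
        trains = simulate_spike_trains(cfg, "basal")
        traces = [render_trace(t, cfg) for t in trains]
        layout = make_layout(3, (64, 64), radius_px=3.0)
        mov = render_movie(traces, layout, (64, 64), background=1.0)
        avg = mov.frames.mean(axis=0)
        from skimage.measure import label as cc_label

        blobs = cc_label(avg > 50.0).max()
        assert blobs == 3

    def test_constant_traces_make_identical_frames(self):
        from calrecruit import Trace

        tr = Trace(np.full(10, 5.0), 20.0)
        layout = make_layout(1, (32, 32), radius_px=3.0)
        mov = render_movie([tr], layout, (32, 32), background=1.0)
        for frame in mov.frames:
            np.testing.assert_allclose(frame, mov.frames[0])

    def test_canvas_too_small_raises(self):
        with pytest.raises(LayoutError):
            make_layout(100, (20, 20), radius_px=4.0)


class TestExperimentSet:
    def test_study_design_emits_thirty_culture_records(self):
        # 10 + 10 + 5 + 5 cultures across the genotype x treatment cells
        configs, design = default_recruitment_design()
        configs = {g: replace(c, n_neurons=5, duration_s=30.0) for g, c in configs.items()}
        records = simulate_experiment_set(configs, design, master_seed=0)
        assert len(records) == 30
        cells = {(r.genotype, r.treatment) for r in records}
        assert len(cells) == 4

    def test_same_master_seed_reproduces_tables(self):
        configs, design = default_recruitment_design()
        configs = {g: replace(c, n_neurons=4, duration_s=30.0) for g, c in configs.items()}
        design = {k: 2 for k in design}
        a = simulate_experiment_set(configs, design, master_seed=5)
        b = simulate_experiment_set(configs, design, master_seed=5)
        for ra, rb in zip(a, b):
            assert ra.labels.equals(rb.labels)
            for x, y in zip(ra.spike_trains, rb.spike_trains):
                np.testing.assert_array_equal(x.spike_times_s, y.spike_times_s)

    def test_every_trace_has_exactly_one_label(self):
        cfg = SimulationConfig(n_neurons=20, duration_s=60.0, seed=9)
        from calrecruit import simulate_culture

        rec = simulate_culture(cfg, "basal", artifact_fraction=0.1, render_traces=True)
        assert len(rec.labels) == len(rec.traces)
        assert rec.labels["roi_id"].is_unique

    def test_null_construction_matches_between_windows(self):
        # multiplier 1 and recruitment 0: basal and 4-AP active fractions
        # should agree on average over several seeded cultures
        base = SimulationConfig(
            n_neurons=50, duration_s=120.0, fourap_rate_multiplier=1.0,
            recruitment_prob=0.0, silent_fraction=0.5,
        )
        diffs = []
        for seed in range(10):
            cfg = replace(base, seed=seed)
            nb = np.mean([t.n_spikes > 0 for t in simulate_spike_trains(cfg, "basal")])
            nf = np.mean([t.n_spikes > 0 for t in simulate_spike_trains(cfg, "fourap")])
            diffs.append(nf - nb)
        assert abs(np.mean(diffs)) < 0.05


class TestSession:
    def test_windows_exclude_stabilization_gap(self):
        cfg = SimulationConfig(n_neurons=5, duration_s=60.0, seed=11)
        ses = simulate_session(cfg, gap_s=30.0, render_traces=False)
        (b0, b1, bn), (f0, f1, fn) = ses.windows
        assert (b0, b1, bn) == (0.0, 60.0, "basal")
        assert (f0, f1, fn) == (90.0, 150.0, "fourap")
        for st in ses.truth["fourap"]:
            assert np.all(st.spike_times_s >= 90.0)

    def test_session_trace_length_covers_full_protocol(self):
        cfg = SimulationConfig(n_neurons=2, duration_s=60.0, seed=12)
        ses = simulate_session(cfg, gap_s=30.0)
        assert ses.traces[0].n_frames == int(150 * 20)
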