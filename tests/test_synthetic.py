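"""Generator contracts: target intermittency, sniff truth, planted phenotypes,
forward-model kernels and byte-level determinism."""

import numpy as np
import pytest

from plumecoding import GeneratorConfig
from plumecoding import io as pio
from plumecoding import sniff as sniffmod
from plumecoding import stimulus as stim
from plumecoding import synthetic as syn


class TestPlumeTrace:
    def test_target_hit_within_tolerance(self, cfg):
        tr = syn.gen_plume_trace(0.5, cfg, rng=np.random.default_rng(1))
        assert abs(stim.compute_intermittency(tr) - 0.5) <= 0.02

    @pytest.mark.parametrize("target", [0.1, 0.15, 0.3, 0.7, 0.9])
    def test_targets_across_range(self, cfg, target):
        tr = syn.gen_plume_trace(target, cfg, kind="binary",
                                 rng=np.random.default_rng(4))
        assert abs(stim.compute_intermittency(tr) - target) <= 0.02

    def test_cs_minus_regime(self, cfg):
        """A 0.15-target plume stays in the withhold band (<= 0.17)."""
        tr = syn.gen_plume_trace(0.15, cfg, rng=np.random.default_rng(2))
        assert stim.compute_intermittency(tr) <= 0.17

    def test_near_one_target_is_near_constant(self, cfg):
        tr = syn.gen_plume_trace(0.995, cfg, kind="binary", tol=0.005,
                                 rng=np.random.default_rng(3))
        assert stim.compute_intermittency(tr) >= 0.99

    def test_invalid_target_rejected(self, cfg):
        with pytest.raises(ValueError):
            syn.gen_plume_trace(1.0, cfg)

    def test_nonconvergence_reports_target(self, cfg):
        with pytest.raises(RuntimeError, match="0.500"):
            syn.gen_plume_trace(0.5, cfg, rng=np.random.default_rng(1),
                                tol=1e-9, max_iter=2)

    def test_normalized_to_c0(self, cfg):
        tr = syn.gen_plume_trace(0.4, cfg, rng=np.random.default_rng(8))
        assert tr.values.max() == pytest.approx(cfg.c0)
        assert tr.values.min() >= 0


class TestSquareWave:
    def test_on_time_sample_count(self, cfg):
        """8 pulses at duty 50: each pulse is on for 6/8 * 0.5 = 0.375 s."""
        tr = syn.gen_square_wave(8, 50, cfg)
        runs = stim.whiff_intervals(tr)
        assert len(runs) == 8
        np.testing.assert_allclose(runs[:, 1] - runs[:, 0], 0.375, atol=2e-3)

    def test_single_short_pulse(self, cfg):
        tr = syn.gen_square_wave(1, 10, cfg)
        runs = stim.whiff_intervals(tr)
        assert len(runs) == 1
        assert runs[0, 1] - runs[0, 0] == pytest.approx(0.6, abs=2e-3)
        assert stim.compute_intermittency(tr) == pytest.approx(0.1, abs=1e-3)

    @pytest.mark.parametrize("bad", [(0, 50), (9, 50), (5, 0), (5, 100)])
    def test_invalid_args(self, cfg, bad):
        with pytest.raises(ValueError):
            syn.gen_square_wave(*bad, cfg)

    def test_amplitude_is_c0(self, cfg):
        tr = syn.gen_square_wave(4, 40, cfg)
        assert set(np.unique(tr.values)) == {0.0, cfg.c0}


class TestSniffTrace:
    @pytest.mark.parametrize("freq,expected", [(2, 12), (8, 48)])
    def test_peak_count_in_odor_window(self, cfg, freq, expected):
        _, onsets, peaks = syn.gen_sniff_trace(freq, cfg, jitter=0.0)
        in_win = np.count_nonzero((peaks >= 2.0) & (peaks < 8.0))
        assert in_win == expected

    def test_zero_jitter_onsets_recovered_exactly(self, sniff_truth):
        trace, onsets, _ = sniff_truth
        det = sniffmod.detect_sniffs(trace)
        assert det.n == onsets.size
        assert np.max(np.abs(det.onsets - onsets)) <= 1.0 / trace.rate

    def test_jittered_onsets_mostly_recovered(self):
        config = GeneratorConfig(seed=7)
        trace, onsets, _ = syn.gen_sniff_trace(
            4.0, config, rng=np.random.default_rng(7), jitter=0.10)
        det = sniffmod.detect_sniffs(trace)
        d = np.abs(det.onsets[:, None] - onsets[None, :]).min(axis=0)
        assert np.mean(d <= 1.0 / trace.rate + 1e-12) >= 0.95

    def test_biphasic_shape(self, sniff_truth):
        trace, onsets, peaks = sniff_truth
        # positive at peaks, negative after the inhalation lobe
        for p in peaks[:5]:
            assert trace.values[int(p * trace.rate)] > 0.9


class TestGlomerulusPopulation:
    def test_preset_cluster_sizes(self, cfg):
        gloms = syn.gen_glomerulus_population(
            228, syn.PRESET_N_CLUSTER1 / 228, cfg)
        labels = np.array([g.cluster for g in gloms])
        assert np.count_nonzero(labels == 1) == 37
        assert np.count_nonzero(labels == 2) == 191

    def test_all_positive_or_all_negative(self, cfg):
        pos = syn.gen_glomerulus_population(20, 0.0, cfg)
        neg = syn.gen_glomerulus_population(20, 1.0, cfg)
        assert all(g.planted_slope > 0 for g in pos)
        assert all(g.planted_slope < 0 for g in neg)

    def test_empty_population_rejected(self, cfg):
        with pytest.raises(ValueError):
            syn.gen_glomerulus_population(0, 0.5, cfg)

    def test_posterior_lateral_gain_gradient(self, cfg):
        gloms = syn.gen_glomerulus_population(200, 0.5, cfg,
                                              rng=np.random.default_rng(5))
        gain = np.array([g.gain for g in gloms])
        grad = np.array([g.ap / 256 + g.ml / 128 for g in gloms])
        assert np.corrcoef(gain, grad)[0, 1] > 0.8


class TestFluorescenceForwardModel:
    def test_impulse_response_is_exponential(self, cfg):
        """A single-sample rate impulse decays with tau = 150 ms."""
        rate = np.zeros(100)
        rate[10] = 1.0
        out = syn.exp_kernel_convolve(rate, cfg.tau_s, cfg.imaging_rate)
        a = np.exp(-1.0 / (cfg.tau_s * cfg.imaging_rate))
        tail = out[10:20]
        np.testing.assert_allclose(tail[1:] / tail[:-1], a, rtol=1e-9)

    def test_zero_rate_unit_is_drift_plus_noise(self, cfg, sniff_truth):
        _, onsets, peaks = sniff_truth
        inh = np.column_stack((onsets, peaks))
        sq = syn.gen_square_wave(5, 50, cfg)
        glom = syn.GroundTruthGlomerulus(roi_id=0, cluster=2,
                                         planted_slope=0.5, gain=0.0,
                                         latency_s=0.05, ap=100, ml=50)
        tr = syn.gen_fluorescence(glom, sq, inh, cfg, noise_sd=0.0,
                                  rng=np.random.default_rng(0))
        t = tr.times()
        c = cfg.bleach_coeffs
        expected = cfg.f0 * (1 + c[0] + c[1] * t + c[2] * t ** 2)
        np.testing.assert_allclose(tr.values, expected, rtol=1e-9)

    def test_cluster2_gi_ordering_by_duty(self, cfg, sniff_truth):
        """Whiff-driven unit spends more time above threshold at duty 80
        than duty 20, end to end through the preprocessing chain."""
        from plumecoding import glomstats, preproc
        _, onsets, peaks = sniff_truth
        inh = np.column_stack((onsets, peaks))
        events = sniffmod.SniffEvents(onsets, peaks)
        glom = syn.gen_glomerulus_population(1, 0.0, cfg)[0]
        gis = {}
        for duty in (20, 80):
            sq = syn.gen_square_wave(5, duty, cfg)
            raw = syn.gen_fluorescence(glom, sq, inh, cfg,
                                       rng=np.random.default_rng(duty))
            resp = preproc.preprocess_trace(raw, events=events)
            gis[duty] = glomstats.compute_GI(resp.z)
        assert gis[80] > gis[20]


class TestSession:
    def test_default_layout(self, go_nogo_session):
        trials, _ = go_nogo_session
        assert len(trials) == 64
        main = trials[8:]
        labels = [t.cs_label for t in main]
        assert labels.count("CSplus") == 28
        assert labels.count("CSminus") == 28
        assert all(t.cs_label == "CSplus" and t.nominal_intermittency > 0.6
                   for t in trials[:8])

    def test_deterministic_bytes(self, cfg):
        gloms = syn.gen_glomerulus_population(2, 0.5, cfg)
        t1, _ = syn.gen_session(GeneratorConfig(seed=5), gloms, n_trials=6,
                                n_engagement=0)
        t2, _ = syn.gen_session(GeneratorConfig(seed=5), gloms, n_trials=6,
                                n_engagement=0)
        assert pio.session_digest(t1) == pio.session_digest(t2)

    def test_deterministic_lick_policy_saturates(self):
        from plumecoding import behavior
        config = GeneratorConfig(seed=17)
        policy = syn.LickPolicy(slope=1e6)
        trials, _ = syn.gen_session(config, [], n_trials=64,
                                    lick_policy=policy)
        m = behavior.session_metrics(behavior.score_trials(trials))
        assert m.hr > 0.95
        assert m.fa < 0.05

    def test_empty_menu_rejected(self, cfg):
        with pytest.raises(ValueError):
            syn.gen_session(cfg, [], cs_plus_menu=())

    def test_realized_intermittency_near_nominal(self, go_nogo_session):
        trials, _ = go_nogo_session
        for tr in trials[:12]:
            realized = stim.compute_intermittency(tr.stimulus)
            assert abs(realized - tr.nominal_intermittency) <= 0.02 + 1e-9
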