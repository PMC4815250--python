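import numpy as np
import pytest

from mrcpbmi.calibration import pseudo_online_cv, select_final_model, TraceBank
from mrcpbmi.online_sim import (
    OnlineConfig,
    emg_gate,
    intent_rule,
    run_block,
    stream_predict,
    tune_online_thresholds,
)
from mrcpbmi.preprocess import filter_chain
from mrcpbmi.synthetic_data import (
    DEFAULT_MODEL_CHANNELS,
    MrcpParams,
    SessionPlan,
    generate_session,
)

MODEL_CHANNELS = list(DEFAULT_MODEL_CHANNELS)


@pytest.fixture(scope="module")
def trained_model(separable_epochs):
    rep = pseudo_online_cv(separable_epochs, 0.7, channels=MODEL_CHANNELS,
                           seed=0, keep_models=True)
    return select_final_model(rep, TraceBank(separable_epochs, MODEL_CHANNELS))


@pytest.fixture(scope="module")
def replay_session():
    return generate_session(
        SessionPlan(n_blocks=1, trials_per_block=20, catch_per_block=3, rng_seed=314),
        MrcpParams(peak_jitter_sd_s=0.05),
        noise_level_uv=0.5,
    )


class TestOnlineConfig:
    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            OnlineConfig(tau_c=1.5)

    def test_invalid_nc(self):
        with pytest.raises(ValueError):
            OnlineConfig(n_c=0)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            OnlineConfig(emg_thresh_mv=(0.0, 0.1))


class TestIntentRule:
    def test_counting_example(self):
        supra = np.array([0.6, 0.8, 0.8, 0.9]) >= 0.7
        assert intent_rule(supra, 3) == [3]

    def test_broken_run_no_intent(self):
        supra = np.array([0.8, 0.6, 0.8, 0.8]) >= 0.7
        assert intent_rule(supra, 3) == []

    def test_nc_one_fires_immediately(self):
        supra = np.array([False, True, True])
        assert intent_rule(supra, 1) == [1, 2]

    def test_counter_resets_after_fire(self):
        supra = np.ones(7, dtype=bool)
        assert intent_rule(supra, 3) == [2, 5]


class TestEmgGate:
    cfg = OnlineConfig(emg_thresh_mv=(1.0, 1.0))

    def env_with_burst(self, muscle, tick, value=2.0, n=200):
        env = np.zeros((2, n))
        env[muscle, tick] = value
        return env

    def test_crossing_within_window_accepts(self):
        # intent at 3.0 s (tick 60), biceps crosses at 3.4 s (tick 68)
        assert emg_gate(60, self.env_with_burst(0, 68), self.cfg)

    def test_crossing_after_window_rejects(self):
        # crossing at 4.2 s only (tick 84) is outside (3.0, 4.0]
        assert not emg_gate(60, self.env_with_burst(0, 84), self.cfg)

    def test_either_muscle_rule(self):
        assert emg_gate(60, self.env_with_burst(1, 70), self.cfg)

    def test_boundary_inclusive(self):
        assert emg_gate(60, self.env_with_burst(0, 80), self.cfg)  # exactly +1 s
        assert not emg_gate(60, self.env_with_burst(0, 60), self.cfg)  # at intent


class TestStreamPredict:
    def test_session_too_short_for_window(self, trained_model):
        from mrcpbmi.io_formats import RawSession

        rng = np.random.default_rng(0)
        s = RawSession(eeg=rng.normal(0, 1, (25, 125)),
                       eeg_labels=list(replay_labels()), fs=500.0)
        preds = stream_predict(s, trained_model)
        assert not preds.valid.any()
        assert preds.probs.shape == (5,)

    def test_channel_mismatch(self, trained_model):
        from mrcpbmi.io_formats import RawSession

        s = RawSession(eeg=np.zeros((2, 1000)), eeg_labels=["X1", "X2"], fs=500.0)
        with pytest.raises(ValueError):
            stream_predict(s, trained_model)

    def test_deterministic(self, replay_session, trained_model):
        a = stream_predict(replay_session, trained_model)
        b = stream_predict(replay_session, trained_model)
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_streamed_trace_matches_batch_filtering(self, replay_session, trained_model):
        # chunked streaming must bit-match whole-session preprocessing
        from mrcpbmi.features import extract_features_batch

        preds_a = stream_predict(replay_session, trained_model, chunk_s=0.37)
        preds_b = stream_predict(replay_session, trained_model, chunk_s=1000.0)
        np.testing.assert_array_equal(preds_a.probs, preds_b.probs)
        filt = filter_chain(replay_session)
        idx = [filt.eeg_labels.index(c) for c in trained_model.channels]
        trace = filt.eeg[idx].mean(axis=0)
        n_win = trained_model.n_window
        W = np.lib.stride_tricks.sliding_window_view(trace, n_win)
        p = trained_model.predict_proba_go(
            extract_features_batch(W, trained_model.go_stats, 1 / 20))
        np.testing.assert_allclose(preds_a.probs[n_win - 1:], p, atol=1e-12)

    def test_catch_like_noise_scores_low(self, trained_model):
        null = generate_session(
            SessionPlan(n_blocks=1, trials_per_block=5, catch_per_block=5, rng_seed=5),
            MrcpParams(amplitude_uv=0.0, peak_jitter_sd_s=0.0),
            noise_level_uv=0.5,
        )
        preds = stream_predict(null, trained_model, cfg=OnlineConfig(tau_c=0.5))
        assert preds.probs[preds.valid].mean() < 0.5
        assert preds.supra.mean() < 0.3


def replay_labels():
    from mrcpbmi.montage import CENTRAL_25_LABELS

    return CENTRAL_25_LABELS


class TestRunBlock:
    cfg = OnlineConfig(tau_c=0.5, n_c=3, emg_thresh_mv=(0.1, 0.1))

    def test_attempted_trials_detected_with_negative_latency(self, replay_session,
                                                             trained_model):
        outcomes, _ = run_block(replay_session, trained_model, self.cfg)
        att = [o for o in outcomes if not o.is_catch]
        det = [o for o in att if o.detected]
        assert len(det) / len(att) >= 0.9
        lats = [o.latency_s for o in det if o.latency_s is not None]
        assert np.mean(lats) < 0

    def test_catch_trials_true_negative(self, replay_session, trained_model):
        outcomes, _ = run_block(replay_session, trained_model, self.cfg)
        for o in outcomes:
            if o.is_catch:
                assert not o.detected
                assert o.timed_out

    def test_gate_is_logical_and(self, replay_session, trained_model):
        cfg = OnlineConfig(tau_c=0.5, n_c=3, emg_thresh_mv=(1e9, 1e9))
        outcomes, _ = run_block(replay_session, trained_model, cfg)
        assert all(not o.detected for o in outcomes)
        assert any(o.n_bmi_intents > 0 for o in outcomes)  # intents fired, gate blocked

    def test_detection_implies_intent_and_gate(self, replay_session, trained_model):
        outcomes, _ = run_block(replay_session, trained_model, self.cfg)
        for o in outcomes:
            if o.detected:
                assert o.bmi_intent_time_s is not None
                assert o.emg_gate_passed
                assert not o.timed_out
                assert o.final_detection_time_s >= o.t_start_s

    def test_gate_bounds_on_rates(self, replay_session, trained_model):
        from mrcpbmi.metrics import block_metrics

        rates = {}
        for mode in ("gated", "bmi", "emg"):
            outcomes, _ = run_block(replay_session, trained_model, self.cfg, mode=mode)
            bm = block_metrics(outcomes)
            rates[mode] = (bm.tpr_pct, bm.fpr_pct)
        assert rates["gated"][0] <= min(rates["bmi"][0], rates["emg"][0])
        assert rates["gated"][1] <= min(rates["bmi"][1], rates["emg"][1])

    def test_replay_determinism(self, replay_session, trained_model):
        a, fa = run_block(replay_session, trained_model, self.cfg)
        b, fb = run_block(replay_session, trained_model, self.cfg)
        assert a == b and fa == fb

    def test_unknown_mode(self, replay_session, trained_model):
        with pytest.raises(ValueError):
            run_block(replay_session, trained_model, self.cfg, mode="hybrid")


class TestThresholdTuning:
    def test_best_entry_maximizes_tpr_minus_fpr(self, replay_session, trained_model):
        tau, n_c, table = tune_online_thresholds(
            replay_session, trained_model,
            cfg=OnlineConfig(emg_thresh_mv=(0.1, 0.1)),
            tau_grid=(0.5, 0.7), nc_grid=(2, 4),
        )
        scores = {k: v[0] - v[1] for k, v in table.items()}
        assert scores[(tau, n_c)] == max(scores.values())
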