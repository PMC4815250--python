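import numpy as np
import pytest

import mrcpbmi.calibration as cal
from mrcpbmi.calibration import (
    C_GRID,
    GAMMA_GRID,
    WL_GRID_S,
    CalibratedModel,
    TraceBank,
    _trial_decisions,
    grid_search,
    optimize_window_length,
    permutation_test,
    pseudo_online_cv,
    select_final_model,
)
from mrcpbmi.synthetic_data import DEFAULT_MODEL_CHANNELS

MODEL_CHANNELS = list(DEFAULT_MODEL_CHANNELS)


class TestTrialDecisions:
    def test_three_consecutive_go(self):
        P = np.array([[0.2, 0.1, 0.3, 0.2, 0.9, 0.8, 0.7, 0.1]])
        is_go, prob = _trial_decisions(P, tau=0.5, n_consec=3)
        assert is_go[0]
        assert prob[0] == pytest.approx(np.mean([0.9, 0.8, 0.7]))

    def test_broken_run_is_nogo_with_mean_over_nogo_decisions(self):
        P = np.array([[0.8, 0.2, 0.8, 0.8, 0.1, 0.3]])
        is_go, prob = _trial_decisions(P, tau=0.5, n_consec=3)
        assert not is_go[0]
        assert prob[0] == pytest.approx(np.mean([0.2, 0.1, 0.3]))

    def test_all_supra_but_too_few_placements(self):
        P = np.array([[0.9, 0.9]])
        is_go, prob = _trial_decisions(P, tau=0.5, n_consec=3)
        assert not is_go[0]
        assert prob[0] == pytest.approx(0.9)  # fallback: mean over all placements

    def test_first_run_wins(self):
        P = np.array([[0.6, 0.6, 0.6, 0.1, 0.99, 0.99, 0.99]])
        is_go, prob = _trial_decisions(P, tau=0.5, n_consec=3)
        assert is_go[0]
        assert prob[0] == pytest.approx(0.6)


class TestPseudoOnlineCv:
    def test_separable_data_near_perfect(self, separable_epochs):
        rep = pseudo_online_cv(separable_epochs, 0.7, mode="adaptive",
                               channels=MODEL_CHANNELS, seed=0)
        assert rep.mean_accuracy >= 0.95
        assert rep.auc >= 0.99

    def test_probabilities_in_unit_interval(self, calibration_epochs):
        rep = pseudo_online_cv(calibration_epochs, 0.6, channels=MODEL_CHANNELS, seed=1)
        assert np.all((rep.assigned_probs >= 0) & (rep.assigned_probs <= 1))
        assert 0.0 <= rep.auc <= 1.0

    def test_roc_monotone(self, calibration_epochs):
        rep = pseudo_online_cv(calibration_epochs, 0.6, channels=MODEL_CHANNELS,
                               seed=1, compute_roc=True)
        fpr, tpr, _ = rep.roc
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)

    def test_auc_matches_rank_statistic_oracle(self, calibration_epochs):
        rep = pseudo_online_cv(calibration_epochs, 0.6, channels=MODEL_CHANNELS, seed=1)
        pos = rep.assigned_probs[rep.true_labels]
        neg = rep.assigned_probs[~rep.true_labels]
        # brute-force pair counting (ties count half)
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert rep.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_fold_reduction_warns_on_tiny_sets(self, separable_epochs):
        bank = TraceBank(separable_epochs, MODEL_CHANNELS)
        # restrict to 8 pairs by rebuilding a small EpochSet
        es = separable_epochs.retained()
        small = type(es)(go=es.go[:8], nogo=es.nogo[:8], trial_ids=es.trial_ids[:8],
                         channels=list(es.channels), fs=es.fs, t_start=es.t_start)
        with pytest.warns(UserWarning, match="reducing folds"):
            rep = pseudo_online_cv(small, 0.7, channels=MODEL_CHANNELS, seed=0)
        assert len(rep.fold_accuracies) == 8

    def test_no_lookahead_in_placement_cache(self, calibration_epochs):
        # placements whose edge precedes sample k are unaffected by later samples
        bank = TraceBank(calibration_epochs, MODEL_CHANNELS)
        n_win = 15
        W, static = bank.cache(n_win)
        k = 40
        bank2 = TraceBank(calibration_epochs, MODEL_CHANNELS)
        bank2.traces = bank2.traces.copy()
        bank2.traces[:, k:] += 1e3  # corrupt the future
        W2, static2 = bank2.cache(n_win)
        n_early = k - n_win + 1  # placements fully inside samples < k
        np.testing.assert_array_equal(W[:, :n_early], W2[:, :n_early])
        np.testing.assert_array_equal(static[:, :n_early], static2[:, :n_early])


class TestGridSearch:
    def test_exact_run_accounting_and_tie_rule(self, monkeypatch, calibration_epochs):
        calls = []

        def fake_cv(bank, labels, wl_s, mode, C, gamma, seed, **kw):
            calls.append((C, gamma))
            return cal.CvReport(wl_s=wl_s, mode=mode, C=C, gamma=gamma,
                                fold_accuracies=[0.5], assigned_probs=np.zeros(2),
                                true_labels=np.array([True, False]),
                                predicted_labels=np.zeros(2, bool), auc=0.5)

        monkeypatch.setattr(cal, "_cv_run", fake_cv)
        C, gamma, table = grid_search(calibration_epochs, 0.7, channels=MODEL_CHANNELS)
        assert len(calls) == len(C_GRID) * len(GAMMA_GRID) == 12
        assert (C, gamma) == (10.0, 0.2)  # all tie -> smallest C, then gamma
        assert len(table) == 12

    def test_best_pair_matches_exhaustive_table(self, separable_epochs):
        C, gamma, table = grid_search(separable_epochs, 0.7, channels=MODEL_CHANNELS,
                                      seed=0, c_grid=(10.0, 100.0), gamma_grid=(0.2, 0.5))
        assert table[(C, gamma)] == max(table.values())


class TestWindowOptimization:
    def test_eleven_candidates(self):
        assert len(WL_GRID_S) == 11
        assert WL_GRID_S[0] == 0.50 and WL_GRID_S[-1] == 1.00
        np.testing.assert_allclose(np.diff(WL_GRID_S), 0.05)

    def test_shortest_max_auc_rule(self, monkeypatch, calibration_epochs):
        aucs = {0.5: 0.80, 0.7: 0.85, 0.9: 0.85}

        def fake_cv(bank, labels, wl_s, mode, C, gamma, seed, **kw):
            return cal.CvReport(wl_s=wl_s, mode=mode, C=C, gamma=gamma,
                                fold_accuracies=[0.5], assigned_probs=np.zeros(2),
                                true_labels=np.array([True, False]),
                                predicted_labels=np.zeros(2, bool),
                                auc=aucs[wl_s])

        monkeypatch.setattr(cal, "_cv_run", fake_cv)
        wl_o, reports = optimize_window_length(calibration_epochs,
                                               channels=MODEL_CHANNELS,
                                               wl_grid=(0.5, 0.7, 0.9))
        assert wl_o == 0.7
        assert set(reports) == {0.5, 0.7, 0.9}

    def test_all_equal_aucs_pick_shortest(self, monkeypatch, calibration_epochs):
        def fake_cv(bank, labels, wl_s, mode, C, gamma, seed, **kw):
            return cal.CvReport(wl_s=wl_s, mode=mode, C=C, gamma=gamma,
                                fold_accuracies=[0.5], assigned_probs=np.zeros(2),
                                true_labels=np.array([True, False]),
                                predicted_labels=np.zeros(2, bool), auc=0.77)

        monkeypatch.setattr(cal, "_cv_run", fake_cv)
        wl_o, _ = optimize_window_length(calibration_epochs, channels=MODEL_CHANNELS)
        assert wl_o == 0.50


class TestFinalModel:
    def test_max_accuracy_fold_selected(self, calibration_epochs):
        rep = pseudo_online_cv(calibration_epochs, 0.7, channels=MODEL_CHANNELS,
                               seed=2, keep_models=True)
        bank = TraceBank(calibration_epochs, MODEL_CHANNELS)
        model = select_final_model(rep, bank)
        k = int(np.argmax(rep.fold_accuracies))
        assert model.meta["fold"] == k
        assert model.meta["fold_accuracy"] == rep.fold_accuracies[k]

    def test_refit_sanity_on_own_training_windows(self, separable_epochs):
        rep = pseudo_online_cv(separable_epochs, 0.7, channels=MODEL_CHANNELS,
                               seed=0, keep_models=True)
        bank = TraceBank(separable_epochs, MODEL_CHANNELS)
        model = select_final_model(rep, bank)
        p = model.predict_proba_go(model.train_X)
        acc = ((p >= 0.5).astype(int) == model.train_y).mean()
        assert acc >= model.meta["fold_accuracy"] - 0.1

    def test_requires_kept_models(self, calibration_epochs):
        rep = pseudo_online_cv(calibration_epochs, 0.7, channels=MODEL_CHANNELS, seed=2)
        with pytest.raises(ValueError):
            select_final_model(rep, TraceBank(calibration_epochs, MODEL_CHANNELS))

    def test_json_round_trip_preserves_predictions(self, tmp_path, separable_epochs, rng):
        rep = pseudo_online_cv(separable_epochs, 0.7, channels=MODEL_CHANNELS,
                               seed=0, keep_models=True)
        model = select_final_model(rep, TraceBank(separable_epochs, MODEL_CHANNELS))
        model.to_json(tmp_path / "m.json")
        loaded = CalibratedModel.from_json(tmp_path / "m.json")
        feats = rng.normal(0, 1, (20, 4))
        np.testing.assert_allclose(loaded.predict_proba_go(feats),
                                   model.predict_proba_go(feats), atol=1e-9)
        assert loaded.wl_s == model.wl_s
        assert loaded.channels == model.channels


class TestPermutationTest:
    def test_add_one_convention_single_perm(self, separable_epochs):
        res = permutation_test(separable_epochs, 0.7, channels=MODEL_CHANNELS,
                               n_perm=1, seed=0)
        assert res.observed_accuracy > res.null_accuracies[0]
        assert res.p_value == pytest.approx(0.5)

    def test_null_mean_near_chance(self, calibration_epochs):
        res = permutation_test(calibration_epochs, 0.7, channels=MODEL_CHANNELS,
                               n_perm=15, seed=3)
        assert abs(res.null_mean - 0.5) < 0.05
        assert res.p_value < 0.1  # real labels beat shuffled ones

    def test_invalid_n_perm(self, calibration_epochs):
        with pytest.raises(ValueError):
            permutation_test(calibration_epochs, 0.7, n_perm=0)


class TestChronologyAndDeterminism:
    def test_cv_deterministic(self, calibration_epochs):
        a = pseudo_online_cv(calibration_epochs, 0.6, channels=MODEL_CHANNELS, seed=5)
        b = pseudo_online_cv(calibration_epochs, 0.6, channels=MODEL_CHANNELS, seed=5)
        assert a.fold_accuracies == b.fold_accuracies
        np.testing.assert_array_equal(a.assigned_probs, b.assigned_probs)
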