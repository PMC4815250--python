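"""Go/No-go SVM calibration with simulated real-time cross-validation.

Training extracts one feature window per epoch (adaptive or fixed placement);
testing slides a same-length window in 50 ms steps through each held-out
epoch, classifies every placement at tau = 0.5 and applies the
three-consecutive-Go rule to reach a trial-level decision:

* three consecutive Go placements -> the trial is Go, scored with the mean
  probability of those three placements;
* otherwise -> No-go, scored with the mean probability over the placements
  decided No-go.

Window length is optimized over the 0.5-1.0 s grid (50 ms steps, 11
candidates) by ROC area: the shortest length attaining the maximum AUC wins.
(C, gamma) come from a grid search over C in {10, 100, 1000} and gamma in
{0.2, 0.5, 0.8, 1}.  Significance is assessed by label permutation.

Statistical hygiene notes (documented deviations): the Go-cluster mean and
covariance used by the Mahalanobis feature, and the feature z-scoring, are
fit on each training fold only, never on held-out trials; adaptive-window
screening (peak earlier than -1.5 s) removes trials from training folds only,
since a deployed system cannot screen unseen data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import (
    ADAPTIVE_REJECT_BEFORE_S,
    FIXED_GO_EDGE_S,
    NOGO_EDGE_S,
    PEAK_SEARCH_INTERVAL_S,
    GoClusterStats,
    find_negative_peak,
    fit_go_stats,
    spatial_average,
    window_n_samples,
)
from .preprocess import EpochSet

__all__ = [
    "C_GRID",
    "GAMMA_GRID",
    "WL_GRID_S",
    "CvReport",
    "CalibratedModel",
    "TraceBank",
    "pseudo_online_cv",
    "grid_search",
    "optimize_window_length",
    "select_final_model",
    "permutation_test",
    "calibrate",
]

C_GRID = (10.0, 100.0, 1000.0)
GAMMA_GRID = (0.2, 0.5, 0.8, 1.0)
#: Candidate window lengths: 0.5 s to 1.0 s in 50 ms steps.
WL_GRID_S = tuple(np.round(np.arange(0.50, 1.0001, 0.05), 2))

DEFAULT_SVM_PARAMS = (10.0, 0.5)
TAU_OFFLINE = 0.5
N_CONSECUTIVE = 3


def _fit_svc(X: np.ndarray, y: np.ndarray, mu: np.ndarray, sd: np.ndarray,
             C: float, gamma: float, random_state: int) -> SVC:
    """C-SVC with RBF kernel and Platt probability outputs on z-scored data."""
    svm = SVC(C=C, gamma=gamma, kernel="rbf", probability=True,
              random_state=random_state)
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates probability=True; the Platt-style outputs
        # are exactly what the method requires, so keep it while it exists
        warnings.simplefilter("ignore", FutureWarning)
        svm.fit((X - mu) / sd, y)
    return svm


# ---------------------------------------------------------------------------
# trace bank: everything label-independent, computed once


class TraceBank:
    """Spatial-average traces of all epochs plus per-window-length caches.

    Rows 0..N-1 are the Go-aligned epochs, rows N..2N-1 the No-go-aligned
    ones of the same trials.  Caches hold, per window sample count, the
    sliding amplitude-vector view and the three label-independent features
    (slope, negative peak, area) for every placement.
    """

    def __init__(self, epochs: EpochSet, channels: list[str] | None = None):
        es = epochs.retained()
        if es.n_pairs < 2:
            raise ValueError("need at least two retained trial pairs")
        idx = None
        if channels is not None:
            idx = [es.channels.index(c) for c in channels]
        go = spatial_average(es.go, idx)
        nogo = spatial_average(es.nogo, idx)
        self.traces = np.concatenate([go, nogo], axis=0)
        self.base_labels = np.concatenate(
            [np.ones(es.n_pairs, dtype=bool), np.zeros(es.n_pairs, dtype=bool)]
        )
        self.fs = es.fs
        self.t_start = es.t_start
        self.dt = 1.0 / es.fs
        self.n_times = es.n_times
        self.channels = channels if channels is not None else list(es.channels)
        self.trial_ids = es.trial_ids
        self.peaks = np.array([
            find_negative_peak(tr, self.fs, self.t_start, PEAK_SEARCH_INTERVAL_S)
            for tr in self.traces
        ])
        self._caches: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def n_epochs(self) -> int:
        return self.traces.shape[0]

    def time_to_index(self, t: float) -> int:
        return round((t - self.t_start) * self.fs)

    def cache(self, n_win: int) -> tuple[np.ndarray, np.ndarray]:
        """(sliding windows (2N, n_placements, n_win), static feats (2N, n_p, 3))."""
        if n_win not in self._caches:
            W = np.lib.stride_tricks.sliding_window_view(self.traces, n_win, axis=1)
            t = np.arange(n_win) * self.dt
            tc = t - t.mean()
            slope = (W @ tc) / (tc @ tc)
            neg_peak = W.min(axis=2)
            area = np.trapezoid(W, dx=self.dt, axis=2)
            static = np.stack([slope, neg_peak, area], axis=-1)
            self._caches[n_win] = (W, static)
        return self._caches[n_win]

    def edge_indices(self, labels: np.ndarray, n_win: int, mode: str) -> np.ndarray:
        """Training-window edge sample per epoch given its (possibly shuffled)
        label; adaptive Go edges sit at the per-trace negative peak, clamped
        so the window fits the epoch."""
        edges = np.full(self.n_epochs, self.time_to_index(NOGO_EDGE_S))
        if mode == "adaptive":
            peak_idx = np.round((self.peaks - self.t_start) * self.fs).astype(int)
            go_edges = np.clip(peak_idx, n_win - 1, self.n_times - 1)
        elif mode == "fixed":
            go_edges = np.full(self.n_epochs, self.time_to_index(FIXED_GO_EDGE_S))
        else:
            raise ValueError(f"mode must be 'adaptive' or 'fixed', got {mode!r}")
        edges[labels] = np.broadcast_to(go_edges, (self.n_epochs,))[labels]
        return edges

    def screened_out(self, labels: np.ndarray, mode: str) -> np.ndarray:
        """Epochs excluded from *training*: Go-labeled traces whose negative
        peak precedes -1.5 s (strictly) under the adaptive scheme."""
        if mode != "adaptive":
            return np.zeros(self.n_epochs, dtype=bool)
        return labels & (self.peaks < ADAPTIVE_REJECT_BEFORE_S)


# ---------------------------------------------------------------------------
# reports / model containers


@dataclass
class FoldModel:
    svm: SVC
    go_stats: GoClusterStats
    scaler_mu: np.ndarray
    scaler_sd: np.ndarray
    train_X: np.ndarray
    train_y: np.ndarray
    random_state: int


@dataclass
class CvReport:
    wl_s: float
    mode: str
    C: float
    gamma: float
    fold_accuracies: list[float]
    assigned_probs: np.ndarray
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    auc: float
    roc: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    fold_models: list[FoldModel] | None = None
    fold_test_indices: list[np.ndarray] | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class CalibratedModel:
    """Everything the replay simulator needs to score a 50 ms tick."""

    svm: SVC
    C: float
    gamma: float
    go_stats: GoClusterStats
    scaler_mu: np.ndarray
    scaler_sd: np.ndarray
    channels: list[str]
    wl_s: float
    fs: float = 20.0
    tau: float = TAU_OFFLINE
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None
    random_state: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_window(self) -> int:
        return window_n_samples(self.wl_s, self.fs)

    def predict_proba_go(self, feats: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(feats) - self.scaler_mu) / self.scaler_sd
        go_col = int(np.where(self.svm.classes_ == 1)[0][0])
        return self.svm.predict_proba(Z)[:, go_col]

    def to_json(self, path: str | Path) -> None:
        """Serialize as JSON: hyperparameters + the training set, from which
        the SVM is refit deterministically on load (version-robust, avoids
        pickling estimator internals)."""
        if self.train_X is None:
            raise ValueError("model was built without retained training data")
        payload = {
            "format": "mrcpbmi-model-v1",
            "C": self.C,
            "gamma": self.gamma,
            "wl_s": self.wl_s,
            "fs": self.fs,
            "tau": self.tau,
            "channels": self.channels,
            "random_state": self.random_state,
            "scaler_mu": self.scaler_mu.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "go_mu": self.go_stats.mu.tolist(),
            "go_sigma": self.go_stats.sigma.tolist(),
            "ridge_eps": self.go_stats.ridge_eps,
            "train_X": self.train_X.tolist(),
            "train_y": self.train_y.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibratedModel":
        p = json.loads(Path(path).read_text())
        if p.get("format") != "mrcpbmi-model-v1":
            raise ValueError("not a mrcpbmi model file")
        X = np.asarray(p["train_X"], dtype=np.float64)
        y = np.asarray(p["train_y"], dtype=int)
        mu = np.asarray(p["scaler_mu"])
        sd = np.asarray(p["scaler_sd"])
        svm = _fit_svc(X, y, mu, sd, p["C"], p["gamma"], p["random_state"])
        go_stats = fit_go_stats_from_saved(
            np.asarray(p["go_mu"]), np.asarray(p["go_sigma"]), p["ridge_eps"]
        )
        return cls(
            svm=svm, C=p["C"], gamma=p["gamma"], go_stats=go_stats,
            scaler_mu=mu, scaler_sd=sd, channels=list(p["channels"]),
            wl_s=p["wl_s"], fs=p["fs"], tau=p["tau"], train_X=X, train_y=y,
            random_state=p["random_state"], meta=p.get("meta", {}),
        )


def fit_go_stats_from_saved(mu: np.ndarray, sigma: np.ndarray, ridge_eps: float) -> GoClusterStats:
    reg = sigma + ridge_eps * np.eye(len(mu))
    return GoClusterStats(mu=mu, sigma=sigma, sigma_inv=np.linalg.inv(reg),
                          ridge_eps=ridge_eps, n_window=len(mu))


# ---------------------------------------------------------------------------
# the CV engine


def _trial_decisions(P: np.ndarray, tau: float, n_consec: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Trial-level (is_go, assigned_prob) from placement probabilities P
    (rows = epochs, columns = chronological placements)."""
    dec = P >= tau
    n_rows, n_p = P.shape
    is_go = np.zeros(n_rows, dtype=bool)
    prob = np.zeros(n_rows)
    if n_p >= n_consec:
        runs = np.lib.stride_tricks.sliding_window_view(dec, n_consec, axis=1).all(axis=2)
    else:
        runs = np.zeros((n_rows, 0), dtype=bool)
    for i in range(n_rows):
        hit = np.flatnonzero(runs[i])
        if hit.size:
            j = hit[0]
            is_go[i] = True
            prob[i] = P[i, j:j + n_consec].mean()
        else:
            nogo_mask = ~dec[i]
            prob[i] = P[i, nogo_mask].mean() if nogo_mask.any() else P[i].mean()
    return is_go, prob


def _fit_fold(bank: TraceBank, labels: np.ndarray, train_idx: np.ndarray,
              n_win: int, mode: str, C: float, gamma: float, random_state: int,
              ) -> FoldModel:
    W, static = bank.cache(n_win)
    screened = bank.screened_out(labels, mode)
    train = np.asarray(train_idx)
    train = train[~screened[train]]
    edges = bank.edge_indices(labels, n_win, mode)
    placement = edges - (n_win - 1)
    amps = W[train, placement[train], :]
    y_train = labels[train].astype(int)
    if y_train.sum() < 2:
        raise ValueError("fewer than two Go-labeled training epochs after screening")
    stats = fit_go_stats(amps[y_train == 1])
    diff = amps - stats.mu
    mahal = np.sqrt(np.maximum(
        np.einsum("ij,jk,ik->i", diff, stats.sigma_inv, diff), 0.0))
    X = np.column_stack([static[train, placement[train], :], mahal])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    svm = _fit_svc(X, y_train, mu, sd, C, gamma, random_state)
    return FoldModel(svm=svm, go_stats=stats, scaler_mu=mu, scaler_sd=sd,
                     train_X=X, train_y=y_train, random_state=random_state)


def _score_placements(bank: TraceBank, fm: FoldModel, rows: np.ndarray,
                      n_win: int) -> np.ndarray:
    """P(y=Go|x) for every sliding placement of the given epochs."""
    W, static = bank.cache(n_win)
    amps = W[rows]
    diff = amps - fm.go_stats.mu
    mahal = np.sqrt(np.maximum(
        np.einsum("apj,jk,apk->ap", diff, fm.go_stats.sigma_inv, diff), 0.0))
    feats = np.concatenate([static[rows], mahal[..., None]], axis=-1)
    flat = (feats.reshape(-1, 4) - fm.scaler_mu) / fm.scaler_sd
    go_col = int(np.where(fm.svm.classes_ == 1)[0][0])
    P = fm.svm.predict_proba(flat)[:, go_col]
    return P.reshape(amps.shape[0], amps.shape[1])


def _cv_run(bank: TraceBank, labels: np.ndarray, wl_s: float, mode: str,
            C: float, gamma: float, seed: int, n_folds: int = 10,
            tau: float = TAU_OFFLINE, n_consec: int = N_CONSECUTIVE,
            keep_models: bool = False, compute_roc: bool = False) -> CvReport:
    n_win = window_n_samples(wl_s, bank.fs)
    n_per_class = int(min(labels.sum(), (~labels).sum()))
    folds = n_folds
    if n_per_class < n_folds:
        warnings.warn(
            f"only {n_per_class} epochs per class; reducing folds to {n_per_class}"
        )
        folds = max(2, n_per_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs: list[float] = []
    models: list[FoldModel] = []
    test_sets: list[np.ndarray] = []
    assigned = np.zeros(bank.n_epochs)
    predicted = np.zeros(bank.n_epochs, dtype=bool)
    for k, (train_idx, test_idx) in enumerate(skf.split(bank.traces, labels)):
        fm = _fit_fold(bank, labels, train_idx, n_win, mode, C, gamma,
                       random_state=seed + k)
        P = _score_placements(bank, fm, test_idx, n_win)
        is_go, prob = _trial_decisions(P, tau, n_consec)
        assigned[test_idx] = prob
        predicted[test_idx] = is_go
        accs.append(float((is_go == labels[test_idx]).mean()))
        if keep_models:
            models.append(fm)
            test_sets.append(test_idx)
    auc = float(roc_auc_score(labels.astype(int), assigned))
    roc = roc_curve(labels.astype(int), assigned) if compute_roc else None
    return CvReport(
        wl_s=wl_s, mode=mode, C=C, gamma=gamma, fold_accuracies=accs,
        assigned_probs=assigned, true_labels=labels.copy(),
        predicted_labels=predicted, auc=auc, roc=roc,
        fold_models=models if keep_models else None,
        fold_test_indices=test_sets if keep_models else None,
    )


# ---------------------------------------------------------------------------
# public operations


def pseudo_online_cv(epochs: EpochSet | TraceBank, wl_s: float,
                     svm_params: tuple[float, float] = DEFAULT_SVM_PARAMS,
                     mode: str = "adaptive", channels: list[str] | None = None,
                     n_folds: int = 10, seed: int = 0, tau: float = TAU_OFFLINE,
                     n_consec: int = N_CONSECUTIVE, keep_models: bool = False,
                     compute_roc: bool = True) -> CvReport:
    """Stratified 10-fold CV whose test phase slides a causal window in 50 ms
    steps through each held-out epoch (simulated real-time evaluation)."""
    bank = epochs if isinstance(epochs, TraceBank) else TraceBank(epochs, channels)
    C, gamma = svm_params
    return _cv_run(bank, bank.base_labels, wl_s, mode, C, gamma, seed,
                   n_folds=n_folds, tau=tau, n_consec=n_consec,
                   keep_models=keep_models, compute_roc=compute_roc)


def grid_search(epochs: EpochSet | TraceBank, wl_s: float, mode: str = "adaptive",
                channels: list[str] | None = None, seed: int = 0,
                c_grid: tuple = C_GRID, gamma_grid: tuple = GAMMA_GRID,
                n_folds: int = 10) -> tuple[float, float, dict]:
    """Best (C, gamma) by mean CV accuracy; ties prefer smaller C, then gamma."""
    bank = epochs if isinstance(epochs, TraceBank) else TraceBank(epochs, channels)
    table: dict[tuple[float, float], float] = {}
    best = None
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            rep = _cv_run(bank, bank.base_labels, wl_s, mode, C, gamma, seed,
                          n_folds=n_folds)
            table[(C, gamma)] = rep.mean_accuracy
            if best is None or rep.mean_accuracy > table[best]:
                best = (C, gamma)
    return best[0], best[1], table


def optimize_window_length(epochs: EpochSet | TraceBank, mode: str = "adaptive",
                           svm_params: tuple[float, float] = DEFAULT_SVM_PARAMS,
                           channels: list[str] | None = None,
                           wl_grid: tuple = WL_GRID_S, seed: int = 0,
                           n_folds: int = 10) -> tuple[float, dict[float, CvReport]]:
    """Evaluate every candidate length; the shortest length attaining the
    maximum ROC area is the optimal window length."""
    bank = epochs if isinstance(epochs, TraceBank) else TraceBank(epochs, channels)
    C, gamma = svm_params
    reports: dict[float, CvReport] = {}
    for wl in wl_grid:
        reports[wl] = _cv_run(bank, bank.base_labels, float(wl), mode, C, gamma, seed,
                              n_folds=n_folds)
    wl_o = None
    best_auc = -np.inf
    for wl in sorted(reports):
        if reports[wl].auc > best_auc + 1e-12:
            best_auc = reports[wl].auc
            wl_o = wl
    return float(wl_o), reports


def select_final_model(report: CvReport, bank: TraceBank,
                       tau: float = TAU_OFFLINE) -> CalibratedModel:
    """Package the fold with the highest accuracy (first fold on ties)."""
    if not report.fold_models:
        raise ValueError("run pseudo_online_cv with keep_models=True first")
    k = int(np.argmax(report.fold_accuracies))
    fm = report.fold_models[k]
    return CalibratedModel(
        svm=fm.svm, C=report.C, gamma=report.gamma, go_stats=fm.go_stats,
        scaler_mu=fm.scaler_mu, scaler_sd=fm.scaler_sd,
        channels=list(bank.channels), wl_s=report.wl_s, fs=bank.fs, tau=tau,
        train_X=fm.train_X, train_y=fm.train_y, random_state=fm.random_state,
        meta={"fold": k, "fold_accuracy": report.fold_accuracies[k],
              "cv_mean_accuracy": report.mean_accuracy, "auc": report.auc,
              "mode": report.mode},
    )


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float

    @property
    def null_mean(self) -> float:
        return float(self.null_accuracies.mean())


def permutation_test(epochs: EpochSet | TraceBank, wl_s: float,
                     svm_params: tuple[float, float] = DEFAULT_SVM_PARAMS,
                     mode: str = "adaptive", channels: list[str] | None = None,
                     n_perm: int = 200, seed: int = 0, n_folds: int = 10,
                     ) -> PermutationResult:
    """Label-permutation significance test.

    The class labels of the 2N epochs are shuffled ``n_perm`` times; for each
    permutation the full pseudo-online CV is repeated and its mean accuracy
    recorded.  The add-one empirical p-value is
    ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    bank = epochs if isinstance(epochs, TraceBank) else TraceBank(epochs, channels)
    C, gamma = svm_params
    observed = _cv_run(bank, bank.base_labels, wl_s, mode, C, gamma, seed,
                       n_folds=n_folds).mean_accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(bank.base_labels)
        null[i] = _cv_run(bank, shuffled, wl_s, mode, C, gamma, seed=seed + 1 + i,
                          n_folds=n_folds).mean_accuracy
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_perm)
    return PermutationResult(observed_accuracy=observed, null_accuracies=null,
                             p_value=p)


def calibrate(epochs: EpochSet, mode: str = "adaptive",
              channels: list[str] | None = None, seed: int = 0,
              run_grid_search: bool = True, grid_wl_s: float = 0.7,
              wl_grid: tuple = WL_GRID_S, n_folds: int = 10,
              tau: float = TAU_OFFLINE) -> tuple[CalibratedModel, dict]:
    """End-to-end calibration: grid search, window-length optimization, final
    model selection.  Returns the model plus a diagnostics dict."""
    bank = TraceBank(epochs, channels)
    if run_grid_search:
        C, gamma, table = grid_search(bank, grid_wl_s, mode=mode, seed=seed,
                                      n_folds=n_folds)
    else:
        (C, gamma), table = DEFAULT_SVM_PARAMS, {}
    wl_o, reports = optimize_window_length(bank, mode=mode, svm_params=(C, gamma),
                                           wl_grid=wl_grid, seed=seed,
                                           n_folds=n_folds)
    final_rep = _cv_run(bank, bank.base_labels, wl_o, mode, C, gamma, seed,
                        n_folds=n_folds, keep_models=True, compute_roc=True)
    model = select_final_model(final_rep, bank, tau=tau)
    diag = {
        "C": C, "gamma": gamma, "grid_table": table, "wl_o_s": wl_o,
        "wl_reports": reports, "final_report": final_rep,
    }
    return model, diag
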