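"""Closed-loop replay: causal streaming, 50 ms predictions, EMG-gated intents.

The session is streamed through the same causal filter chain used for
calibration (state carried across chunks, so streamed output bit-matches
whole-session filtering).  Every 50 ms tick the trailing ``wl_O`` window of
the spatial-average trace is featurized and scored; an intent fires at the
``N_c``-th consecutive tick whose probability exceeds ``tau_c`` (the counter
fully resets after a fired intent and after a gate rejection).  A fired
intent is accepted only if either muscle's RMS envelope crosses its threshold
within the 1 s gate timer; the first accepted intent ends the trial.  Catch
trials with an accepted intent are recorded as false positives.  Intents
during fixation are logged and gate-checked but never trigger movement and do
not enter block rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibratedModel
from .features import extract_features_batch
from .io_formats import RawSession
from .preprocess import FilterChainSpec, StreamingFilterChain, condition_emg

__all__ = [
    "OnlineConfig",
    "OnlinePredictions",
    "TrialOutcome",
    "stream_predict",
    "intent_rule",
    "emg_gate",
    "run_block",
    "tune_online_thresholds",
]


@dataclass(frozen=True)
class OnlineConfig:
    tau_c: float = 0.5
    n_c: int = 3
    tick_s: float = 0.05
    emg_thresh_mv: tuple[float, float] = (0.1, 0.1)  # biceps, triceps
    gate_timeout_s: float = 1.0
    trial_timeout_s: float = 15.0
    vel_thresh_dps: float | None = None  # None -> 5% of mean peak velocity

    def __post_init__(self) -> None:
        if not 0 < self.tau_c < 1:
            raise ValueError("tau_c must lie in (0, 1)")
        if self.n_c < 1:
            raise ValueError("n_c must be >= 1")
        if any(t <= 0 for t in self.emg_thresh_mv):
            raise ValueError("EMG thresholds must be positive")


@dataclass
class OnlinePredictions:
    tick_times_s: np.ndarray
    probs: np.ndarray
    supra: np.ndarray
    valid: np.ndarray  # False while the trailing window is not yet full


@dataclass
class TrialOutcome:
    trial_id: int
    is_catch: bool
    t_start_s: float
    t_end_s: float
    bmi_intent_time_s: float | None = None
    n_bmi_intents: int = 0
    emg_gate_passed: bool = False
    final_detection_time_s: float | None = None
    time_to_detect_s: float | None = None
    latency_s: float | None = None
    timed_out: bool = True

    @property
    def detected(self) -> bool:
        return self.final_detection_time_s is not None


def stream_predict(session: RawSession, model: CalibratedModel,
                   cfg: OnlineConfig = OnlineConfig(), chunk_s: float = 1.0,
                   spec: FilterChainSpec = FilterChainSpec()) -> OnlinePredictions:
    """Causally filter the session in chunks and score every 50 ms tick.

    Each tick's feature window is the trailing ``wl_O`` of the spatial
    average; ticks before the first full window are marked invalid.
    """
    missing = [c for c in model.channels if c not in session.eeg_labels]
    if missing:
        raise ValueError(f"model channels absent from session: {missing}")
    if abs(1.0 / cfg.tick_s - spec.fs_out) > 1e-9:
        raise ValueError("tick_s must match the decimated sampling interval")
    chain = StreamingFilterChain(session.eeg_labels, session.fs, spec)
    chunk = max(1, round(chunk_s * session.fs))
    outputs = [
        chain.process(session.eeg[:, i:i + chunk])
        for i in range(0, session.n_samples, chunk)
    ]
    filtered = np.concatenate(outputs, axis=1)
    idx = [session.eeg_labels.index(c) for c in model.channels]
    trace = filtered[idx].mean(axis=0)

    n_ticks = trace.shape[0]
    n_win = model.n_window
    probs = np.zeros(n_ticks)
    valid = np.zeros(n_ticks, dtype=bool)
    if n_ticks >= n_win:
        W = np.lib.stride_tricks.sliding_window_view(trace, n_win)
        feats = extract_features_batch(W, model.go_stats, 1.0 / model.fs)
        probs[n_win - 1:] = model.predict_proba_go(feats)
        valid[n_win - 1:] = True
    supra = valid & (probs >= cfg.tau_c)
    return OnlinePredictions(
        tick_times_s=np.arange(n_ticks) * cfg.tick_s,
        probs=probs, supra=supra, valid=valid,
    )


def intent_rule(supra: np.ndarray, n_c: int) -> list[int]:
    """Tick indices at which an intent fires (N_c-th consecutive supra-
    threshold tick; counter resets after each fired intent)."""
    intents = []
    count = 0
    for k, flag in enumerate(np.asarray(supra, dtype=bool)):
        count = count + 1 if flag else 0
        if count == n_c:
            intents.append(k)
            count = 0
    return intents


def emg_gate(intent_tick: int, env: np.ndarray, cfg: OnlineConfig) -> bool:
    """Accept iff either muscle's RMS envelope crosses its threshold at any
    tick in ``(intent, intent + gate_timeout]``."""
    horizon = round(cfg.gate_timeout_s / cfg.tick_s)
    lo, hi = intent_tick + 1, min(intent_tick + horizon + 1, env.shape[1])
    if lo >= hi:
        return False
    th = np.asarray(cfg.emg_thresh_mv)[:, None]
    return bool((env[:, lo:hi] > th).any())


def _trial_windows(session: RawSession, cfg: OnlineConfig) -> list[tuple[int, bool, float, float]]:
    starts = sorted(
        (ev for ev in session.events if ev.kind in ("target_onset", "catch_target_onset")),
        key=lambda e: e.sample,
    )
    out = []
    for i, ev in enumerate(starts):
        t0 = ev.sample / session.fs
        t1 = t0 + cfg.trial_timeout_s
        if i + 1 < len(starts):
            t1 = min(t1, starts[i + 1].sample / session.fs)
        out.append((ev.trial_id, ev.kind == "catch_target_onset", t0, t1))
    return out


def _kin_onset(session: RawSession, t0: float, t1: float, vel_thresh: float) -> float | None:
    if session.kin is None:
        return None
    vel = session.kin[1]
    lo = round(t0 * session.fs_kin)
    hi = min(round(t1 * session.fs_kin), vel.shape[0])
    crossing = np.flatnonzero(np.abs(vel[lo:hi]) > vel_thresh)
    if crossing.size == 0:
        return None
    return (lo + crossing[0]) / session.fs_kin


def _default_vel_thresh(session: RawSession, windows) -> float:
    """5% of the mean per-trial peak velocity (practice-trial rule)."""
    if session.kin is None:
        return np.inf
    peaks = []
    for _, is_catch, t0, t1 in windows:
        if is_catch:
            continue
        lo = round(t0 * session.fs_kin)
        hi = min(round(t1 * session.fs_kin), session.kin.shape[1])
        seg = np.abs(session.kin[1, lo:hi])
        if seg.size and seg.max() > 0:
            peaks.append(seg.max())
    return 0.05 * float(np.mean(peaks)) if peaks else np.inf


def run_block(session: RawSession, model: CalibratedModel,
              cfg: OnlineConfig = OnlineConfig(), mode: str = "gated",
              preds: OnlinePredictions | None = None,
              ) -> tuple[list[TrialOutcome], list[dict]]:
    """Replay a session trial by trial.

    ``mode`` selects the detector: ``gated`` (BMI intents validated by the
    EMG gate), ``bmi`` (intents accepted unconditionally) or ``emg``
    (threshold crossing of the EMG envelope alone).  Returns the per-trial
    outcomes plus a log of gate-checked intents that occurred during
    fixation/inter-trial intervals (never acted on).
    """
    if mode not in ("gated", "bmi", "emg"):
        raise ValueError(f"unknown mode {mode!r}")
    if preds is None:
        preds = stream_predict(session, model, cfg)
    _, env = condition_emg(session, tick_s=cfg.tick_s)
    n_ticks = min(preds.probs.shape[0], env.shape[1])
    # recompute against cfg so a cached prediction series can be reused
    # across different tau_c values
    supra = (preds.valid & (preds.probs >= cfg.tau_c))[:n_ticks]
    env = env[:, :n_ticks]
    windows = _trial_windows(session, cfg)
    vel_thresh = cfg.vel_thresh_dps
    if vel_thresh is None:
        vel_thresh = _default_vel_thresh(session, windows)

    outcomes: list[TrialOutcome] = []
    in_trial = np.zeros(n_ticks, dtype=bool)
    th = np.asarray(cfg.emg_thresh_mv)[:, None]
    for trial_id, is_catch, t0, t1 in windows:
        k0 = int(np.ceil(t0 / cfg.tick_s))
        k1 = min(int(np.floor(t1 / cfg.tick_s)), n_ticks - 1)
        in_trial[k0:k1 + 1] = True
        out = TrialOutcome(trial_id=trial_id, is_catch=is_catch, t_start_s=t0, t_end_s=t1)
        if k0 > k1:
            outcomes.append(out)
            continue
        if mode == "emg":
            above = np.flatnonzero((env[:, k0:k1 + 1] > th).any(axis=0))
            if above.size:
                out.final_detection_time_s = (k0 + above[0]) * cfg.tick_s
                out.emg_gate_passed = True
        else:
            intents = intent_rule(supra[k0:k1 + 1], cfg.n_c)
            out.n_bmi_intents = len(intents)
            if intents:
                out.bmi_intent_time_s = (k0 + intents[0]) * cfg.tick_s
            for rel in intents:
                tick = k0 + rel
                accept = True if mode == "bmi" else emg_gate(tick, env, cfg)
                if accept:
                    out.emg_gate_passed = mode == "gated"
                    out.final_detection_time_s = tick * cfg.tick_s
                    break
        if out.final_detection_time_s is not None:
            out.timed_out = False
            out.time_to_detect_s = out.final_detection_time_s - t0
            if not is_catch:
                kin_on = _kin_onset(session, t0, t1, vel_thresh)
                if kin_on is not None:
                    out.latency_s = out.final_detection_time_s - kin_on
        outcomes.append(out)

    fixation_log: list[dict] = []
    if mode != "emg":
        # scan contiguous out-of-trial runs with a fresh counter each
        k = 0
        while k < n_ticks:
            if in_trial[k]:
                k += 1
                continue
            j = k
            while j < n_ticks and not in_trial[j]:
                j += 1
            for rel in intent_rule(supra[k:j], cfg.n_c):
                tick = k + rel
                fixation_log.append({
                    "time_s": tick * cfg.tick_s,
                    "gate_passed": emg_gate(tick, env, cfg),
                })
            k = j
    return outcomes, fixation_log


def tune_online_thresholds(session: RawSession, model: CalibratedModel,
                           cfg: OnlineConfig = OnlineConfig(),
                           tau_grid: tuple = (0.4, 0.5, 0.6, 0.7, 0.8),
                           nc_grid: tuple = (1, 2, 3, 4, 5, 6),
                           ) -> tuple[float, int, dict]:
    """Sweep (tau_c, N_c) on a held-out block, maximizing TPR - FPR."""
    table = {}
    best = None
    from dataclasses import replace as _replace
    for tau in tau_grid:
        preds = None
        for n_c in nc_grid:
            trial_cfg = _replace(cfg, tau_c=tau, n_c=n_c)
            if preds is None:
                preds = stream_predict(session, model, trial_cfg)
            outcomes, _ = run_block(session, model, trial_cfg, preds=preds)
            att = [o for o in outcomes if not o.is_catch]
            cat = [o for o in outcomes if o.is_catch]
            tpr = np.mean([o.detected for o in att]) if att else 0.0
            fpr = np.mean([o.detected for o in cat]) if cat else 0.0
            score = tpr - fpr
            table[(tau, n_c)] = (float(tpr), float(fpr))
            if best is None or score > best[0] + 1e-12:
                best = (score, tau, n_c)
    return best[1], best[2], table
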