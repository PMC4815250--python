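"""Causal delta-band conditioning and epoching.

The EEG chain is: causal 4th-order Butterworth high-pass (0.1 Hz) ->
Large-Laplacian re-reference -> causal 4th-order Butterworth low-pass (1 Hz)
-> decimation to 20 Hz.  Every stage is causal, and the streaming variant
(:class:`StreamingFilterChain`) carries IIR state across chunks so that
block-wise and whole-session processing are bit-identical — calibration and
the replay simulator therefore see exactly the same signal.

No further anti-aliasing is applied before decimation: with content limited
to <= 1 Hz by the low-pass, a 20 Hz output rate is alias-safe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io_formats import RawSession, epoch_slices
from .montage import large_laplacian_neighbors

__all__ = [
    "EpochSet",
    "FilterChainSpec",
    "StreamingFilterChain",
    "filter_chain",
    "laplacian_matrix",
    "make_epochs",
    "reject_artifact_epochs",
    "baseline_correct",
    "condition_emg",
]

EPOCH_RANGE_S = (-2.5, 1.0)


@dataclass(frozen=True)
class FilterChainSpec:
    """Parameters of the preprocessing chain."""

    hp_hz: float = 0.1
    lp_hz: float = 1.0
    order: int = 4
    fs_out: float = 20.0

    def design(self, fs: float) -> tuple[np.ndarray, np.ndarray, int]:
        factor = fs / self.fs_out
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError(
                f"sampling rate {fs} Hz is not an integer multiple of {self.fs_out} Hz"
            )
        sos_hp = signal.butter(self.order, self.hp_hz, "highpass", fs=fs, output="sos")
        sos_lp = signal.butter(self.order, self.lp_hz, "lowpass", fs=fs, output="sos")
        return sos_hp, sos_lp, int(round(factor))


def _neighbor_index_sets(labels: list[str], warn: bool = True
                         ) -> list[tuple[int, list[int]]]:
    table = large_laplacian_neighbors(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    sets = []
    orphans = []
    for lab in labels:
        neigh = table.get(lab)
        if neigh:
            sets.append((idx[lab], [idx[n] for n in neigh]))
        else:
            orphans.append(lab)
    if orphans and warn:
        warnings.warn(
            f"channels without Laplacian neighbors passed through unreferenced: {orphans}"
        )
    return sets


def _apply_laplacian(y: np.ndarray, neighbor_sets: list[tuple[int, list[int]]]) -> np.ndarray:
    """Subtract each channel's neighbor mean.

    Implemented with fixed-order elementwise sums (not a matmul) so the result
    is bitwise independent of how the time axis is chunked — required for the
    streaming == batch equality contract.
    """
    out = y.copy()
    for i, neigh in neighbor_sets:
        acc = y[neigh[0]].copy()
        for j in neigh[1:]:
            acc += y[j]
        out[i] = y[i] - acc / len(neigh)
    return out


def laplacian_matrix(labels: list[str]) -> np.ndarray:
    """Large-Laplacian re-referencing matrix for ``labels``.

    Row i is channel i minus the mean of its next-nearest neighbors; channels
    without any neighbor in the montage pass through unreferenced (warned).
    """
    table = large_laplacian_neighbors(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    L = np.eye(len(labels))
    orphans = []
    for lab, i in idx.items():
        neigh = table.get(lab)
        if not neigh:
            orphans.append(lab)
            continue
        for other in neigh:
            L[i, idx[other]] = -1.0 / len(neigh)
    if orphans:
        warnings.warn(
            f"channels without Laplacian neighbors passed through unreferenced: {orphans}"
        )
    return L


class StreamingFilterChain:
    """Chunk-wise version of :func:`filter_chain` with carried filter state.

    Feed raw EEG chunks (channels x samples at the native rate) in order;
    each call returns the newly available output samples at ``fs_out``.
    """

    def __init__(self, labels: list[str], fs: float,
                 spec: FilterChainSpec = FilterChainSpec()):
        self.spec = spec
        self.fs = fs
        self.labels = list(labels)
        self._sos_hp, self._sos_lp, self.factor = spec.design(fs)
        n_ch = len(labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._neighbor_sets = _neighbor_index_sets(labels, warn=False)
        self._zi_hp = np.zeros((self._sos_hp.shape[0], n_ch, 2))
        self._zi_lp = np.zeros((self._sos_lp.shape[0], n_ch, 2))
        self._n_in = 0  # input samples consumed so far

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.asarray(chunk, dtype=np.float64)
        if chunk.shape[0] != len(self.labels):
            raise ValueError("chunk channel count does not match montage")
        y, self._zi_hp = signal.sosfilt(self._sos_hp, chunk, axis=-1, zi=self._zi_hp)
        y = _apply_laplacian(y, self._neighbor_sets)
        y, self._zi_lp = signal.sosfilt(self._sos_lp, y, axis=-1, zi=self._zi_lp)
        # emit input-sample indices that are multiples of the decimation factor
        start = (-self._n_in) % self.factor
        out = y[:, start::self.factor]
        self._n_in += chunk.shape[1]
        return out


def filter_chain(session: RawSession, spec: FilterChainSpec = FilterChainSpec()) -> RawSession:
    """Whole-session preprocessing to ``spec.fs_out`` (default 20 Hz).

    EMG is dropped from the output (it is conditioned separately at the native
    rate by :func:`condition_emg`); kinematics pass through untouched.  Event
    samples are mapped onto the decimated grid by floor division.
    """
    sos_hp, sos_lp, factor = spec.design(session.fs)
    y = signal.sosfilt(sos_hp, session.eeg, axis=-1)
    y = _apply_laplacian(y, _neighbor_index_sets(session.eeg_labels))
    y = signal.sosfilt(sos_lp, y, axis=-1)
    y = y[:, ::factor]
    events = [replace(ev, sample=ev.sample // factor) for ev in session.events]
    return RawSession(
        eeg=y,
        eeg_labels=list(session.eeg_labels),
        fs=spec.fs_out,
        emg=None,
        emg_labels=[],
        kin=session.kin,
        fs_kin=session.fs_kin,
        events=events,
        meta={**session.meta, "preprocessed": True, "decimation_factor": factor},
    )


# ---------------------------------------------------------------------------
# epochs


@dataclass
class EpochSet:
    """Paired, labeled Go/No-go epochs at the decimated rate.

    ``go[i]`` and ``nogo[i]`` come from the same attempted trial
    (``trial_ids[i]``): Go aligned to movement-onset, No-go to target-onset.
    Rejection operates on pairs, so classes stay balanced by construction.
    """

    go: np.ndarray  # (n_pairs, n_channels, n_times)
    nogo: np.ndarray
    trial_ids: np.ndarray
    channels: list[str]
    fs: float
    t_start: float = EPOCH_RANGE_S[0]
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reject_reason: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(self.n_pairs, dtype=bool)
        if not self.reject_reason:
            self.reject_reason = [None] * self.n_pairs
        if self.go.shape != self.nogo.shape:
            raise ValueError("go/nogo epoch arrays must have identical shape")

    @property
    def n_pairs(self) -> int:
        return self.go.shape[0]

    @property
    def n_times(self) -> int:
        return self.go.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_times) / self.fs

    def retained(self) -> "EpochSet":
        keep = ~self.rejected
        return EpochSet(
            go=self.go[keep],
            nogo=self.nogo[keep],
            trial_ids=self.trial_ids[keep],
            channels=list(self.channels),
            fs=self.fs,
            t_start=self.t_start,
        )

    def concat(self, other: "EpochSet") -> "EpochSet":
        if other.channels != self.channels or other.n_times != self.n_times:
            raise ValueError("incompatible epoch sets")
        offset = self.trial_ids.max() + 1 if self.n_pairs else 0
        return EpochSet(
            go=np.concatenate([self.go, other.go]),
            nogo=np.concatenate([self.nogo, other.nogo]),
            trial_ids=np.concatenate([self.trial_ids, other.trial_ids + offset]),
            channels=list(self.channels),
            fs=self.fs,
            t_start=self.t_start,
            rejected=np.concatenate([self.rejected, other.rejected]),
            reject_reason=list(self.reject_reason) + list(other.reject_reason),
        )


def make_epochs(filtered: RawSession,
                t_range: tuple[float, float] = EPOCH_RANGE_S) -> EpochSet:
    """Cut paired Go/No-go epochs from a preprocessed session.

    Go epochs align to movement-onset, No-go to the same trial's target-onset;
    catch-trial target-onsets carry a distinct event kind and are excluded.
    Trials whose Go or No-go window falls outside the recording are skipped.
    """
    go_slices = dict_by_trial(epoch_slices(filtered, "movement_onset", t_range))
    nogo_slices = dict_by_trial(epoch_slices(filtered, "target_onset", t_range))
    trials = sorted(set(go_slices) & set(nogo_slices))
    go = np.stack([filtered.eeg[:, go_slices[t]] for t in trials]) if trials else \
        np.empty((0, len(filtered.eeg_labels), round((t_range[1] - t_range[0]) * filtered.fs)))
    nogo = np.stack([filtered.eeg[:, nogo_slices[t]] for t in trials]) if trials else go.copy()
    return EpochSet(
        go=go,
        nogo=nogo,
        trial_ids=np.asarray(trials, dtype=int),
        channels=list(filtered.eeg_labels),
        fs=filtered.fs,
        t_start=t_range[0],
    )


def dict_by_trial(slices: list[tuple[int, slice]]) -> dict[int, slice]:
    return {trial_id: sl for trial_id, sl in slices}


def reject_artifact_epochs(epochs: EpochSet, amp_thresh_uv: float = 100.0,
                           channels: list[str] | None = None) -> EpochSet:
    """Flag Go epochs whose peak-to-peak amplitude exceeds the threshold.

    Automated stand-in for visual artifact screening; the paired No-go epoch
    is removed with it, keeping the class distribution equal.
    """
    if not np.isfinite(amp_thresh_uv):
        return epochs
    if amp_thresh_uv <= 0:
        raise ValueError("amplitude threshold must be positive")
    if channels is None:
        ch_idx = slice(None)
    else:
        ch_idx = [epochs.channels.index(c) for c in channels]
    p2p = epochs.go[:, ch_idx, :].max(axis=-1) - epochs.go[:, ch_idx, :].min(axis=-1)
    bad = (p2p > amp_thresh_uv).any(axis=-1)
    rejected = epochs.rejected | bad
    reasons = [
        ("amplitude" if b and r is None else r)
        for b, r in zip(bad, epochs.reject_reason)
    ]
    return EpochSet(
        go=epochs.go,
        nogo=epochs.nogo,
        trial_ids=epochs.trial_ids,
        channels=list(epochs.channels),
        fs=epochs.fs,
        t_start=epochs.t_start,
        rejected=rejected,
        reject_reason=reasons,
    )


def baseline_correct(epoch: np.ndarray, fs: float, baseline_s: float = 0.25) -> np.ndarray:
    """Subtract the mean over the first ``baseline_s`` of the epoch.

    Used only for grand-average visualization, never in the classification
    path (it does not affect classifier accuracy and is not applied online).
    """
    n = round(baseline_s * fs)
    epoch = np.asarray(epoch, dtype=np.float64)
    return epoch - epoch[..., :n].mean(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# EMG


def condition_emg(session: RawSession, band: tuple[float, float] = (30.0, 200.0),
                  order: int = 8, rms_window_s: float = 0.3,
                  tick_s: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass EMG and compute its trailing RMS envelope on the tick grid.

    Returns ``(tick_times_s, envelope)`` with envelope shaped muscles x ticks
    in the input units (mV).  The band-pass is causal (Butterworth); the RMS
    uses a trailing ``rms_window_s`` window (shorter at the recording start).
    """
    if session.emg is None:
        raise ValueError("session has no EMG channels")
    nyq = session.fs / 2
    hi = min(band[1], 0.99 * nyq)
    sos = signal.butter(order // 2, (band[0], hi), "bandpass", fs=session.fs, output="sos")
    filt = signal.sosfilt(sos, session.emg, axis=-1)
    sq = np.concatenate([np.zeros((filt.shape[0], 1)), np.cumsum(filt**2, axis=-1)], axis=-1)
    step = round(tick_s * session.fs)
    w = round(rms_window_s * session.fs)
    ticks = np.arange(0, session.n_samples, step)
    lo = np.maximum(0, ticks - w + 1)
    counts = ticks - lo + 1
    env = np.sqrt((sq[:, ticks + 1] - sq[:, lo]) / counts)
    return ticks / session.fs, env
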