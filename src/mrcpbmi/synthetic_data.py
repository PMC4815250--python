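"""Synthetic EEG/EMG/kinematics sessions with the structure the method assumes.

Each attempted trial carries, on a configurable subset of channels, a slow
negative cortical potential: a half-cosine descent starting ~1.5-2 s before
movement onset to a negative peak near onset, followed by a linear rebound.
Per-trial latency jitter, 1/f (pink) background noise with a shared low-rank
component, a band-limited EMG burst at movement onset and a minimum-jerk
elbow trajectory complete the model.  Catch trials contain background
activity only.

Everything is driven by one seeded generator: identical seeds give
bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import Event, RawSession
from .montage import CENTRAL_25_LABELS

__all__ = [
    "MrcpParams",
    "EmgParams",
    "KinParams",
    "SessionPlan",
    "DEFAULT_AFFECTED_CHANNELS",
    "DEFAULT_MODEL_CHANNELS",
    "pink_noise",
    "mrcp_waveform",
    "min_jerk",
    "generate_trial",
    "generate_session",
]

#: Channel -> gain map for the synthetic cortical source (sensorimotor cluster).
DEFAULT_AFFECTED_CHANNELS = (
    ("FCz", 0.5), ("FC1", 0.4), ("FC2", 0.4),
    ("Cz", 1.0), ("C1", 0.7), ("C2", 0.6),
    ("CPz", 0.7), ("CP1", 0.5), ("CP2", 0.4),
)

#: Sensible default channel selection for the detection trace.
DEFAULT_MODEL_CHANNELS = ("Cz", "C1", "C2", "CPz")


@dataclass(frozen=True)
class MrcpParams:
    """Shape of the per-trial slow negative potential.

    Times are relative to the movement-onset trigger; ``peak_offset_s`` shifts
    the mean peak (negative values make the cortical peak lead the trigger).
    """

    amplitude_uv: float = -8.0
    ramp_start_s: float = -1.5
    peak_offset_s: float = 0.0
    peak_jitter_sd_s: float = 0.2
    rebound_s: float = 0.6
    affected_channels: tuple[tuple[str, float], ...] = DEFAULT_AFFECTED_CHANNELS

    def __post_init__(self) -> None:
        if self.amplitude_uv > 0:
            raise ValueError("amplitude_uv must be negative (or 0 for a null signal)")
        if self.peak_jitter_sd_s < 0:
            raise ValueError("peak_jitter_sd_s must be >= 0")
        if not self.affected_channels:
            raise ValueError("affected_channels must be non-empty")
        if self.ramp_start_s >= self.peak_offset_s:
            raise ValueError("ramp must start before the peak")


@dataclass(frozen=True)
class EmgParams:
    burst_amplitude_mv: float = 0.5
    baseline_rms_mv: float = 0.02
    burst_duration_s: float = 1.2
    delay_s: float = 0.0  # electromechanical delay of the burst onset
    band_hz: tuple[float, float] = (30.0, 200.0)


@dataclass(frozen=True)
class KinParams:
    fs: float = 1000.0
    range_deg: float = 60.0
    duration_s: float = 1.5


@dataclass(frozen=True)
class SessionPlan:
    """Trial/fixation schedule of one simulated session."""

    n_blocks: int = 1
    trials_per_block: int = 20
    catch_per_block: int = 3
    fixation_range_s: tuple[float, float] = (4.0, 6.0)
    react_range_s: tuple[float, float] = (1.5, 3.0)
    trial_timeout_s: float = 15.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.catch_per_block <= 5 <= self.trials_per_block:
            raise ValueError("need 0 <= catch_per_block <= 5 <= trials_per_block")
        lo, hi = self.fixation_range_s
        if not 0 <= lo <= hi <= self.trial_timeout_s:
            raise ValueError("fixation_range_s must lie within [0, trial_timeout_s]")


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-shaped noise of length ``n``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _background(n_ch: int, n: int, rng: np.random.Generator,
                shared_gain: float = 0.5) -> np.ndarray:
    """Per-channel pink noise plus one shared pink component, unit RMS rows."""
    indep = np.stack([pink_noise(n, rng) for _ in range(n_ch)])
    shared = pink_noise(n, rng)
    w = rng.uniform(0.5, 1.0, n_ch)
    x = indep + shared_gain * w[:, None] * shared
    rms = np.sqrt((x**2).mean(axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def mrcp_waveform(t_rel_mo: np.ndarray, params: MrcpParams, jitter_s: float = 0.0) -> np.ndarray:
    """Template amplitude at times relative to movement onset (muV, gain 1).

    Half-cosine descent from ``ramp_start_s`` to the (jittered) peak, then a
    linear rebound to baseline over ``rebound_s``.
    """
    t_peak = params.peak_offset_s + jitter_s
    t_ramp = params.ramp_start_s + jitter_s
    out = np.zeros_like(t_rel_mo, dtype=np.float64)
    ramp = (t_rel_mo >= t_ramp) & (t_rel_mo <= t_peak)
    s = (t_rel_mo[ramp] - t_ramp) / (t_peak - t_ramp)
    out[ramp] = params.amplitude_uv * 0.5 * (1 - np.cos(np.pi * s))
    if params.rebound_s > 0:
        reb = (t_rel_mo > t_peak) & (t_rel_mo <= t_peak + params.rebound_s)
        out[reb] = params.amplitude_uv * (1 - (t_rel_mo[reb] - t_peak) / params.rebound_s)
    return out


def min_jerk(t: np.ndarray, duration_s: float, range_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk position (deg) and velocity (deg/s) profiles on ``t``."""
    tau = np.clip(t / duration_s, 0.0, 1.0)
    pos = range_deg * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = range_deg / duration_s * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    vel[(t < 0) | (t > duration_s)] = 0.0
    return pos, vel


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    sos = signal.butter(4, (band[0], min(band[1], 0.99 * fs / 2)), "bandpass",
                        fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt((x**2).mean())
    return x / rms if rms > 0 else x


def generate_trial(params: MrcpParams, noise_level_uv: float = 2.0, fs: float = 500.0,
                   rng: np.random.Generator | None = None,
                   labels: list[str] | None = None,
                   t_range_s: tuple[float, float] = (-3.0, 2.0),
                   ) -> tuple[np.ndarray, float, float]:
    """One multichannel EEG segment around a movement onset.

    Returns ``(eeg, t_mo, t_peak)`` with times in seconds from segment start.
    Affected channels carry the (jittered) template plus noise; the rest
    noise only.  ``noise_level_uv`` may be 0 for a noiseless trial.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if noise_level_uv < 0:
        raise ValueError("noise_level_uv must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    labels = list(CENTRAL_25_LABELS) if labels is None else list(labels)
    n = round((t_range_s[1] - t_range_s[0]) * fs)
    t_mo = -t_range_s[0]
    jitter = rng.normal(0.0, params.peak_jitter_sd_s) if params.peak_jitter_sd_s else 0.0
    t = np.arange(n) / fs - t_mo
    wave = mrcp_waveform(t, params, jitter)
    eeg = np.zeros((len(labels), n))
    if noise_level_uv > 0:
        eeg = noise_level_uv * _background(len(labels), n, rng)
    gain = dict(params.affected_channels)
    for i, lab in enumerate(labels):
        g = gain.get(lab)
        if g:
            eeg[i] += g * wave
    t_peak = t_mo + params.peak_offset_s + jitter
    return eeg, t_mo, t_peak


def generate_session(plan: SessionPlan, params: MrcpParams = MrcpParams(),
                     emg_params: EmgParams = EmgParams(),
                     kin_params: KinParams = KinParams(),
                     noise_level_uv: float = 2.0, fs: float = 500.0,
                     labels: list[str] | None = None,
                     lead_in_s: float = 4.0, tail_s: float = 4.0) -> RawSession:
    """Full multi-block session with triggers, EMG bursts and kinematics.

    Catch-trial order within each block is a seeded shuffle; catch trials run
    for the full timeout with background activity only.  Ground truth (true
    onset and peak times per trial) is stored in ``meta['trials']``.
    """
    rng = np.random.default_rng(plan.rng_seed)
    labels = list(CENTRAL_25_LABELS) if labels is None else list(labels)

    # --- schedule ----------------------------------------------------------
    events: list[Event] = []
    truth: list[dict] = []
    t = lead_in_s
    trial_id = 0
    for _ in range(plan.n_blocks):
        is_catch = np.zeros(plan.trials_per_block, dtype=bool)
        is_catch[:plan.catch_per_block] = True
        rng.shuffle(is_catch)
        for catch in is_catch:
            t += rng.uniform(*plan.fixation_range_s)
            t_on = t
            rec = {"trial_id": trial_id, "catch": bool(catch), "t_target_on": t_on,
                   "t_mo": None, "t_peak": None}
            if catch:
                events.append(Event("catch_target_onset", round(t_on * fs), trial_id))
                t = t_on + plan.trial_timeout_s
            else:
                events.append(Event("target_onset", round(t_on * fs), trial_id))
                t_mo = t_on + rng.uniform(*plan.react_range_s)
                jitter = rng.normal(0.0, params.peak_jitter_sd_s) if params.peak_jitter_sd_s else 0.0
                events.append(Event("movement_onset", round(t_mo * fs), trial_id))
                t_reach = t_mo + kin_params.duration_s
                events.append(Event("target_reached", round(t_reach * fs), trial_id))
                rec["t_mo"] = t_mo
                rec["t_peak"] = t_mo + params.peak_offset_s + jitter
                rec["jitter"] = jitter
                t = t_reach
            truth.append(rec)
            trial_id += 1
    duration = t + tail_s
    n = round(duration * fs)

    # --- EEG ---------------------------------------------------------------
    eeg = noise_level_uv * _background(len(labels), n, rng) if noise_level_uv > 0 \
        else np.zeros((len(labels), n))
    gain = dict(params.affected_channels)
    gains = np.array([gain.get(lab, 0.0) for lab in labels])
    tgrid = np.arange(n) / fs
    for rec in truth:
        if rec["catch"]:
            continue
        t_peak = rec["t_peak"]
        lo = max(0, round((t_peak + params.ramp_start_s - params.peak_offset_s - 0.1) * fs))
        hi = min(n, round((t_peak + params.rebound_s + 0.1) * fs))
        wave = mrcp_waveform(tgrid[lo:hi] - rec["t_mo"], params, rec["jitter"])
        eeg[:, lo:hi] += gains[:, None] * wave

    # --- EMG ---------------------------------------------------------------
    emg = emg_params.baseline_rms_mv * np.stack(
        [_bandlimited_noise(n, fs, emg_params.band_hz, rng) for _ in range(2)]
    )
    for k, rec in enumerate(r for r in truth if not r["catch"]):
        t0 = rec["t_mo"] + emg_params.delay_s
        center = t0 + emg_params.burst_duration_s / 2
        sd = emg_params.burst_duration_s / 4
        lo = max(0, round((t0 - 0.05) * fs))
        hi = min(n, round((t0 + 2 * emg_params.burst_duration_s) * fs))
        envelope = np.exp(-0.5 * ((tgrid[lo:hi] - center) / sd) ** 2)
        envelope[tgrid[lo:hi] < t0] = 0.0  # burst starts at onset, not before
        muscle = k % 2  # alternate flexion (biceps) / extension (triceps)
        emg[muscle, lo:hi] += emg_params.burst_amplitude_mv * envelope * \
            _bandlimited_noise(hi - lo, fs, emg_params.band_hz, rng)

    # --- kinematics --------------------------------------------------------
    n_kin = round(duration * kin_params.fs)
    tk = np.arange(n_kin) / kin_params.fs
    pos = np.zeros(n_kin)
    vel = np.zeros(n_kin)
    for rec in truth:
        if rec["catch"]:
            continue
        p, v = min_jerk(tk - rec["t_mo"], kin_params.duration_s, kin_params.range_deg)
        # out-and-back: return to home right after the reach
        p2, v2 = min_jerk(tk - (rec["t_mo"] + kin_params.duration_s + 0.5),
                          kin_params.duration_s, kin_params.range_deg)
        pos += p - p2
        vel += v - v2

    return RawSession(
        eeg=eeg,
        eeg_labels=labels,
        fs=fs,
        emg=emg,
        emg_labels=["biceps", "triceps"],
        kin=np.stack([pos, vel]),
        fs_kin=kin_params.fs,
        events=events,
        meta={
            "generator": "mrcpbmi.synthetic_data",
            "seed": plan.rng_seed,
            "noise_level_uv": noise_level_uv,
            "trials": truth,
        },
    )
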