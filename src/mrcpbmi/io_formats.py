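"""Session container and BrainVision I/O.

A :class:`RawSession` bundles synchronized EEG (muV), bipolar EMG (mV),
elbow kinematics (deg, deg/s at their own rate) and trigger events.  Two
on-disk representations are supported:

* the *portable container*: a directory holding a JSON sidecar
  (``session.json``) plus raw little-endian float64 arrays — lossless and
  trivially inspectable;
* the BrainVision triplet (``.vhdr``/``.vmrk``/``.eeg``) with 16-bit scaled
  integers, documented as lossy (one quantization step) and without
  kinematics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Event",
    "RawSession",
    "IoFormatError",
    "EVENT_KINDS",
    "write_session",
    "read_container",
    "read_brainvision",
    "epoch_slices",
]

EVENT_KINDS = ("target_onset", "movement_onset", "target_reached", "catch_target_onset")

#: BrainVision amplitude resolution used on export (per paper's amplifier setup:
#: EEG dynamic range +/-3.2768 mV at 16 bit -> 0.1 muV/bit; EMG +/-327.68 mV -> 0.01 mV/bit).
EEG_RESOLUTION_UV = 0.1
EMG_RESOLUTION_MV = 0.01


class IoFormatError(ValueError):
    """Structured error for malformed or inconsistent session files."""


@dataclass(frozen=True)
class Event:
    """A trigger event at ``sample`` (0-based, at the session's EEG rate)."""

    kind: str
    sample: int
    trial_id: int

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise IoFormatError(f"unknown event kind {self.kind!r}")


@dataclass
class RawSession:
    """Synchronized multichannel recording with trigger events.

    ``eeg`` is channels x samples in muV; ``emg`` (optional) shares the EEG
    sampling rate and sample count and is in mV.  ``kin`` holds position and
    velocity rows at ``fs_kin``.
    """

    eeg: np.ndarray
    eeg_labels: list[str]
    fs: float
    emg: np.ndarray | None = None
    emg_labels: list[str] = field(default_factory=list)
    kin: np.ndarray | None = None
    fs_kin: float = 1000.0
    events: list[Event] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        if self.eeg.ndim != 2:
            raise IoFormatError("eeg must be 2-D (channels x samples)")
        if self.eeg.shape[0] != len(self.eeg_labels):
            raise IoFormatError(
                f"{self.eeg.shape[0]} EEG rows but {len(self.eeg_labels)} labels"
            )
        if len(set(self.eeg_labels) | set(self.emg_labels)) != len(self.eeg_labels) + len(
            self.emg_labels
        ):
            raise IoFormatError("channel labels must be unique")
        if self.emg is not None:
            self.emg = np.asarray(self.emg, dtype=np.float64)
            if self.emg.shape != (len(self.emg_labels), self.n_samples):
                raise IoFormatError("EMG shape inconsistent with labels/sample count")
        if self.kin is not None:
            self.kin = np.asarray(self.kin, dtype=np.float64)
        for ev in self.events:
            if not 0 <= ev.sample < self.n_samples:
                raise IoFormatError(f"event {ev} outside the recording")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def events_of(self, kind: str) -> list[Event]:
        return [ev for ev in self.events if ev.kind == kind]

    def copy(self) -> "RawSession":
        return replace(
            self,
            eeg=self.eeg.copy(),
            emg=None if self.emg is None else self.emg.copy(),
            kin=None if self.kin is None else self.kin.copy(),
            events=list(self.events),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# portable container


def _write_array(path: Path, arr: np.ndarray) -> None:
    np.ascontiguousarray(arr, dtype="<f8").tofile(path)


def write_session(session: RawSession, path: str | Path, format: str = "container") -> Path:
    """Write ``session`` to ``path``; see module docstring for formats."""
    path = Path(path)
    if format == "container":
        return _write_container(session, path)
    if format == "brainvision":
        return write_brainvision(session, path)
    raise ValueError(f"unknown format {format!r}")


def _write_container(session: RawSession, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "format": "mrcpbmi-container-v1",
        "fs": session.fs,
        "fs_kin": session.fs_kin,
        "eeg_labels": session.eeg_labels,
        "emg_labels": session.emg_labels,
        "n_samples": session.n_samples,
        "n_kin_samples": None if session.kin is None else int(session.kin.shape[1]),
        "events": [
            {"kind": ev.kind, "sample": int(ev.sample), "trial_id": int(ev.trial_id)}
            for ev in session.events
        ],
        "meta": session.meta,
    }
    (path / "session.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    _write_array(path / "eeg.bin", session.eeg)
    if session.emg is not None:
        _write_array(path / "emg.bin", session.emg)
    if session.kin is not None:
        _write_array(path / "kin.bin", session.kin)
    return path


def read_container(path: str | Path) -> RawSession:
    path = Path(path)
    sidecar_path = path / "session.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(sidecar_path)
    sc = json.loads(sidecar_path.read_text())
    n = sc["n_samples"]
    eeg = np.fromfile(path / "eeg.bin", dtype="<f8")
    n_eeg = len(sc["eeg_labels"])
    if eeg.size != n_eeg * n:
        raise IoFormatError(
            f"eeg.bin holds {eeg.size} values, expected {n_eeg}x{n}"
        )
    eeg = eeg.reshape(n_eeg, n)
    emg = None
    if sc["emg_labels"] and (path / "emg.bin").exists():
        emg = np.fromfile(path / "emg.bin", dtype="<f8").reshape(len(sc["emg_labels"]), n)
    kin = None
    if sc.get("n_kin_samples") and (path / "kin.bin").exists():
        kin = np.fromfile(path / "kin.bin", dtype="<f8").reshape(2, sc["n_kin_samples"])
    events = [Event(e["kind"], e["sample"], e["trial_id"]) for e in sc["events"]]
    return RawSession(
        eeg=eeg,
        eeg_labels=list(sc["eeg_labels"]),
        fs=sc["fs"],
        emg=emg,
        emg_labels=list(sc["emg_labels"]),
        kin=kin,
        fs_kin=sc["fs_kin"],
        events=events,
        meta=sc.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# BrainVision triplet

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=INT_16

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0
{marker_lines}
"""


def write_brainvision(session: RawSession, header_path: str | Path,
                      marker_map: dict[str, str] | None = None) -> Path:
    """Export to a BrainVision triplet (16-bit ints; kinematics are dropped).

    ``marker_map`` maps event kinds to marker descriptions (identity default).
    """
    header_path = Path(header_path)
    if header_path.suffix != ".vhdr":
        header_path = header_path.with_suffix(".vhdr")
    header_path.parent.mkdir(parents=True, exist_ok=True)
    stem = header_path.stem
    kind_to_desc = marker_map or {k: k for k in EVENT_KINDS}

    labels = list(session.eeg_labels) + list(session.emg_labels)
    resolutions = [EEG_RESOLUTION_UV] * len(session.eeg_labels) + [
        EMG_RESOLUTION_MV
    ] * len(session.emg_labels)
    units = ["µV"] * len(session.eeg_labels) + ["mV"] * len(session.emg_labels)
    channel_lines = "\n".join(
        f"Ch{i + 1}={lab},,{res:g},{unit}"
        for i, (lab, res, unit) in enumerate(zip(labels, resolutions, units))
    )
    header_path.write_text(
        _VHDR_TEMPLATE.format(
            stem=stem,
            n_channels=len(labels),
            sampling_interval_us=int(round(1e6 / session.fs)),
            channel_lines=channel_lines,
        )
    )

    marker_lines = []
    for i, ev in enumerate(sorted(session.events, key=lambda e: e.sample)):
        desc = kind_to_desc.get(ev.kind, ev.kind)
        # BrainVision marker positions are 1-based
        marker_lines.append(f"Mk{i + 2}=Stimulus,{desc},{ev.sample + 1},1,0")
    header_path.with_suffix(".vmrk").write_text(
        _VMRK_TEMPLATE.format(stem=stem, marker_lines="\n".join(marker_lines))
    )

    rows = [session.eeg / EEG_RESOLUTION_UV]
    if session.emg is not None:
        rows.append(session.emg / EMG_RESOLUTION_MV)
    data = np.concatenate(rows, axis=0)
    ints = np.clip(np.round(data), -32768, 32767).astype("<i2")
    # MULTIPLEXED: interleaved channel-major per sample
    ints.T.tofile(header_path.with_suffix(".eeg"))
    return header_path


def _parse_bv_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line and current is not None:
            key, val = line.split("=", 1)
            current[key.strip()] = val.strip()
    return sections


def read_brainvision(header_path: str | Path,
                     marker_map: dict[str, str] | None = None,
                     fs_kin: float = 1000.0) -> RawSession:
    """Read a BrainVision triplet into a :class:`RawSession`.

    Channels with unit mV are treated as EMG.  ``marker_map`` maps marker
    descriptions to event kinds; descriptions without a mapping (and not
    already a known kind) are dropped with a warning.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    hdr = _parse_bv_ini(header_path.read_text())
    common = hdr.get("Common Infos", {})
    binfo = hdr.get("Binary Infos", {})
    if binfo.get("BinaryFormat", "INT_16") != "INT_16":
        raise IoFormatError(f"unsupported BinaryFormat {binfo.get('BinaryFormat')!r}")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise IoFormatError("only MULTIPLEXED orientation is supported")
    n_channels = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])

    labels, resolutions, units = [], [], []
    chinfo = hdr.get("Channel Infos", {})
    for i in range(n_channels):
        parts = chinfo[f"Ch{i + 1}"].split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
        units.append(parts[3] if len(parts) > 3 else "µV")

    data_path = header_path.parent / common["DataFile"]
    marker_path = header_path.parent / common["MarkerFile"]
    for p in (data_path, marker_path):
        if not p.exists():
            raise FileNotFoundError(p)

    raw = np.fromfile(data_path, dtype="<i2")
    if raw.size % n_channels:
        raise IoFormatError(
            f"data file holds {raw.size} values, not divisible by {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    is_emg = [u == "mV" for u in units]
    eeg = data[[not f for f in is_emg]]
    emg = data[is_emg] if any(is_emg) else None
    eeg_labels = [l for l, f in zip(labels, is_emg) if not f]
    emg_labels = [l for l, f in zip(labels, is_emg) if f]

    desc_to_kind = {k: k for k in EVENT_KINDS}
    if marker_map:
        desc_to_kind.update(marker_map)
    events: list[Event] = []
    trial_id = -1
    mrk = _parse_bv_ini(marker_path.read_text()).get("Marker Infos", {})
    for key in sorted(mrk, key=lambda k: int(k[2:])):
        mtype, desc, pos = mrk[key].split(",")[:3]
        if mtype == "New Segment":
            continue
        kind = desc_to_kind.get(desc)
        if kind is None:
            warnings.warn(f"unmapped marker description {desc!r}; event dropped")
            continue
        if kind in ("target_onset", "catch_target_onset"):
            trial_id += 1
        events.append(Event(kind, int(pos) - 1, max(trial_id, 0)))

    return RawSession(
        eeg=eeg,
        eeg_labels=eeg_labels,
        fs=fs,
        emg=emg,
        emg_labels=emg_labels,
        events=events,
        fs_kin=fs_kin,
        meta={"source": str(header_path)},
    )


# ---------------------------------------------------------------------------
# epoching helpers


def epoch_slices(session: RawSession, kind: str,
                 t_range: tuple[float, float] = (-2.5, 1.0)) -> list[tuple[int, slice]]:
    """Half-open sample ranges of ``t_range`` around each ``kind`` event.

    Events whose window exceeds the recording are skipped with a warning.
    """
    t0, t1 = t_range
    if t1 <= t0:
        raise ValueError("t_range must be increasing")
    offset = round(t0 * session.fs)
    n_win = round((t1 - t0) * session.fs)
    out = []
    for ev in session.events_of(kind):
        start = ev.sample + offset
        stop = start + n_win
        if start < 0 or stop > session.n_samples:
            warnings.warn(
                f"event at sample {ev.sample} ({kind}, trial {ev.trial_id}): "
                "epoch window exceeds recording; skipped"
            )
            continue
        out.append((ev.trial_id, slice(start, stop)))
    return out
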