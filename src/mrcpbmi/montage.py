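"""10-20 / 10-10 montage geometry and Large-Laplacian neighbor sets.

Channels are placed on an integer grid: rows run front to back (Fp=0 ... O=8),
columns run left to right in half-steps (z=0, odd labels negative, even
positive).  The Large Laplacian uses next-nearest neighbors: the channels two
grid steps away along each axis (approximately 6 cm on an adult head).
Boundary channels use whichever of the four neighbors exist.
"""

from __future__ import annotations

import re

__all__ = [
    "ACTICAP_64_LABELS",
    "EMG_SPLITTER_LABELS",
    "DEFAULT_EEG_LABELS",
    "CENTRAL_25_LABELS",
    "grid_position",
    "large_laplacian_neighbors",
]

#: Standard 64-channel active-electrode cap labels.
ACTICAP_64_LABELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "C3", "Cz", "C4", "T7", "T8", "CP5", "CP1", "CP2", "CP6", "P7", "P3",
    "Pz", "P4", "P8", "O1", "Oz", "O2", "AF7", "AF3", "AF4", "AF8", "F5",
    "F1", "F2", "F6", "FT9", "FT7", "FC3", "FC4", "FT8", "FT10", "C5", "C1",
    "C2", "C6", "TP9", "TP7", "CP3", "CPz", "CP4", "TP8", "TP10", "P5", "P1",
    "P2", "P6", "PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
]

#: Peripheral electrodes rewired to bipolar EMG through the splitter box.
EMG_SPLITTER_LABELS = ["FT9", "FT10", "TP9", "TP10"]

#: The cap channels that actually carry EEG in the recording setup.
DEFAULT_EEG_LABELS = [l for l in ACTICAP_64_LABELS if l not in EMG_SPLITTER_LABELS]

#: Compact sensorimotor montage (5 x 5 grid over F..P rows) for fast simulation.
CENTRAL_25_LABELS = [
    f"{row}{col}"
    for row in ("F", "FC", "C", "CP", "P")
    for col in ("3", "1", "z", "2", "4")
]

_ROW_INDEX = {
    "Fp": 0, "AF": 1, "F": 2, "FT": 3, "FC": 3, "T": 4, "C": 4,
    "TP": 5, "CP": 5, "P": 6, "PO": 7, "O": 8,
}

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def grid_position(label: str) -> tuple[int, int]:
    """(row, col) grid coordinates of a 10-20/10-10 label."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse channel label {label!r}")
    prefix, suffix = m.group(1), m.group(2)
    if prefix not in _ROW_INDEX:
        raise ValueError(f"unknown row prefix in label {label!r}")
    row = _ROW_INDEX[prefix]
    if suffix == "z":
        col = 0
    else:
        n = int(suffix)
        col = (n + 1) // 2 * (-1 if n % 2 else 1)
    return row, col


def large_laplacian_neighbors(labels: list[str]) -> dict[str, list[str]]:
    """Next-nearest-neighbor sets (offsets of two grid steps) per channel.

    Channels with no neighbor present in ``labels`` are omitted from the
    mapping; the caller decides how to treat them.
    """
    pos = {}
    for lab in labels:
        try:
            pos[lab] = grid_position(lab)
        except ValueError:
            continue
    by_pos = {p: lab for lab, p in pos.items()}
    table: dict[str, list[str]] = {}
    for lab, (r, c) in pos.items():
        neigh = []
        for dr, dc in ((-2, 0), (2, 0), (0, -2), (0, 2)):
            other = by_pos.get((r + dr, c + dc))
            if other is not None and other != lab:
                neigh.append(other)
        if neigh:
            table[lab] = neigh
    return table
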