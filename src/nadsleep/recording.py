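"""In-memory recording container and on-disk formats.

Two raw formats are supported, mirroring how the two sessions were acquired:

* ERP sessions: a documented container of 32-bit float sample arrays
  (``<name>.dat``, channels x samples, row-major, little-endian) with a JSON
  sidecar (``<name>.json``) holding channel labels, sampling rate and units.
* Sleep sessions: 16-bit EDF, written by a small self-contained writer and
  readable by any EDF tool (mne is used for reading).

Hypnograms are TSV tables of 30 s epochs with stage labels
{W, N1, N2, SWS, REM} and an artifact flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "Recording", "ERP_MONTAGE", "SLEEP_MONTAGE", "MASTOIDS",
    "write_float_container", "read_float_container",
    "write_edf", "read_edf", "write_hypnogram", "read_hypnogram",
    "HYPNOGRAM_EPOCH_S", "STAGES", "NONREM_STAGES",
]

#: 21-channel ERP montage (10-20 subset incl. both mastoids)
ERP_MONTAGE = ("F7", "F3", "FZ", "F4", "F8", "FC3", "FC4", "T7", "C3", "CZ",
               "C4", "T8", "CP5", "CP6", "P3", "PZ", "P4", "O1", "O2",
               "M1", "M2")

#: sleep montage: 8 scalp sites + mastoids (recorded against CZ)
SLEEP_MONTAGE = ("F3", "FZ", "F4", "C3", "C4", "P3", "PZ", "P4", "M1", "M2")

MASTOIDS = ("M1", "M2")

HYPNOGRAM_EPOCH_S = 30.0
STAGES = ("W", "N1", "N2", "SWS", "REM")
NONREM_STAGES = ("N1", "N2", "SWS")


@dataclass
class Recording:
    """Multi-channel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        self.ch_names = tuple(self.ch_names)
        if self.data.shape[0] != len(self.ch_names):
            raise InputError(
                f"{self.data.shape[0]} rows for {len(self.ch_names)} channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise InputError(f"channel {name!r} not in recording") from None

    def get(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def pick(self, names) -> "Recording":
        idx = [self.channel_index(n) for n in names]
        return Recording(self.data[idx], self.sfreq, tuple(names),
                         dict(self.meta))

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.sfreq, self.ch_names,
                         dict(self.meta))


# --------------------------------------------------------------------------
# float32 + JSON sidecar container (ERP sessions)

def write_float_container(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    data = np.ascontiguousarray(rec.data, dtype="<f4")
    data.tofile(path.with_suffix(".dat"))
    sidecar = {"channels": list(rec.ch_names), "sfreq": rec.sfreq,
               "units": "uV", "n_samples": rec.n_samples,
               "dtype": "<f4", "order": "channels_x_samples"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_float_container(path: str | Path) -> Recording:
    path = Path(path)
    try:
        sidecar = json.loads(path.with_suffix(".json").read_text())
    except FileNotFoundError as e:
        raise InputError(f"missing sidecar for {path}") from e
    data = np.fromfile(path.with_suffix(".dat"), dtype="<f4")
    n_ch = len(sidecar["channels"])
    data = data.reshape(n_ch, sidecar["n_samples"]).astype(float)
    return Recording(data, float(sidecar["sfreq"]),
                     tuple(sidecar["channels"]))


# --------------------------------------------------------------------------
# EDF (sleep sessions)

def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a 16-bit EDF file (1 s data records, physical units µV).

    Pads the final partial second with the edge value.  Physical ranges are
    set per channel from the data with headroom so quantisation error stays
    below ~0.01 µV for typical EEG amplitudes.
    """
    path = Path(path)
    fs = rec.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise InputError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(rec.ch_names)
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = rec.data
    if rec.n_samples < n_rec * fs:
        pad = n_rec * fs - rec.n_samples
        data = np.hstack([data, np.repeat(data[:, -1:], pad, axis=1)])

    def fix(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    hdr = b"".join([
        fix("0", 8), fix("X X X X", 80), fix("Startdate X X X X", 80),
        fix("01.01.00", 8), fix("00.00.00", 8),
        fix(str(256 * (1 + n_ch)), 8), fix("EDF", 44),
        fix(str(n_rec), 8), fix("1", 8), fix(str(n_ch), 4),
    ])
    phys_min, phys_max, scaled = [], [], []
    for ch in range(n_ch):
        lo = float(np.min(data[ch])) - 1.0
        hi = float(np.max(data[ch])) + 1.0
        span = max(hi - lo, 2.0)
        lo, hi = lo - 0.05 * span, hi + 0.05 * span
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((data[ch] - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(np.clip(dig, -32768, 32767).astype("<i2"))

    def col(vals, width):
        return b"".join(fix(v, width) for v in vals)

    labels = [f"EEG {n}" for n in rec.ch_names]
    hdr += col(labels, 16)
    hdr += col(["Unknown"] * n_ch, 80)
    hdr += col(["uV"] * n_ch, 8)
    hdr += col([f"{v:.3f}"[:8] for v in phys_min], 8)
    hdr += col([f"{v:.3f}"[:8] for v in phys_max], 8)
    hdr += col(["-32768"] * n_ch, 8)
    hdr += col(["32767"] * n_ch, 8)
    hdr += col([""] * n_ch, 80)
    hdr += col([str(fs)] * n_ch, 8)
    hdr += col([""] * n_ch, 32)

    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for ch in range(n_ch):
                f.write(scaled[ch][r * fs:(r + 1) * fs].tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via mne, returning data in µV."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = tuple(n.removeprefix("EEG ").strip() for n in raw.ch_names)
    return Recording(raw.get_data() * 1e6, raw.info["sfreq"], names)


# --------------------------------------------------------------------------
# hypnogram

def write_hypnogram(hyp: pd.DataFrame, path: str | Path) -> None:
    hyp.to_csv(path, sep="\t", index=False)


def read_hypnogram(path: str | Path) -> pd.DataFrame:
    hyp = pd.read_csv(path, sep="\t")
    required = {"epoch_index", "stage", "artifact"}
    if not required.issubset(hyp.columns):
        raise InputError(f"hypnogram must have columns {sorted(required)}")
    bad = set(hyp.stage) - set(STAGES)
    if bad:
        raise InputError(f"unknown sleep stages {sorted(bad)}")
    return hyp
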