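"""Suffix-locked ERP pipeline: re-reference, filter, epoch, reject, average.

The processing chain mirrors standard infant-ERP practice: mastoid
re-referencing, a calibrated 0.5--20 Hz zero-phase band-pass whose strong DC
suppression permits averaging without baseline correction, suffix-locked
epoching, artifact rejection by a 90 µV standard-deviation criterion in a
500 ms sliding window, per-condition averaging with a 10-trial minimum,
region-of-interest aggregation, and signed mean amplitudes in named analysis
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import filters
from .errors import ConfigurationError, InputError
from .recording import MASTOIDS, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet", "ConditionAverage", "RoiWaveform", "EffectValue",
    "ROI_LAYOUT", "COMPOSITE_REGIONS", "ANALYSIS_WINDOWS",
    "rereference_to_mastoids", "bandpass_erp", "epoch_suffix_locked",
    "reject_artifacts", "average_condition", "roi_waveforms",
    "window_mean", "effect_value", "display_filter",
]

#: paired lateral ROIs and midline sites
ROI_LAYOUT = {
    "LF": ("F7", "F3"), "RF": ("F8", "F4"),
    "LC": ("C3", "FC3"), "RC": ("C4", "FC4"),
    "LP": ("P3", "CP5"), "RP": ("P4", "CP6"),
    "MF": ("FZ",), "MC": ("CZ",), "MPO": ("PZ", "O1", "O2"),
}

#: composite regions, each the unweighted mean over its electrode list
COMPOSITE_REGIONS = {
    "frontal": ("F7", "F3", "FZ", "F4", "F8"),
    "central": ("FC3", "C3", "CZ", "FC4", "C4"),
    "parietal_occipital": ("P3", "CP5", "P4", "CP6", "PZ", "O1", "O2"),
    "CPO": ("FC3", "FC4", "C3", "CZ", "C4", "P3", "PZ", "P4",
            "CP5", "CP6", "O1", "O2"),
    "LFC": ("F7", "F3", "FC3", "C3"),
}

#: named analysis windows in ms relative to suffix onset (closed intervals)
ANALYSIS_WINDOWS = {
    "early": (100.0, 300.0),
    "middle": (400.0, 600.0),
    "late_encoding": (700.0, 850.0),
    "late_test": (750.0, 900.0),
    "intermediate": (600.0, 750.0),
    "middle_first": (400.0, 500.0),
    "middle_second": (500.0, 600.0),
    "mid_broad": (500.0, 750.0),
}


@dataclass
class EpochSet:
    """Suffix-locked trials: ``samples`` is trials x channels x time (µV)."""

    samples: np.ndarray
    times_ms: np.ndarray
    ch_names: tuple[str, ...]
    labels: pd.DataFrame
    mask: np.ndarray  # True = kept

    def __post_init__(self):
        if len(self.mask) != self.samples.shape[0]:
            raise InputError("mask length must equal trial count")
        if len(self.labels) != self.samples.shape[0]:
            raise InputError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.samples.shape[0]


@dataclass
class ConditionAverage:
    data: np.ndarray            # channels x time, µV
    times_ms: np.ndarray
    ch_names: tuple[str, ...]
    n_trials: int
    insufficient: bool = False  # fewer than the required artifact-free trials


@dataclass
class RoiWaveform:
    roi: str
    data: np.ndarray            # time, µV
    times_ms: np.ndarray
    insufficient: bool = False


@dataclass
class EffectValue:
    name: str
    region: str
    window: str
    amplitude_uv: float
    minuend: str
    subtrahend: str


# --------------------------------------------------------------------------

def rereference_to_mastoids(rec: Recording) -> Recording:
    """Subtract the mastoid mean from every scalp channel; drop the mastoids."""
    for m in MASTOIDS:
        if m not in rec.ch_names:
            raise InputError(f"mastoid channel {m} missing; cannot re-reference")
    ref = (rec.get(MASTOIDS[0]) + rec.get(MASTOIDS[1])) / 2.0
    scalp = [n for n in rec.ch_names if n not in MASTOIDS]
    idx = [rec.channel_index(n) for n in scalp]
    return Recording(rec.data[idx] - ref[None, :], rec.sfreq, tuple(scalp),
                     dict(rec.meta))


def bandpass_erp(rec: Recording) -> Recording:
    """Calibrated 0.5--20 Hz zero-phase band-pass (see :mod:`.filters`)."""
    taps = filters.design_erp_bandpass(rec.sfreq)
    out = rec.copy()
    out.data = filters.apply_zero_phase(
        rec.data, taps.astype(rec.data.dtype, copy=False), axis=-1)
    return out


def epoch_suffix_locked(rec: Recording, events: pd.DataFrame,
                        window_ms: tuple[float, float] = (-100.0, 1000.0),
                        ) -> EpochSet:
    """Cut one trial per event row, time-locked to the suffix onset sample.

    No baseline correction is applied (the band-pass's DC suppression stands
    in for it).  Events whose window falls outside the recording are skipped
    with a logged warning.
    """
    if "onset_sample" not in events.columns:
        raise InputError("events table must have an onset_sample column")
    fs = rec.sfreq
    start = int(round(window_ms[0] * fs / 1000.0))
    n_t = int(round((window_ms[1] - window_ms[0]) * fs / 1000.0)) + 1
    times_ms = (start + np.arange(n_t)) * 1000.0 / fs

    onsets = events["onset_sample"].to_numpy(dtype=int)
    lo = onsets + start
    ok = (lo >= 0) & (lo + n_t <= rec.n_samples)
    if not ok.all():
        bad = events.index[~ok].tolist()
        logger.warning("skipping %d out-of-range events: %s", len(bad), bad)
    idx = lo[ok][:, None] + np.arange(n_t)[None, :]
    samples = rec.data[:, idx].transpose(1, 0, 2)  # trials x channels x time
    labels = events.loc[ok].reset_index(drop=True)
    return EpochSet(samples.copy(), times_ms, rec.ch_names, labels,
                    np.ones(int(ok.sum()), dtype=bool))


def sliding_window_sd(x: np.ndarray, n_win: int, ddof: int = 0) -> np.ndarray:
    """SD over every length-``n_win`` window (step 1 sample) along the last
    axis, computed from cumulative sums."""
    c1 = np.cumsum(x, axis=-1, dtype=float)
    c2 = np.cumsum(x * x, axis=-1, dtype=float)
    pad = [(0, 0)] * (x.ndim - 1) + [(1, 0)]
    c1, c2 = np.pad(c1, pad), np.pad(c2, pad)
    s1 = c1[..., n_win:] - c1[..., :-n_win]
    s2 = c2[..., n_win:] - c2[..., :-n_win]
    var = (s2 - s1 * s1 / n_win) / (n_win - ddof)
    return np.sqrt(np.maximum(var, 0.0))


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 90.0,
                     window_ms: float = 500.0, fs: float | None = None,
                     ddof: int = 0) -> EpochSet:
    """Mark trials whose SD exceeds ``threshold_uv`` in any sliding window.

    A trial is rejected iff, on any channel, the sample standard deviation
    within any ``window_ms`` window (sliding by one sample) exceeds the
    threshold.  ``ddof=0`` (population SD) by default; the denominator
    convention is configurable since the original software does not document
    it.  Previously rejected trials stay rejected.
    """
    if fs is None:
        dt = np.median(np.diff(epochs.times_ms))
        fs = 1000.0 / dt
    n_win = int(round(window_ms * fs / 1000.0))
    if epochs.samples.shape[-1] < n_win:
        raise InputError(
            f"trials shorter ({epochs.samples.shape[-1]} samples) than the "
            f"{window_ms} ms rejection window ({n_win} samples)")
    sd = sliding_window_sd(epochs.samples, n_win, ddof=ddof)
    bad = (sd > threshold_uv).any(axis=(1, 2))
    new = replace(epochs)
    new.mask = epochs.mask & ~bad
    return new


def average_condition(epochs: EpochSet, selector, min_trials: int = 10,
                      ) -> ConditionAverage:
    """Average artifact-free trials matching ``selector``.

    ``selector`` is either a mapping of label column -> value or a callable
    on the labels DataFrame returning a boolean mask.  Averages based on
    fewer than ``min_trials`` artifact-free trials are flagged
    ``insufficient`` and must not enter statistics.
    """
    if callable(selector):
        match = np.asarray(selector(epochs.labels), dtype=bool)
    else:
        match = np.ones(epochs.n_trials, dtype=bool)
        for col, val in selector.items():
            match &= (epochs.labels[col] == val).to_numpy()
    if not match.any():
        raise InputError("no trials match the condition selector")
    keep = match & epochs.mask
    n = int(keep.sum())
    if n == 0:
        data = np.full(epochs.samples.shape[1:], np.nan)
    else:
        data = epochs.samples[keep].mean(axis=0, dtype=np.float64)
    return ConditionAverage(data, epochs.times_ms, epochs.ch_names, n,
                            insufficient=n < min_trials)


def roi_waveforms(avg: ConditionAverage,
                  layout: dict[str, tuple[str, ...]] | None = None,
                  ) -> dict[str, RoiWaveform]:
    """Unweighted electrode means for every ROI / composite region."""
    if layout is None:
        layout = {**ROI_LAYOUT, **COMPOSITE_REGIONS}
    missing = {roi: [e for e in electrodes if e not in avg.ch_names]
               for roi, electrodes in layout.items()}
    missing = {roi: m for roi, m in missing.items() if m}
    if missing:
        raise InputError(f"electrodes missing for ROIs: {missing}")
    out = {}
    for roi, electrodes in layout.items():
        idx = [avg.ch_names.index(e) for e in electrodes]
        out[roi] = RoiWaveform(roi, avg.data[idx].mean(axis=0), avg.times_ms,
                               insufficient=avg.insufficient)
    return out


def window_mean(wave: RoiWaveform, window: str) -> float:
    """Time-mean amplitude (µV) of a waveform over a registered window."""
    if window not in ANALYSIS_WINDOWS:
        raise ConfigurationError(
            f"unknown analysis window {window!r}; registered: "
            f"{sorted(ANALYSIS_WINDOWS)}")
    lo, hi = ANALYSIS_WINDOWS[window]
    sel = (wave.times_ms >= lo - 1e-9) & (wave.times_ms <= hi + 1e-9)
    if not sel.any():
        raise InputError(f"window {window} outside the epoch time axis")
    return float(wave.data[sel].mean())


def effect_value(cond_a: RoiWaveform, cond_b: RoiWaveform, window: str,
                 region: str, name: str = "", minuend: str = "",
                 subtrahend: str = "") -> EffectValue:
    """Signed contrast ``window_mean(a) - window_mean(b)``.

    The sign conventions follow the study design: irregular - regular for
    memory effects, second half - first half for familiarity effects.
    """
    if cond_a.roi != cond_b.roi:
        raise InputError(
            f"contrast across different regions: {cond_a.roi} vs {cond_b.roi}")
    amp = window_mean(cond_a, window) - window_mean(cond_b, window)
    return EffectValue(name or f"{region}:{window}", region, window, amp,
                       minuend, subtrahend)


def display_filter(wave: RoiWaveform, fs: float | None = None) -> RoiWaveform:
    """7 Hz zero-phase low-pass for figures only; never applied before stats."""
    if fs is None:
        fs = 1000.0 / np.median(np.diff(wave.times_ms))
    taps = filters.design_display_lowpass(fs)
    # epoch-length waveforms are short relative to the filter: reflect-pad
    # so the whole epoch sits in the filter's settled region
    pad = taps.size
    data = np.pad(wave.data, pad, mode="reflect")
    out = filters.apply_zero_phase(data, taps)[pad:-pad]
    return RoiWaveform(wave.roi, out, wave.times_ms, wave.insufficient)
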