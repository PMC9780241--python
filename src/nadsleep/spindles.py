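"""Individualized fast-sleep-spindle detection by RMS thresholding.

The detector follows the classic amplitude-criterion scheme used in infant
sleep studies: the artifact-free NonREM EEG is low-pass filtered at 32 Hz and
down-sampled to 128 Hz; the individual peak frequency of fast spindles
(typically 13--14 Hz in infants) is identified per channel from the averaged
power spectrum; the signal is band-pass filtered in a 3 Hz band centred on
that peak; a 0.2 s sliding RMS of the filtered signal is thresholded at 1.5
standard deviations of the filtered signal; threshold crossings lasting
0.5--5 s become spindle events, with close successors merged; the
peak-to-peak amplitude is the max - min of the band-passed signal within the
event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from . import filters
from .errors import ConfigurationError, InputError, InsufficientDataError
from .recording import (HYPNOGRAM_EPOCH_S, MASTOIDS, NONREM_STAGES, Recording)

logger = logging.getLogger(__name__)

__all__ = [
    "SpindleEvent", "NonRemStream", "rereference_sleep", "preprocess_sleep",
    "individual_peak_frequency", "detect_spindles", "gate_candidates",
    "merge_candidates",
    "summarize_spindles", "run_spindle_analysis", "SLEEP_REGIONS",
]

#: channel groupings for regional summaries
SLEEP_REGIONS = {
    "frontal": ("F3", "FZ", "F4"),
    "central": ("C3", "CZ", "C4"),
    "parietal": ("P3", "PZ", "P4"),
}

#: fast-spindle search band for the individual peak frequency, Hz
SEARCH_BAND = (11.0, 16.0)


@dataclass
class SpindleEvent:
    channel: str
    onset_s: float          # seconds in the original recording
    offset_s: float
    duration_s: float
    peak_freq_hz: float     # individual peak frequency used for detection
    p2p_uv: float


@dataclass
class NonRemStream:
    """Concatenated artifact-free NonREM EEG at the analysis rate.

    ``segments`` lists contiguous runs as (stream_start, stream_stop,
    original_onset_s); detected events never span a segment boundary.
    """

    data: np.ndarray                 # channels x samples, µV
    sfreq: float
    ch_names: tuple[str, ...]
    segments: list[tuple[int, int, float]]
    nonrem_minutes: float

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.ch_names.index(name)]
        except ValueError:
            raise InputError(f"channel {name!r} not in stream") from None

    def segment_arrays(self, name: str):
        x = self.channel(name)
        return [x[a:b] for a, b, _ in self.segments]


def rereference_sleep(rec: Recording) -> Recording:
    """Re-reference a CZ-referenced sleep recording to the mastoid mean.

    The recording reference (CZ) carries no signal of its own in the data, so
    after re-referencing it can be reconstructed as minus the mastoid mean;
    this recovers the mid-central channel for the regional summaries.  If the
    mastoids are absent the data are returned unchanged with a logged note.
    """
    if not all(m in rec.ch_names for m in MASTOIDS):
        logger.info("mastoids absent; sleep recording left at its original "
                    "reference, CZ not reconstructed")
        return rec.copy()
    ref = (rec.get(MASTOIDS[0]) + rec.get(MASTOIDS[1])) / 2.0
    scalp = [n for n in rec.ch_names if n not in MASTOIDS]
    idx = [rec.channel_index(n) for n in scalp]
    data = np.vstack([rec.data[idx] - ref[None, :], -ref[None, :]])
    return Recording(data, rec.sfreq, tuple(scalp) + ("CZ",), dict(rec.meta))


def preprocess_sleep(rec: Recording, hypnogram: pd.DataFrame,
                     nonrem_stages: tuple[str, ...] = NONREM_STAGES,
                     target_sfreq: float = 128.0,
                     lp_cutoff: float = 32.0) -> NonRemStream:
    """32 Hz low-pass, down-sample to 128 Hz, keep artifact-free NonREM.

    The hypnogram must cover the recording in 30 s epochs.  Contiguous runs
    of retained epochs form segments; the segment table keeps original onset
    times so events can be reported in recording time.
    """
    n_epochs = int(np.ceil(rec.duration / HYPNOGRAM_EPOCH_S))
    if len(hypnogram) < n_epochs:
        raise InputError(
            f"hypnogram ({len(hypnogram)} epochs) does not cover the "
            f"recording ({n_epochs} epochs of {HYPNOGRAM_EPOCH_S:g} s)")
    factor = rec.sfreq / target_sfreq
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigurationError(
            f"sampling rate {rec.sfreq} not an integer multiple of "
            f"{target_sfreq}")
    factor = int(round(factor))
    taps = filters.design_lowpass(lp_cutoff, rec.sfreq, transition=6.0)
    low = filters.apply_zero_phase(rec.data, taps, axis=-1)
    down = low[:, ::factor]

    keep = [(row.stage in nonrem_stages) and (int(row.artifact) == 0)
            for row in hypnogram.itertuples()]
    epoch_len = int(round(HYPNOGRAM_EPOCH_S * target_sfreq))
    pieces, segments, pos = [], [], 0
    i = 0
    while i < len(keep):
        if keep[i]:
            j = i
            while j + 1 < len(keep) and keep[j + 1]:
                j += 1
            a = i * epoch_len
            b = min((j + 1) * epoch_len, down.shape[1])
            if b > a:
                pieces.append(down[:, a:b])
                segments.append((pos, pos + (b - a), i * HYPNOGRAM_EPOCH_S))
                pos += b - a
            i = j + 1
        else:
            i += 1
    if not pieces:
        logger.warning("no artifact-free NonREM epochs; empty stream")
        data = np.empty((down.shape[0], 0))
    else:
        data = np.concatenate(pieces, axis=1)
    return NonRemStream(data, target_sfreq, rec.ch_names, segments,
                        nonrem_minutes=data.shape[1] / target_sfreq / 60.0)


def individual_peak_frequency(stream: NonRemStream, channel: str,
                              search_band: tuple[float, float] = SEARCH_BAND,
                              seg_seconds: float = 4.0) -> float:
    """Frequency of the power-spectrum maximum in the fast-spindle band.

    Averaged modified periodograms (Hann window, 4 s segments, 50% overlap)
    give a resolution of 0.25 Hz; periodograms are computed per contiguous
    NonREM segment and averaged with weights proportional to the number of
    windows each contributes.
    """
    if stream.n_samples < 60.0 * stream.sfreq:
        raise InsufficientDataError(
            "need at least 60 s of NonREM EEG for the peak-frequency spectrum")
    nperseg = int(round(seg_seconds * stream.sfreq))
    acc, wsum = None, 0.0
    for seg in stream.segment_arrays(channel):
        if seg.size < nperseg:
            continue
        f, p = signal.welch(seg, fs=stream.sfreq, nperseg=nperseg,
                            noverlap=nperseg // 2)
        w = 1 + (seg.size - nperseg) // (nperseg // 2)
        acc = p * w if acc is None else acc + p * w
        wsum += w
    if acc is None:
        raise InsufficientDataError("no NonREM segment long enough for a "
                                    "4 s spectral window")
    psd = acc / wsum
    band = (f >= search_band[0]) & (f <= search_band[1])
    return float(f[band][np.argmax(psd[band])])


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs (stop exclusive)."""
    d = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def gate_candidates(runs: list[tuple[int, int]], min_n: int,
                    max_n: int) -> list[tuple[int, int]]:
    """Keep threshold crossings whose length is within [min_n, max_n]
    samples (the 0.5--5 s duration criterion)."""
    return [(i, j) for i, j in runs if min_n <= j - i <= max_n]


def merge_candidates(cands: list[tuple[int, int]], gap_n: int,
                     max_n: int) -> list[tuple[int, int]]:
    """Merge successive candidate intervals per the spindle counting rule.

    Two successive events become one when the gap between the end of the
    first and the start of the second is strictly shorter than ``gap_n``
    samples AND the merged event is not longer than ``max_n`` samples.
    Applied left to right, so a merged event can absorb further successors.
    """
    merged: list[tuple[int, int]] = []
    for i, j in cands:
        if merged and (i - merged[-1][1]) < gap_n \
                and (j - merged[-1][0]) <= max_n:
            merged[-1] = (merged[-1][0], j)
        else:
            merged.append((i, j))
    return merged


def _sliding_rms(x: np.ndarray, n_win: int) -> np.ndarray:
    """Centered sliding RMS with edge truncation (shrinking windows)."""
    c = np.cumsum(np.concatenate([[0.0], x * x]))
    idx = np.arange(x.size)
    half = n_win // 2
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (n_win - half), x.size)
    return np.sqrt((c[hi] - c[lo]) / (hi - lo))


def detect_spindles(stream: NonRemStream, channel: str, peak_hz: float,
                    half_width_hz: float = 1.5, threshold_sd: float = 1.5,
                    rms_window_s: float = 0.2,
                    duration_bounds_s: tuple[float, float] = (0.5, 5.0),
                    merge_gap_s: float = 0.5) -> list[SpindleEvent]:
    """Detect discrete spindles on one channel of a NonREM stream.

    Candidate intervals are where the 0.2 s sliding RMS of the band-passed
    signal exceeds ``threshold_sd`` standard deviations of the band-passed
    stream (SD taken over the full concatenated stream, so the threshold is
    signal-relative and gain-invariant).  Candidates shorter than 0.5 s or
    longer than 5 s are discarded; two successive events are merged when the
    gap is below 0.5 s and the merged event does not exceed 5 s.
    """
    fs = stream.sfreq
    if not (0.0 < peak_hz - half_width_hz and peak_hz + half_width_hz < fs / 2):
        raise ConfigurationError(
            f"band {peak_hz}±{half_width_hz} Hz outside (0, {fs / 2}) Hz")
    numtaps = int(round(4.0 * fs)) // 2 * 2 + 1
    taps = signal.firwin(numtaps, [peak_hz - half_width_hz,
                                   peak_hz + half_width_hz],
                         fs=fs, pass_zero=False, window="hamming")
    filtered_segs = []
    for seg in stream.segment_arrays(channel):
        if seg.size == 0:
            filtered_segs.append(seg)
        elif seg.size < numtaps:
            pad = numtaps
            padded = np.pad(seg, pad, mode="reflect") if seg.size > 1 else \
                np.zeros(2 * pad + seg.size)
            filtered_segs.append(
                filters.apply_zero_phase(padded, taps)[pad:pad + seg.size])
        else:
            filtered_segs.append(filters.apply_zero_phase(seg, taps))
    if not filtered_segs:
        return []
    sd = float(np.concatenate(filtered_segs).std())
    if sd == 0.0:
        return []
    threshold = threshold_sd * sd
    n_rms = max(int(round(rms_window_s * fs)), 1)
    min_n = int(round(duration_bounds_s[0] * fs))
    max_n = int(round(duration_bounds_s[1] * fs))

    events = []
    for (a, b, onset_s), xf in zip(stream.segments, filtered_segs):
        rms = _sliding_rms(xf, n_rms)
        cands = gate_candidates(_runs(rms > threshold), min_n, max_n)
        merged = merge_candidates(cands, int(round(merge_gap_s * fs)), max_n)
        for i, j in merged:
            seg = xf[i:j]
            events.append(SpindleEvent(
                channel=channel,
                onset_s=onset_s + i / fs,
                offset_s=onset_s + j / fs,
                duration_s=(j - i) / fs,
                peak_freq_hz=peak_hz,
                p2p_uv=float(seg.max() - seg.min()),
            ))
    return events


def summarize_spindles(events_by_channel: dict[str, list[SpindleEvent]],
                       nonrem_minutes: float,
                       regions: dict[str, tuple[str, ...]] | None = None,
                       ) -> pd.DataFrame:
    """Per-channel and per-region amplitude / count / density table.

    Density is events per minute of artifact-free NonREM sleep.  Region
    values are means of the available member-channel values; the mean
    amplitude of a channel without events is undefined (NaN).
    """
    if nonrem_minutes <= 0:
        raise InsufficientDataError("density undefined without NonREM time")
    if regions is None:
        regions = SLEEP_REGIONS
    rows = []
    for ch, events in events_by_channel.items():
        amps = [e.p2p_uv for e in events]
        rows.append(dict(label=ch, kind="channel",
                         mean_p2p_uv=float(np.mean(amps)) if amps else np.nan,
                         count=len(events),
                         density_per_min=len(events) / nonrem_minutes))
    table = pd.DataFrame(rows)
    for region, members in regions.items():
        sub = table[table.label.isin(members)]
        if sub.empty:
            continue
        if len(sub) < len(members):
            logger.info("region %s uses channels %s only", region,
                        sorted(sub.label))
        rows.append(dict(label=region, kind="region",
                         mean_p2p_uv=float(sub.mean_p2p_uv.mean()),
                         count=float(sub["count"].mean()),
                         density_per_min=float(sub.density_per_min.mean())))
    return pd.DataFrame(rows)


def run_spindle_analysis(rec: Recording, hypnogram: pd.DataFrame,
                         channels: tuple[str, ...] | None = None,
                         already_rereferenced: bool = False, **kwargs):
    """Full chain: re-reference, preprocess, peak frequency, detect, summarize.

    Returns ``(events_df, summary_df, stream)``.  Channels without at least
    60 s of NonREM data propagate as empty event lists.
    """
    if not already_rereferenced:
        rec = rereference_sleep(rec)
    stream = preprocess_sleep(rec, hypnogram)
    if channels is None:
        channels = tuple(n for n in stream.ch_names if n not in MASTOIDS)
    events = {}
    for ch in channels:
        try:
            peak = individual_peak_frequency(stream, ch)
        except InsufficientDataError:
            logger.warning("channel %s: too little NonREM data, no events", ch)
            events[ch] = []
            continue
        events[ch] = detect_spindles(stream, ch, peak, **kwargs)
    rows = [vars(e) for evs in events.values() for e in evs]
    events_df = pd.DataFrame(rows, columns=["channel", "onset_s", "offset_s",
                                            "duration_s", "peak_freq_hz",
                                            "p2p_uv"])
    if stream.nonrem_minutes > 0:
        summary_df = summarize_spindles(events, stream.nonrem_minutes)
    else:
        summary_df = pd.DataFrame(columns=["label", "kind", "mean_p2p_uv",
                                           "count", "density_per_min"])
    return events_df, summary_df, stream
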