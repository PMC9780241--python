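"""Synthetic ERP sessions and nap-sleep EEG with known ground truth.

The generator emulates the study conditions end to end so every pipeline
stage is testable without any recorded data:

* ERP sessions: 21-channel, 500 Hz continuous EEG per subject.  Background
  activity is spatially correlated 1/f Gaussian noise; each scheduled trial
  adds the condition's evoked components (Hanning-windowed monophasic bumps,
  matching the slow deflections of infant ERPs) time-locked to the suffix
  onset; artifact trials receive a large square excursion on one random
  channel so the 90 µV sliding-SD criterion fires deterministically.
* Nap sleep: 256 Hz EEG over the 8-site sleep montage (+ mastoids) with a
  30 s-epoch hypnogram.  Fast-spindle bursts (sinusoid under a raised-cosine
  envelope, frequency drawn around 13.65 Hz) are placed by a Poisson process
  within artifact-free NonREM epochs only, non-overlapping, with the exact
  onset/offset/frequency/amplitude of every event recorded as ground truth.

Component amplitudes are bump peaks in µV; the stored ground-truth effect
table reports, per contrast, region and analysis window, the window-mean of
the injected condition difference — the quantity the ERP pipeline estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft

from .erp import ANALYSIS_WINDOWS, COMPOSITE_REGIONS, ROI_LAYOUT
from .errors import ConfigurationError, GenerationError
from .recording import (ERP_MONTAGE, HYPNOGRAM_EPOCH_S, SLEEP_MONTAGE,
                        Recording)

__all__ = [
    "EvokedComponent", "EffectSpec", "NoiseSpec", "SpindleSimSpec",
    "ErpSubject", "default_effect_spec", "generate_erp_dataset",
    "generate_sleep_eeg", "ground_truth_effects",
]


# --------------------------------------------------------------------------
# specifications

@dataclass
class EvokedComponent:
    """One evoked deflection: a Hanning bump with condition-dependent peak.

    ``by`` names the trial-label column that modulates the amplitude and
    ``amplitudes`` maps its values to bump peaks (µV) at weight-1 electrodes.
    ``group`` restricts the component to wake or nap subjects.
    """

    name: str
    phase: str                       # "encoding" or "test"
    electrodes: tuple[str, ...]
    center_ms: float
    width_ms: float
    by: str                          # label column, e.g. "half", "regularity"
    amplitudes: dict[str, float]     # label value -> peak µV
    group: str = "both"              # "wake", "nap", "both"
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ConfigurationError(f"{self.name}: width must be positive")
        for e, w in self.weights.items():
            if not -1.0 <= w <= 1.0:
                raise ConfigurationError(
                    f"{self.name}: topography weight {w} for {e} outside "
                    "[-1, 1]")

    def weight(self, electrode: str) -> float:
        return self.weights.get(electrode, 1.0)


@dataclass
class EffectSpec:
    components: list[EvokedComponent]


@dataclass
class NoiseSpec:
    rms_uv: float = 25.0             # broadband background RMS per channel
    spectral_exponent: float = 1.0   # power ~ 1/f^exponent
    channel_correlation: float = 0.6
    artifact_prob: float = 0.3       # per-trial artifact rate (study-like
                                     # rejection: ~22 of 32 test trials kept)
    artifact_amp_uv: float = 400.0
    artifact_dur_ms: float = 250.0

    def __post_init__(self):
        if self.rms_uv < 0:
            raise ConfigurationError("noise RMS must be >= 0")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ConfigurationError("artifact probability must be in [0, 1]")


@dataclass
class SpindleSimSpec:
    density_per_min: float = 5.0     # events / min NonREM
    freq_mean_hz: float = 13.65      # infant fast-spindle peak regime
    freq_sd_hz: float = 0.45
    duration_range_s: tuple[float, float] = (0.8, 2.0)
    p2p_mean_uv: float = 40.0
    p2p_sd_uv: float = 5.0
    background_rms_uv: float = 15.0
    spectral_exponent: float = 1.0
    min_gap_s: float = 0.6           # >= 0.5 keeps events unambiguous;
                                     # set below 0.5 to exercise the merge rule
    hypnogram: tuple[tuple[str, int], ...] = (
        ("W", 4), ("N1", 2), ("N2", 20), ("SWS", 16), ("N2", 2),
        ("REM", 6), ("W", 2))        # 20 min NonREM in a 26 min nap
    artifact_epochs: tuple[int, ...] = ()
    mastoid_rms_uv: float = 5.0

    def __post_init__(self):
        lo, hi = self.duration_range_s
        if not (0.0 < lo <= hi <= 5.0):
            raise ConfigurationError("duration range must lie within (0, 5] s")
        if self.density_per_min < 0:
            raise ConfigurationError("density must be >= 0")


@dataclass
class ErpSubject:
    subject: int
    group: str                                # "wake" or "nap"
    recordings: dict[str, Recording]          # phase -> continuous recording
    events: dict[str, pd.DataFrame]           # phase -> event table
    ground_truth: pd.DataFrame                # injected effect table


#: contrast registry: name -> (label column, minuend, subtrahend, phase)
CONTRASTS = {
    "familiarity": ("half", "second", "first", "encoding"),
    "memory": ("regularity", "irregular", "regular", "test"),
}

_FRONTAL_CENTRAL = COMPOSITE_REGIONS["frontal"] + COMPOSITE_REGIONS["central"]


def default_effect_spec() -> EffectSpec:
    """Evoked components emulating the study's familiarity and memory effects.

    Encoding: the early frontal-central positivity decreases by 2 µV from
    first to second half, the mid-central positivity by 1 µV, and the late
    frontal negativity shrinks by 1 µV.  Test: an early familiarity-like
    memory effect of +1.5 µV (irregular - regular) over frontal-central
    sites and a late frontal effect of +1 µV in both groups; the nap group
    additionally shows the polarity-inversed mid-latency N400-like effect
    (-1.5 µV) over centro-parieto-occipital sites, the wake group a
    familiarity-like +1.2 µV central effect.
    """
    return EffectSpec(components=[
        EvokedComponent("early_familiarity", "encoding", _FRONTAL_CENTRAL,
                        200.0, 300.0, "half",
                        {"first": 3.0, "second": 1.0}),
        EvokedComponent("mid_familiarity", "encoding",
                        COMPOSITE_REGIONS["central"], 500.0, 300.0, "half",
                        {"first": 2.0, "second": 1.0}),
        EvokedComponent("late_familiarity", "encoding",
                        COMPOSITE_REGIONS["frontal"], 775.0, 250.0, "half",
                        {"first": -2.0, "second": -1.0}),
        EvokedComponent("early_memory", "test", _FRONTAL_CENTRAL,
                        200.0, 300.0, "regularity",
                        {"regular": 1.0, "irregular": 2.5}),
        EvokedComponent("late_memory", "test", COMPOSITE_REGIONS["frontal"],
                        825.0, 250.0, "regularity",
                        {"regular": 0.0, "irregular": 1.0}),
        EvokedComponent("mid_memory_wake", "test",
                        COMPOSITE_REGIONS["central"], 450.0, 300.0,
                        "regularity", {"regular": 0.0, "irregular": 1.2},
                        group="wake"),
        EvokedComponent("n400_nap", "test", COMPOSITE_REGIONS["CPO"],
                        550.0, 300.0, "regularity",
                        {"regular": 0.5, "irregular": -1.0}, group="nap"),
    ])


# --------------------------------------------------------------------------
# helpers

def _hanning_bump(center_ms: float, width_ms: float, fs: float,
                  t0_ms: float, n_samples: int) -> np.ndarray:
    """Unit-peak Hanning bump evaluated on a sample grid starting at t0."""
    t = t0_ms + np.arange(n_samples) * 1000.0 / fs
    x = (t - (center_ms - width_ms / 2.0)) / width_ms
    out = np.zeros(n_samples)
    inside = (x >= 0.0) & (x <= 1.0)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * x[inside]))
    return out


def one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                     rms_uv: float, exponent: float = 1.0,
                     fs: float = 500.0, dtype=np.float64) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^exponent, unit-free
    shape scaled to the requested per-channel RMS."""
    n_f = n_samples // 2 + 1
    real_dtype = np.dtype(dtype)
    coef = (rng.standard_normal((n_channels, n_f), dtype=real_dtype)
            + 1j * rng.standard_normal((n_channels, n_f), dtype=real_dtype))
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros(n_f, dtype=real_dtype)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = fft.irfft(coef * shape, n=n_samples, axis=1)
    if rms_uv == 0.0:
        return np.zeros_like(x)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms_uv


def _mixing_matrix(n: int, corr: float) -> np.ndarray:
    """Cholesky factor of a uniform-correlation matrix."""
    r = np.full((n, n), corr)
    np.fill_diagonal(r, 1.0)
    return np.linalg.cholesky(r)


# --------------------------------------------------------------------------
# ERP sessions

def generate_erp_dataset(schedule: pd.DataFrame, effects: EffectSpec,
                         noise: NoiseSpec, n_subjects: int, seed: int,
                         groups: list[str] | None = None, fs: float = 500.0,
                         isi_s: float = 1.3, pad_s: float = 6.0,
                         subject_amp_sd_uv: float = 1.5,
                         ) -> list[ErpSubject]:
    """Simulate per-subject continuous ERP-session recordings + event tables.

    Each scheduled trial contributes background noise plus the matching
    condition's evoked components, time-locked to the suffix onset.
    ``groups`` assigns "wake"/"nap" per subject (default alternating);
    ``subject_amp_sd_uv`` adds a per-subject, per-component amplitude offset
    emulating between-infant variability.  Ground-truth effect tables (the
    noise-free window-mean contrasts per region) are attached per subject.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    for comp in effects.components:
        unknown = [e for e in comp.electrodes if e not in ERP_MONTAGE]
        if unknown:
            raise ConfigurationError(
                f"component {comp.name}: electrodes {unknown} not in the "
                "21-channel montage")
    if groups is None:
        groups = ["nap" if i % 2 == 0 else "wake" for i in range(n_subjects)]
    if len(groups) != n_subjects:
        raise ConfigurationError("groups must have one entry per subject")

    rng = np.random.default_rng(seed)
    mix = _mixing_matrix(len(ERP_MONTAGE), noise.channel_correlation)
    phases = sorted(schedule.phase.unique(),
                    key=["encoding", "test"].index)
    subjects = []
    gt_cache: dict[str, pd.DataFrame] = {}
    for s in range(n_subjects):
        group = groups[s]
        # per-subject amplitude offsets, shared across that component's trials
        offs = {c.name: rng.normal(0.0, subject_amp_sd_uv)
                for c in effects.components}
        recs, evs = {}, {}
        for phase in phases:
            rows = schedule[schedule.phase == phase].reset_index(drop=True)
            n_trials = len(rows)
            onsets_s = pad_s + np.arange(n_trials) * isi_s \
                + rng.uniform(0.0, 0.1, n_trials)
            n_samples = int(np.ceil((onsets_s[-1] + isi_s + pad_s) * fs))
            n_samples = fft.next_fast_len(n_samples)  # keeps FFTs cheap
            data = one_over_f_noise(rng, len(ERP_MONTAGE), n_samples,
                                    noise.rms_uv, noise.spectral_exponent, fs,
                                    dtype=np.float32)
            if noise.rms_uv > 0:
                data = mix.astype(np.float32) @ data
            onset_samples = np.round(onsets_s * fs).astype(int)
            comps = [c for c in effects.components if c.phase == phase
                     and c.group in ("both", group)]
            for comp in comps:
                n_b = int(round((comp.width_ms / 1000.0) * fs)) + 1
                t0 = comp.center_ms - comp.width_ms / 2.0
                start_off = int(round(t0 * fs / 1000.0))
                bump = _hanning_bump(comp.center_ms, comp.width_ms, fs,
                                     start_off * 1000.0 / fs, n_b)
                ch_idx = np.array([ERP_MONTAGE.index(e)
                                   for e in comp.electrodes])
                w = np.array([comp.weight(e) for e in comp.electrodes])
                for trial in range(n_trials):
                    amp = comp.amplitudes[rows[comp.by].iloc[trial]] \
                        + offs[comp.name]
                    a = onset_samples[trial] + start_off
                    data[ch_idx, a:a + n_b] += (amp * w)[:, None] * bump
            # artifact trials: square excursion on one random scalp channel
            n_art = int(round(noise.artifact_dur_ms / 1000.0 * fs))
            is_art = rng.random(n_trials) < noise.artifact_prob
            for trial in np.flatnonzero(is_art):
                ch = rng.integers(0, len(ERP_MONTAGE) - 2)  # scalp only
                a = onset_samples[trial] + rng.integers(0, int(0.4 * fs))
                data[ch, a:a + n_art] += noise.artifact_amp_uv
            ev = rows.copy()
            ev.insert(0, "onset_sample", onset_samples)
            ev["artifact_injected"] = is_art.astype(int)
            recs[phase] = Recording(data, fs, ERP_MONTAGE,
                                    {"subject": s, "group": group,
                                     "phase": phase})
            evs[phase] = ev
        if group not in gt_cache:
            gt_cache[group] = ground_truth_effects(effects, group, fs=fs)
        subjects.append(ErpSubject(s, group, recs, evs, gt_cache[group]))
    return subjects


def ground_truth_effects(effects: EffectSpec, group: str,
                         fs: float = 500.0) -> pd.DataFrame:
    """Injected window-mean contrast amplitudes per region and window.

    Evaluates the noise-free condition-difference waveform of each registered
    contrast, averages it over every ROI/composite region and analysis
    window, and tabulates the result.  ``true_uv`` reports the contrast as
    seen through the published ERP band-pass (the measurement protocol's
    response is part of the study conditions and attenuates slow monophasic
    deflections); ``true_uv_unfiltered`` is the raw injected value.
    Per-subject amplitude offsets shift both conditions of a contrast
    equally, so they cancel and the table depends only on group.
    """
    from . import filters

    n_epoch = int(round(1100.0 * fs / 1000.0)) + 1
    t_ms = np.arange(n_epoch) * 1000.0 / fs - 100.0
    taps = filters.design_erp_bandpass(fs)
    # evaluate on a long padded grid so the 9.6 s filter sees a full signal
    pad = taps.size
    rows = []
    for contrast, (col, minu, subtr, phase) in CONTRASTS.items():
        diff = np.zeros((len(ERP_MONTAGE), n_epoch + 2 * pad))
        for comp in effects.components:
            if comp.phase != phase or comp.group not in ("both", group):
                continue
            base = comp.amplitudes[minu] - comp.amplitudes[subtr]
            bump = _hanning_bump(comp.center_ms, comp.width_ms, fs,
                                 -100.0 - pad * 1000.0 / fs,
                                 n_epoch + 2 * pad)
            for e in comp.electrodes:
                diff[ERP_MONTAGE.index(e)] += base * comp.weight(e) * bump
        filtered = filters.apply_zero_phase(diff, taps)[:, pad:pad + n_epoch]
        raw = diff[:, pad:pad + n_epoch]
        for region, electrodes in {**ROI_LAYOUT, **COMPOSITE_REGIONS}.items():
            idx = [ERP_MONTAGE.index(e) for e in electrodes]
            wave_f = filtered[idx].mean(axis=0)
            wave_r = raw[idx].mean(axis=0)
            for window, (lo, hi) in ANALYSIS_WINDOWS.items():
                sel = (t_ms >= lo - 1e-9) & (t_ms <= hi + 1e-9)
                rows.append(dict(contrast=contrast, region=region,
                                 window=window, group=group,
                                 true_uv=float(wave_f[sel].mean()),
                                 true_uv_unfiltered=float(wave_r[sel].mean()),
                                 minuend=minu, subtrahend=subtr))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# nap sleep

def generate_sleep_eeg(spec: SpindleSimSpec, seed: int,
                       fs: float = 256.0):
    """Simulate a nap EEG with ground-truth spindle events.

    Returns ``(recording, hypnogram, ground_truth)``.  Spindles are placed by
    a Poisson process within artifact-free NonREM epochs only, never
    overlapping and never crossing a NonREM run boundary; each is a sinusoid
    at its drawn frequency under a raised-cosine envelope rescaled so the
    realised peak-to-peak amplitude equals the drawn value.  The same events
    appear on all scalp channels; mastoids carry independent low-level noise.
    """
    rng = np.random.default_rng(seed)
    stages, artifacts = [], []
    for stage, count in spec.hypnogram:
        stages += [stage] * count
    artifacts = [1 if i in spec.artifact_epochs else 0
                 for i in range(len(stages))]
    hyp = pd.DataFrame(dict(epoch_index=np.arange(len(stages)),
                            stage=stages, artifact=artifacts))
    n_samples = int(len(stages) * HYPNOGRAM_EPOCH_S * fs)
    scalp = [c for c in SLEEP_MONTAGE if c not in ("M1", "M2")]

    data = np.zeros((len(SLEEP_MONTAGE), n_samples))
    if spec.background_rms_uv > 0:
        data[:len(scalp)] = one_over_f_noise(
            rng, len(scalp), n_samples, spec.background_rms_uv,
            spec.spectral_exponent, fs)
    if spec.mastoid_rms_uv > 0:
        data[len(scalp):] = one_over_f_noise(
            rng, 2, n_samples, spec.mastoid_rms_uv, spec.spectral_exponent,
            fs)

    # contiguous artifact-free NonREM runs, in seconds
    keep = [(s in ("N1", "N2", "SWS")) and a == 0
            for s, a in zip(stages, artifacts)]
    runs, i = [], 0
    while i < len(keep):
        if keep[i]:
            j = i
            while j + 1 < len(keep) and keep[j + 1]:
                j += 1
            runs.append((i * HYPNOGRAM_EPOCH_S, (j + 1) * HYPNOGRAM_EPOCH_S))
            i = j + 1
        else:
            i += 1

    events = []
    gap = spec.min_gap_s
    for run_start, run_stop in runs:
        run_len = run_stop - run_start
        n_events = rng.poisson(spec.density_per_min * run_len / 60.0)
        if n_events == 0:
            continue
        durs = rng.uniform(*spec.duration_range_s, n_events)
        slack = run_len - durs.sum() - gap * (n_events + 1)
        if slack < 0:
            raise GenerationError(
                f"density {spec.density_per_min}/min with durations "
                f"{spec.duration_range_s} s and {gap} s gaps does not fit a "
                f"{run_len:.0f} s NonREM run without overlap")
        cuts = np.sort(rng.uniform(0.0, slack, n_events))
        for k in range(n_events):
            # k-th onset: leading gap + spare time cut + earlier events
            start = run_start + gap + cuts[k] + durs[:k].sum() + k * gap
            freq = rng.normal(spec.freq_mean_hz, spec.freq_sd_hz)
            p2p = max(rng.normal(spec.p2p_mean_uv, spec.p2p_sd_uv), 1.0)
            a = int(round(start * fs))
            n_b = int(round(durs[k] * fs))
            t = np.arange(n_b) / fs
            env = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / (n_b / fs)))
            burst = env * np.sin(2.0 * np.pi * freq * t)
            span = burst.max() - burst.min()
            burst *= p2p / span
            data[:len(scalp), a:a + n_b] += burst[None, :]
            events.append(dict(onset_s=start, offset_s=start + durs[k],
                               duration_s=durs[k], freq_hz=freq,
                               p2p_uv=p2p))
    rec = Recording(data, fs, SLEEP_MONTAGE, {"kind": "nap"})
    gt = pd.DataFrame(events, columns=["onset_s", "offset_s", "duration_s",
                                       "freq_hz", "p2p_uv"])
    return rec, hyp, gt
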