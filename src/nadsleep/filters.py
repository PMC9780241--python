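"""Zero-phase FIR filtering for ERP and sleep-EEG preprocessing.

The ERP band-pass reproduces the response contract of the original
preprocessing software: a 0.5--20 Hz zero-phase band-pass whose *measured*
half-power (-3 dB) points sit at 0.61 Hz and 19.89 Hz, with essentially
complete DC suppression so that ERPs can be averaged without baseline
correction.

Design approach: the band-pass is the cascade of a linear-phase low-pass and
a high-pass obtained by spectral inversion of a unit-DC-gain low-pass.
Spectral inversion pins the DC gain of the high-pass (and hence of the
cascade) at exactly zero; the window-design cutoff parameters are then
calibrated numerically so that the measured -3 dB points of the cascade land
on the published frequencies.  The calibration solves the response contract
directly rather than assuming any particular relation between nominal cutoff
and half-power point.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.optimize import brentq

__all__ = [
    "design_erp_bandpass",
    "design_lowpass",
    "amplitude_response",
    "half_power_points",
    "dc_attenuation_db",
    "apply_zero_phase",
]

#: published half-power points of the ERP band-pass, Hz
ERP_BAND_EDGES = (0.61, 19.89)

_SQRT_HALF = 1.0 / np.sqrt(2.0)


def amplitude_response(taps: np.ndarray, freqs, fs: float) -> np.ndarray:
    """Real (zero-phase) amplitude response of a symmetric FIR at ``freqs``.

    For a linear-phase filter the frequency response is A(f) * exp(-i w d);
    this returns A(f), evaluated exactly at the requested frequencies.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    n = np.arange(taps.size)
    delay = (taps.size - 1) / 2
    w = 2 * np.pi * freqs[:, None] / fs
    # rotate out the linear phase so the sum is real for symmetric taps
    resp = np.sum(taps[None, :] * np.cos(w * (n[None, :] - delay)), axis=1)
    return resp


def _unit_dc_lowpass(numtaps: int, cutoff: float, fs: float) -> np.ndarray:
    h = signal.firwin(numtaps, cutoff, fs=fs, window="hamming", pass_zero=True)
    return h / h.sum()  # DC gain exactly 1


def _inverted_highpass(numtaps: int, cutoff: float, fs: float) -> np.ndarray:
    h = -_unit_dc_lowpass(numtaps, cutoff, fs)
    h[(numtaps - 1) // 2] += 1.0  # spectral inversion: DC gain exactly 0
    return h


@lru_cache(maxsize=8)
def _calibrated_bandpass(fs: float, numtaps_hp: int, numtaps_lp: int,
                         f_lo: float, f_hi: float) -> tuple:
    """Solve for window-design cutoffs so the cascade's measured -3 dB
    points equal (f_lo, f_hi). Returns the cascade taps (as a tuple for
    hashability of the cache)."""

    def lp_amp(cut, f):
        return amplitude_response(_unit_dc_lowpass(numtaps_lp, cut, fs), f, fs)[0]

    def hp_amp(cut, f):
        return amplitude_response(_inverted_highpass(numtaps_hp, cut, fs), f, fs)[0]

    # The transition bands are far apart, so each edge is nearly independent
    # of the other; two alternation passes converge well inside tolerance.
    cut_hp, cut_lp = f_lo, f_hi
    for _ in range(2):
        other = lp_amp(cut_lp, f_lo)
        cut_hp = brentq(lambda c: hp_amp(c, f_lo) * other - _SQRT_HALF,
                        0.05, 2.0, xtol=1e-6)
        other = hp_amp(cut_hp, f_hi)
        cut_lp = brentq(lambda c: lp_amp(c, f_hi) * other - _SQRT_HALF,
                        f_hi - 5.0, f_hi + 5.0, xtol=1e-6)
    taps = np.convolve(_inverted_highpass(numtaps_hp, cut_hp, fs),
                       _unit_dc_lowpass(numtaps_lp, cut_lp, fs))
    return tuple(taps)


def design_erp_bandpass(fs: float = 500.0) -> np.ndarray:
    """Calibrated 0.5--20 Hz zero-phase ERP band-pass for sampling rate ``fs``.

    Returns the symmetric FIR taps of the cascade.  Filter lengths scale with
    the sampling rate so that the impulse-response duration (hence the
    response shape near the published edges) is rate-independent.
    """
    if fs <= 2 * ERP_BAND_EDGES[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for a 20 Hz band edge")
    # 8 s high-pass / 1.6 s low-pass impulse responses, odd lengths
    numtaps_hp = int(round(8.0 * fs)) // 2 * 2 + 1
    numtaps_lp = int(round(1.6 * fs)) // 2 * 2 + 1
    return np.asarray(_calibrated_bandpass(float(fs), numtaps_hp, numtaps_lp,
                                           *ERP_BAND_EDGES))


def design_lowpass(cutoff: float, fs: float, width_factor: float = 3.3,
                   transition: float | None = None) -> np.ndarray:
    """Unit-DC-gain linear-phase low-pass (Hamming window design)."""
    if transition is None:
        transition = max(cutoff * 0.25, 0.5)
    numtaps = int(np.ceil(width_factor * fs / transition)) // 2 * 2 + 1
    return _unit_dc_lowpass(numtaps, cutoff, fs)


def design_display_lowpass(fs: float = 500.0, cutoff: float = 7.0) -> np.ndarray:
    """7 Hz zero-phase low-pass applied to ERP waveforms for plotting only."""
    return design_lowpass(cutoff, fs, transition=3.0)


def half_power_points(taps: np.ndarray, fs: float,
                      resolution: float = 1e-4) -> tuple[float, float]:
    """Measure the -3 dB frequencies of a band-pass from its magnitude response.

    Scans a fine grid for the outermost half-power crossings and refines each
    by root bisection on the exact amplitude function.
    """
    grid, resp = signal.freqz(taps, worN=1 << 17, fs=fs)
    amp = np.abs(resp)
    above = amp >= _SQRT_HALF
    if not above.any():
        raise ValueError("response never reaches the half-power level")
    i_lo, i_hi = np.argmax(above), len(above) - 1 - np.argmax(above[::-1])

    def f(x):
        return np.abs(amplitude_response(taps, x, fs)[0]) - _SQRT_HALF

    lo = brentq(f, grid[max(i_lo - 1, 0)], grid[i_lo], xtol=resolution) \
        if i_lo > 0 else grid[0]
    hi = brentq(f, grid[i_hi], grid[min(i_hi + 1, len(grid) - 1)],
                xtol=resolution) if i_hi < len(grid) - 1 else grid[-1]
    return float(lo), float(hi)


def dc_attenuation_db(taps: np.ndarray) -> float:
    """DC gain in dB (large negative = strong suppression)."""
    g = abs(float(np.sum(taps)))
    if g == 0.0:
        return -np.inf
    return 20.0 * np.log10(g)


def apply_zero_phase(x: np.ndarray, taps: np.ndarray, axis: int = -1) -> np.ndarray:
    """Apply a symmetric (linear-phase) FIR with zero net phase.

    'same'-mode FFT convolution; because the taps are symmetric the group
    delay cancels and the output is time-aligned with the input.  The signal
    must be at least as long as the filter (warm-up requirement).
    """
    if x.shape[axis] < taps.size:
        raise ValueError(
            f"signal length {x.shape[axis]} shorter than filter ({taps.size} taps)")
    return signal.fftconvolve(x, _shape_taps(taps, x.ndim, axis), mode="same",
                              axes=axis)


def _shape_taps(taps: np.ndarray, ndim: int, axis: int) -> np.ndarray:
    shape = [1] * ndim
    shape[axis % ndim] = taps.size
    return taps.reshape(shape)
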