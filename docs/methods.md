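# Methods

This note documents the models, numerical choices and known limitations of
the package. All quantities below are computed by the test suite or the
examples; none are asserted from memory.

## ERP band-pass filter

The preprocessing contract is a response, not a design: a zero-phase
0.5–20 Hz band-pass whose measured −3 dB points lie at 0.61 and 19.89 Hz,
with DC suppression strong enough (≥90 dB) that ERPs can be averaged
without baseline correction.

The implementation is a cascade of two linear-phase Hamming-window FIR
filters: a low-pass, and a high-pass obtained by spectral inversion of a
unit-DC-gain low-pass (`h_hp = δ − h_lp` with `Σ h_lp = 1` exactly), which
pins the cascade's DC gain at exactly zero — measured attenuation is
~−340 dB, far beyond the −90 dB contract. The window-design cutoff
parameters are then calibrated by root finding (Brent's method on the exact
amplitude response) so the *measured* half-power points land on
0.61/19.89 Hz; the two transition bands are far apart, so two alternation
passes converge well inside the ±0.02 Hz tolerance. Impulse-response
durations are 8 s (high-pass) and 1.6 s (low-pass) regardless of sampling
rate, i.e. 4001 + 801 taps at 500 Hz, cascade 4801 taps. The filter is
applied by FFT convolution in `same` mode; because the taps are symmetric
the group delay cancels and the output is exactly zero-phase.

Consequence worth knowing: a high-pass with a 0.61 Hz half-power point
removes a substantial share of the window-mean of slow monophasic ERP
deflections (tens of percent for 300 ms bumps). This is a property of the
published response, not of this implementation; the simulation ground truth
therefore reports the injected contrast both unfiltered and as seen through
the filter (`true_uv_unfiltered` vs `true_uv`), and recovery is assessed
against the latter, which is the estimand of the measurement protocol.

## Artifact rejection

A trial is rejected iff, on any analysis channel, the sample SD within any
500 ms window (sliding by one sample) exceeds 90 µV. The window length is
`round(0.5 · fs)` samples (250 at 500 Hz) and the SD uses the population
denominator (`ddof=0`); the original software documents neither choice, so
both are configurable. The implementation uses cumulative sums and is
verified for exact agreement against an exhaustive per-window `np.std`
oracle on 1,000 random epochs.

## Epoching, averaging, ROIs, windows

Epochs span −100 to +1000 ms around the suffix onset (the analysis windows
only need 100–900 ms; the margin is for display filtering), 551 samples at
500 Hz, no baseline correction. Condition averages with fewer than 10
artifact-free trials are flagged `insufficient`; they keep their values in
the output tables but the battery drops those subjects listwise from every
test whose cells they contaminate. ROIs and composite regions are
unweighted means over their printed electrode lists (composites are *not*
means of constituent ROIs — with unequal ROI sizes the two differ).
Window means are closed-interval time means. The 7 Hz display low-pass is
available for plotting only and is never applied before statistics.

## Spindle detection

NonREM (N1 + N2 + SWS by default, configurable to N2 + SWS) artifact-free
30 s epochs are low-pass filtered at 32 Hz (zero-phase FIR on the
continuous signal), decimated 256→128 Hz, and concatenated with segment
boundaries recorded; detection runs per contiguous segment so no event
spans a discontinuity. The individual peak frequency is the argmax of the
averaged modified periodogram (Hann, 4 s segments, 50% overlap → 0.25 Hz
resolution) in the 11–16 Hz search band, per channel. Detection: 3 Hz-wide
zero-phase band-pass centred on the peak; 0.2 s centred sliding RMS with
edge truncation; threshold 1.5 × SD of the band-passed signal, the SD taken
over the full concatenated NonREM stream per channel (so the threshold is
signal-relative: a global gain change leaves detections identical and
scales amplitudes proportionally); crossings gated to 0.5–5 s; successive
events merged when the gap is strictly below 0.5 s and the merged event
stays ≤5 s; peak-to-peak amplitude is max − min of the band-passed signal
within the event (the broadband alternative is configurable; the original
work does not say which was used).

Two empirical properties of this scheme that users should expect: the
0.2 s RMS window plus the band-filter envelope smear extend detected
durations by roughly 0.1–0.3 s relative to the physical burst, and under
pure noise the false-alarm rate is about 0.7–1.3 events/min (Monte-Carlo,
white or 1/f noise) — small against the ~5/min operating density but not
negligible.

When the sleep recording is referenced to the mid-central electrode and
both mastoids are present, re-referencing to the mastoid mean reconstructs
the mid-central channel as minus the mastoid mean, completing the central
region (C3, CZ, C4); otherwise the central summary uses C3 and C4 only,
with a logged note.

## Statistics

The repeated-measures ANOVA handles any number of balanced within-subject
factors plus one optional between-subject factor. Each effect is projected
onto an orthonormal contrast basis (Kronecker products of per-factor
contrast/averaging operators); H and E cross-products are formed in that
space, with Type III main effects (unweighted means of group means) when
group sizes differ — matching the conventions of the commercial software
this battery mirrors, and verified numerically against R's `car::Anova`
(type 3) including the per-effect Greenhouse–Geisser ε computed from the
pooled within-group covariance, ε = tr(S)²/(q·tr(S²)) clipped to
[1/q, 1]. Partial η² = SS_effect/(SS_effect + SS_error). Sums of squares
below 1e−12 of the data's total sum of squares are treated as rounding
residue (identical-cell inputs yield F = 0 rather than 0/0 noise).

Cohen's *d* is mean/SD of the (paired) differences for one-sample and
dependent tests and the pooled-SD standardized mean difference for
independent tests; CIs are for the tested mean difference. Pearson CIs use
the Fisher z transform with a normal quantile. The dependent-correlation
test follows Meng, Rosenthal & Rubin: z = (z₁ − z₂)·√((N−3)/(2(1−r_y)h)),
h = (1 − f·r̄²)/(1 − r̄²), f = (1 − r_y)/(2(1 − r̄²)) capped at 1. The
Kolmogorov–Smirnov normality check is an advisory (logged, never enforced);
a Wilcoxon signed-rank fallback is provided. Median splits assign the
middle observation of an odd-sized group to the lower half; ties at the
median break by stable input order with a logged warning.

## Synthetic data

The generator's defaults are the study conditions; they are not tuned.

*ERP sessions* — 21-channel (19 scalp + both mastoids) 500 Hz continuous
EEG. Background: per-channel Gaussian 1/f noise (power ∝ 1/f), RMS 25 µV,
mixed through the Cholesky factor of a uniform 0.6 inter-channel
correlation. Evoked components are Hanning-windowed monophasic bumps —
the simplest shape matching slow infant-ERP deflections — whose peak
amplitudes (µV) depend on the condition; the defaults inject a −2 µV early
frontal-central familiarity decrement, −1 µV mid-central and +1 µV late
frontal changes in encoding, a +1.5 µV early and +1 µV late memory effect
in the test phase, plus the group-specific mid-latency effects (wake:
+1.2 µV central; nap: −1.5 µV over CPO). Per-subject variability adds a
N(0, 1.5 µV) offset per component, which cancels in every within-subject
contrast. Trials are spaced 1.3 s plus uniform 0–0.1 s jitter. Artifact
trials (probability 0.3, chosen so that artifact-free trial counts match
the reported ones, ~22 of 32 test trials) receive a 400 µV, 250 ms square
excursion on one random scalp channel, which deterministically trips the
90 µV criterion. Generation uses float32 and FFT-friendly signal lengths
for speed; averaging accumulates in float64.

*Nap sleep* — 256 Hz EEG over F3/FZ/F4/C3/C4/P3/PZ/P4 plus mastoids, with
a 30 s-epoch hypnogram (default: 26 min nap containing 20 min NonREM and a
REM period). Spindles are Poisson-placed (5/min NonREM) within contiguous
artifact-free NonREM runs, non-overlapping with a ≥0.6 s gap (configurable
below 0.5 s to exercise the merge rule); each event is a sinusoid at
N(13.65, 0.45) Hz under a raised-cosine envelope, numerically rescaled so
its realized peak-to-peak equals the drawn N(40, 5) µV value; durations are
uniform on 0.8–2.0 s. Background is 1/f noise at 15 µV RMS per channel
(independent across channels), mastoids 5 µV. A density that cannot fit a
NonREM run without overlap raises a generation error naming the constraint.

What the simulation does *not* emulate: volume-conducted spatial structure
of spindles (events are injected identically on all scalp channels, and
the reconstructed mid-central channel carries no signal, so its regional
summary is biased low in simulation); spindle frequency chirp; stage-
dependent background spectra; ocular/muscle artifacts with realistic
morphology; and any prosodic/acoustic structure of the language stimuli.
Passing recovery suites therefore validates the pipeline's machinery, not
the physiological realism of the inputs.

## Problem sizes used by the validation suites

Chosen as the package's own test design: artifact rejection is checked
against the brute-force oracle on 1,000 random toy epochs; spindle recovery
pools seeds 1–10 of the default nap (event-level F1 with IoU ≥ 0.3
matching; observed ≈0.99 with mean amplitude error ≈3%); ERP effect
recovery runs 50 independent simulated experiments of 40 subjects × 32
trials/cell (sign agreement and a 25% bound on the mean recovered
amplitude); the ANOVA is matched to the sums-of-squares oracle on 100
random designs at 1e−8; the one-sample t's type-I error uses 10,000 null
replicates and the dependent-correlation z 5,000.

## Known limitations

* The rm-ANOVA requires balanced within-subject designs (one observation
  per subject per cell); unbalanced data must be aggregated first.
* The battery's correlation block needs ≥4 nap subjects with complete
  effect values and spindle summaries; below that it is skipped with a log
  message.
* EDF output is 16-bit with per-channel physical scaling (quantisation
  ≲0.01 µV for typical EEG ranges); EDF reading goes through mne.
* Detected spindle durations are systematically longer than the underlying
  burst (RMS-window and filter smear, see above); duration-sensitive
  analyses should calibrate against simulation.
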