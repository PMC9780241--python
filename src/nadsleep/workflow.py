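"""Per-subject ERP processing: raw recordings to condition/effect tables.

Runs the full chain (mastoid re-reference, band-pass, suffix-locked
epoching, sliding-SD artifact rejection, condition averaging with the
10-trial minimum, ROI aggregation, window means) and emits two long-format
tables:

* condition table — one row per subject x phase x condition x ROI x window
  with the mean amplitude, the artifact-free trial count and the
  insufficient-data flag;
* effect table — signed contrasts (familiarity: second - first half;
  memory: irregular - regular, also split by old/new verb stems) per region
  and window.

Conditions flagged insufficient keep their amplitudes in the tables but must
be excluded from statistics; the battery drops those subjects listwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import erp
from .recording import Recording

__all__ = ["process_erp_subject", "CONDITION_SETS", "ROI_FACTORS"]

#: phase -> list of (condition name, label selector)
CONDITION_SETS = {
    "encoding": [
        ("first", {"half": "first"}),
        ("second", {"half": "second"}),
    ],
    "test": [
        ("regular", {"regularity": "regular"}),
        ("irregular", {"regularity": "irregular"}),
        ("regular_old", {"regularity": "regular", "stem_novelty": "old"}),
        ("irregular_old", {"regularity": "irregular", "stem_novelty": "old"}),
        ("regular_new", {"regularity": "regular", "stem_novelty": "new"}),
        ("irregular_new", {"regularity": "irregular", "stem_novelty": "new"}),
    ],
}

#: the nine ROIs as a Laterality x Region factorial
ROI_FACTORS = {
    "LF": ("left", "frontal"), "MF": ("mid", "frontal"),
    "RF": ("right", "frontal"),
    "LC": ("left", "central"), "MC": ("mid", "central"),
    "RC": ("right", "central"),
    "LP": ("left", "parietal_occipital"), "MPO": ("mid", "parietal_occipital"),
    "RP": ("right", "parietal_occipital"),
}

#: contrast name -> (phase, minuend condition, subtrahend condition)
EFFECT_CONTRASTS = {
    "familiarity": ("encoding", "second", "first"),
    "memory": ("test", "irregular", "regular"),
    "memory_old": ("test", "irregular_old", "regular_old"),
    "memory_new": ("test", "irregular_new", "regular_new"),
}

_PHASE_WINDOWS = {
    "encoding": ["early", "middle", "late_encoding"],
    "test": ["early", "middle", "late_test", "intermediate",
             "middle_first", "middle_second", "mid_broad"],
}


def process_erp_subject(recordings: dict[str, Recording],
                        events: dict[str, pd.DataFrame],
                        subject: int, group: str, min_trials: int = 10,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process one subject's sessions into condition and effect tables."""
    cond_rows, waves = [], {}
    for phase, rec in recordings.items():
        rec = erp.rereference_to_mastoids(rec)
        rec = erp.bandpass_erp(rec)
        epochs = erp.epoch_suffix_locked(rec, events[phase])
        epochs = erp.reject_artifacts(epochs)
        for cond, selector in CONDITION_SETS[phase]:
            avg = erp.average_condition(epochs, selector,
                                        min_trials=min_trials)
            rois = erp.roi_waveforms(avg)
            waves[(phase, cond)] = rois
            for roi, wave in rois.items():
                for window in _PHASE_WINDOWS[phase]:
                    cond_rows.append(dict(
                        subject=subject, group=group, phase=phase,
                        condition=cond, roi=roi, window=window,
                        amplitude_uv=erp.window_mean(wave, window),
                        n_trials=avg.n_trials,
                        insufficient=avg.insufficient))

    effect_rows = []
    regions = list(erp.ROI_LAYOUT) + list(erp.COMPOSITE_REGIONS)
    for effect, (phase, minu, subtr) in EFFECT_CONTRASTS.items():
        if (phase, minu) not in waves:
            continue
        for region in regions:
            wa, wb = waves[(phase, minu)][region], waves[(phase, subtr)][region]
            for window in _PHASE_WINDOWS[phase]:
                ev = erp.effect_value(wa, wb, window, region, name=effect,
                                      minuend=minu, subtrahend=subtr)
                effect_rows.append(dict(
                    subject=subject, group=group, effect=effect,
                    region=region, window=window,
                    amplitude_uv=ev.amplitude_uv,
                    insufficient=wa.insufficient or wb.insufficient))
    return pd.DataFrame(cond_rows), pd.DataFrame(effect_rows)
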