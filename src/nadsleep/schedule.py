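"""Stimulus schedules for the AXB / CXD artificial-grammar paradigm.

The miniature language pairs an auxiliary or modal verb (element A or C) with
a dependent verb suffix (B or D) across a variable intervening verb stem, so
each sentence instantiates one of four frames: A_B, C_D (one language
version's regular dependencies) and A_D, C_B (the other version's).  Element
occurrence probabilities and the adjacent-element transition structure are
identical in every condition by construction, so only the nonadjacent
dependency distinguishes regular from irregular sentences.

Encoding phase: 128 sentences — 16 "old" verb stems x 2 regular frames, each
phrase presented four times (twice in each half, the second half repeating
the first half's phrases).  Memory-test phase: 128 sentences — 32 per cell of
regularity (regular / irregular) x stem novelty (old / new).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError

__all__ = ["generate_trial_schedule", "validate_schedule",
    "FRAMES", "REGULAR_FRAMES"]

FRAMES = ("A_B", "C_D", "A_D", "C_B")

#: regular (familiarised) frames per language version
REGULAR_FRAMES = {1: ("A_B", "C_D"), 2: ("A_D", "C_B")}

N_OLD_STEMS = 16
N_STEMS = 32

_COLUMNS = ["phase", "sentence_index", "frame", "stem_id", "stem_novelty",
            "regularity", "half", "language_version"]


def _sentence_index(frame: str, stem: int) -> int:
    return FRAMES.index(frame) * N_STEMS + stem


def _shuffle_no_repeat(rows: list[dict], key, rng: np.random.Generator,
                       max_tries: int = 200) -> list[dict]:
    """Random order with no two adjacent rows sharing ``key`` (swap repair)."""
    rows = list(rows)
    for _ in range(max_tries):
        rng.shuffle(rows)
        ok = True
        for i in range(1, len(rows)):
            if key(rows[i]) == key(rows[i - 1]):
                # swap with a later position that breaks the repeat
                fixed = False
                for j in range(i + 1, len(rows)):
                    if key(rows[j]) != key(rows[i - 1]) and (
                            j == len(rows) - 1 or True):
                        rows[i], rows[j] = rows[j], rows[i]
                        if i + 1 >= len(rows) or key(rows[i + 1]) != key(rows[i]):
                            fixed = True
                            break
                        rows[i], rows[j] = rows[j], rows[i]
                if not fixed:
                    ok = False
                    break
        if ok and all(key(rows[i]) != key(rows[i - 1])
                      for i in range(1, len(rows))):
            return rows
    raise GenerationError("could not order trials without immediate repeats")


def generate_trial_schedule(version: int, seed: int,
                            no_immediate_repeat: bool = True) -> pd.DataFrame:
    """Build the encoding + memory-test presentation schedule.

    Parameters
    ----------
    version : {1, 2}
        Language version; decides which auxiliary/modal--suffix pairings are
        regular.
    seed : int
        Seeds the presentation-order randomisation; identical seeds give
        identical schedules.
    no_immediate_repeat : bool
        If True (default), no phrase (encoding) or verb stem (test) is
        presented twice in direct succession.  The original presentation-order
        constraints are not documented; this rule is a plausible stand-in and
        can be switched off.
    """
    if version not in REGULAR_FRAMES:
        raise ConfigurationError(f"language version must be 1 or 2, got {version!r}")
    rng = np.random.default_rng(seed)
    regular = REGULAR_FRAMES[version]
    irregular = tuple(f for f in FRAMES if f not in regular)

    # --- encoding: 16 old stems x 2 regular frames, twice per half ---------
    phrases = [(frame, stem) for frame in regular
               for stem in range(1, N_OLD_STEMS + 1)]
    enc_rows = []
    for half in ("first", "second"):
        half_rows = [dict(phase="encoding", sentence_index=_sentence_index(f, s),
                          frame=f, stem_id=s, stem_novelty="old",
                          regularity="regular", half=half,
                          language_version=version)
                     for f, s in phrases for _ in range(2)]
        if no_immediate_repeat:
            half_rows = _shuffle_no_repeat(
                half_rows, key=lambda r: (r["frame"], r["stem_id"]), rng=rng)
        else:
            rng.shuffle(half_rows)
        enc_rows.extend(half_rows)

    # --- memory test: 32 sentences per regularity x novelty cell -----------
    test_rows = []
    for frames, reg in ((regular, "regular"), (irregular, "irregular")):
        for novelty, stems in (("old", range(1, N_OLD_STEMS + 1)),
                               ("new", range(N_OLD_STEMS + 1, N_STEMS + 1))):
            test_rows += [dict(phase="test", sentence_index=_sentence_index(f, s),
                               frame=f, stem_id=s, stem_novelty=novelty,
                               regularity=reg, half=pd.NA,
                               language_version=version)
                          for f in frames for s in stems]
    if no_immediate_repeat:
        test_rows = _shuffle_no_repeat(test_rows, key=lambda r: r["stem_id"],
                                       rng=rng)
    else:
        rng.shuffle(test_rows)

    df = pd.DataFrame(enc_rows + test_rows, columns=_COLUMNS)
    validate_schedule(df)
    return df


def _frame_elements(frame: str) -> tuple[str, str]:
    first, suffix = frame.split("_")
    return first, suffix


def validate_schedule(df: pd.DataFrame) -> None:
    """Check the structural invariants of a schedule; raise GenerationError.

    Verified by exhaustive counting: phase row counts, cell sizes, equal
    element (A/B/C/D) frequencies across the four test cells, constant
    adjacent-pair transition counts (first-element -> stem category and stem
    category -> suffix), and per-stem balance across regularity.
    """
    enc = df[df.phase == "encoding"]
    test = df[df.phase == "test"]
    if len(enc) != 128:
        raise GenerationError(f"encoding must have 128 rows, found {len(enc)}")
    if len(test) != 128:
        raise GenerationError(f"test must have 128 rows, found {len(test)}")
    counts = enc.groupby(["frame", "stem_id"]).size()
    if not (counts == 4).all() or len(counts) != 32:
        raise GenerationError("encoding must present each phrase four times")
    half_counts = enc.groupby(["half", "frame", "stem_id"]).size()
    if not (half_counts == 2).all():
        raise GenerationError("each phrase must appear twice per encoding half")

    cells = {}
    for (reg, nov), cell in test.groupby(["regularity", "stem_novelty"]):
        if len(cell) != 32:
            raise GenerationError(
                f"test cell {reg}/{nov} must have 32 rows, found {len(cell)}")
        first = cell.frame.map(lambda f: _frame_elements(f)[0])
        suffix = cell.frame.map(lambda f: _frame_elements(f)[1])
        cells[(reg, nov)] = {
            "elements": (first.value_counts().to_dict()
                         | suffix.value_counts().to_dict()),
            "transitions": {**{(a, "X"): c for a, c in
                               first.value_counts().items()},
                            **{("X", b): c for b, c in
                               suffix.value_counts().items()}},
        }
    ref = next(iter(cells.values()))
    for name, cell in cells.items():
        if cell["elements"] != ref["elements"]:
            raise GenerationError(f"element frequencies differ in cell {name}")
        if cell["transitions"] != ref["transitions"]:
            raise GenerationError(f"transition frequencies differ in cell {name}")
    # each stem occurs equally often under regular and irregular structure
    stem_by_reg = test.groupby(["stem_novelty", "stem_id", "regularity"]).size()
    if not (stem_by_reg == 2).all():
        raise GenerationError("stems must be balanced across regularity")
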