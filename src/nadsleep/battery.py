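"""The registered analysis battery mirroring the study's Results section.

Given the condition/effect tables from :mod:`.workflow` and per-subject
spindle summaries, runs: the familiarity ANOVA (Familiarity x Laterality x
Region), the memory ANOVAs (Regularity x Old/New x Laterality x Region with
the between-subject Group factor), group-wise one-sample tests per region at
the region-count-adjusted alpha, the spindle--ERP correlations including the
dependent-correlation comparison between old- and new-stem effects, and the
median-split spindle-subgroup ANOVA.

Subjects flagged insufficient in any cell entering a given test are dropped
listwise from that test.  Every row of the output table records the alpha
that applied and the decision at that alpha.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats
from .errors import DegenerateInputError, DesignError, InsufficientDataError
from .workflow import ROI_FACTORS

logger = logging.getLogger(__name__)

__all__ = ["run_battery", "spindle_predictor"]

#: sleep channels averaged into the left/mid frontal-central spindle predictor
SPINDLE_PREDICTOR_CHANNELS = ("F3", "FZ", "C3")
#: channels defining the median-split measure (left- and mid-frontal)
MEDIAN_SPLIT_CHANNELS = ("F3", "FZ")


def _anova_frame(cond: pd.DataFrame, phase: str, conditions: list[str],
                 window: str) -> pd.DataFrame:
    d = cond[(cond.phase == phase) & (cond.window == window)
             & cond.condition.isin(conditions)
             & cond.roi.isin(ROI_FACTORS)].copy()
    bad = d.loc[d.insufficient, "subject"].unique()
    if len(bad):
        logger.info("%s/%s: dropping %d subjects with insufficient trials",
                    phase, window, len(bad))
        d = d[~d.subject.isin(bad)]
    d["laterality"] = d.roi.map(lambda r: ROI_FACTORS[r][0])
    d["region"] = d.roi.map(lambda r: ROI_FACTORS[r][1])
    return d


def _result_row(test, kind, statistic, df, p, effect_size, ci_low, ci_high,
                alpha, n):
    return dict(test=test, kind=kind, statistic=statistic, df=str(df), p=p,
                effect_size=effect_size, ci_low=ci_low, ci_high=ci_high,
                alpha=alpha, significant=bool(p < alpha), n=n)


def spindle_predictor(spindle_table: pd.DataFrame,
                      channels=SPINDLE_PREDICTOR_CHANNELS) -> pd.Series:
    """Per-subject mean spindle peak-to-peak amplitude over given channels.

    ``spindle_table`` is long format: subject, label, mean_p2p_uv (channel
    rows of the spindle summary, one block per nap subject).
    """
    d = spindle_table[spindle_table.label.isin(channels)]
    return d.groupby("subject").mean_p2p_uv.mean()


def run_battery(cond: pd.DataFrame, effects: pd.DataFrame,
                spindle_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the registered battery; returns one row per test."""
    rows: list[dict] = []

    # --- familiarity ANOVAs (encoding) ---------------------------------
    for window in ("early", "middle", "late_encoding"):
        d = _anova_frame(cond, "encoding", ["first", "second"], window)
        try:
            res = stats.rm_anova_gg(
                d.rename(columns={"condition": "Familiarity"}),
                dv="amplitude_uv", subject="subject",
                within=["Familiarity", "laterality", "region"])
        except (DesignError, DegenerateInputError) as e:
            logger.warning("familiarity ANOVA %s failed: %s", window, e)
            continue
        n = d.subject.nunique()
        for r in res:
            if "Familiarity" in r.effect:
                rows.append(_result_row(
                    f"familiarity_anova[{window}]:{r.effect}", "rm_anova",
                    r.F, (round(r.df1, 2), round(r.df2, 2)), r.p,
                    r.partial_eta_sq, np.nan, np.nan, 0.05, n))

    # --- memory ANOVAs (test, Group between) ---------------------------
    for window in ("early", "middle", "late_test"):
        d = _anova_frame(cond, "test",
                         ["regular_old", "irregular_old",
                          "regular_new", "irregular_new"], window)
        d["Regularity"] = d.condition.str.split("_").str[0]
        d["OldNew"] = d.condition.str.split("_").str[1]
        try:
            res = stats.rm_anova_gg(
                d, dv="amplitude_uv", subject="subject",
                within=["Regularity", "OldNew", "laterality", "region"],
                between="group")
        except (DesignError, DegenerateInputError) as e:
            logger.warning("memory ANOVA %s failed: %s", window, e)
            continue
        n = d.subject.nunique()
        keep = ("Regularity", "Regularity x group", "Regularity x OldNew",
                "Regularity x region", "Regularity x region x group", "group")
        for r in res:
            if r.effect in keep:
                rows.append(_result_row(
                    f"memory_anova[{window}]:{r.effect}", "rm_anova",
                    r.F, (round(r.df1, 2), round(r.df2, 2)), r.p,
                    r.partial_eta_sq, np.nan, np.nan, 0.05, n))

    # --- group-wise one-sample tests per region at adjusted alpha ------
    regions = ("frontal", "central", "parietal_occipital")
    alpha = stats.alpha_for_regions(len(regions))
    for effect, window in (("memory", "early"), ("memory", "middle"),
                           ("memory", "late_test"),
                           ("familiarity", "early")):
        for group, sub in effects.groupby("group"):
            for region in regions:
                d = sub[(sub.effect == effect) & (sub.region == region)
                        & (sub.window == window) & ~sub.insufficient]
                if len(d) < 2:
                    continue
                try:
                    t = stats.ttest("one_sample", d.amplitude_uv.to_numpy())
                except DegenerateInputError:
                    continue
                rows.append(_result_row(
                    f"{effect}[{window}]:{group}:{region}", "one_sample_t",
                    t.t, t.df, t.p, t.cohen_d, t.ci_low, t.ci_high, alpha,
                    t.n))

    # --- spindle-ERP correlations and the dependent-correlation test ---
    if spindle_table is not None and len(spindle_table):
        pred = spindle_predictor(spindle_table)
        nap = effects[(effects.group == "nap") & ~effects.insufficient]

        def lfc(effect):
            d = nap[(nap.effect == effect) & (nap.region == "LFC")
                    & (nap.window == "intermediate")]
            return d.set_index("subject").amplitude_uv

        old, new = lfc("memory_old"), lfc("memory_new")
        common = pred.index.intersection(old.index).intersection(new.index)
        if len(common) >= 4:
            x = pred.loc[common].to_numpy()
            yo, yn = old.loc[common].to_numpy(), new.loc[common].to_numpy()
            try:
                c_old = stats.pearson_ci(x, yo)
                c_new = stats.pearson_ci(x, yn)
                r_oldnew = stats.pearson_ci(yo, yn)
                z, pz = stats.meng_z(c_old.r, c_new.r, r_oldnew.r,
                                     len(common))
                rows.append(_result_row("spindle_vs_FCMR_old", "pearson",
                                        c_old.r, len(common) - 2, c_old.p,
                                        c_old.r, c_old.ci_low, c_old.ci_high,
                                        0.05, len(common)))
                rows.append(_result_row("spindle_vs_FCMR_new", "pearson",
                                        c_new.r, len(common) - 2, c_new.p,
                                        c_new.r, c_new.ci_low, c_new.ci_high,
                                        0.05, len(common)))
                rows.append(_result_row("spindle_corr_old_vs_new", "meng_z",
                                        z, np.nan, pz, np.nan, np.nan, np.nan,
                                        0.05, len(common)))
            except DegenerateInputError as e:
                logger.warning("spindle correlations skipped: %s", e)

        # --- median-split subgroup ANOVA -------------------------------
        split_measure = spindle_predictor(spindle_table,
                                          MEDIAN_SPLIT_CHANNELS)
        nap_cond = cond[(cond.group == "nap") & (cond.roi == "CPO")
                        & (cond.window == "middle")
                        & cond.condition.isin(["regular", "irregular"])]
        subs = split_measure.index.intersection(nap_cond.subject.unique())
        if len(subs) >= 4:
            vals = split_measure.loc[subs]
            low, high = stats.median_split(vals.to_numpy())
            subgroup = pd.Series("high", index=subs)
            subgroup.iloc[low] = "low"
            d = nap_cond[nap_cond.subject.isin(subs)].copy()
            d["subgroup"] = d.subject.map(subgroup)
            bad = d.loc[d.insufficient, "subject"].unique()
            d = d[~d.subject.isin(bad)]
            try:
                res = stats.rm_anova_gg(
                    d.rename(columns={"condition": "Regularity"}),
                    dv="amplitude_uv", subject="subject",
                    within=["Regularity"], between="subgroup")
                for r in res:
                    if r.effect == "Regularity x subgroup":
                        rows.append(_result_row(
                            "median_split_anova:Regularity x subgroup",
                            "rm_anova", r.F,
                            (round(r.df1, 2), round(r.df2, 2)), r.p,
                            r.partial_eta_sq, np.nan, np.nan, 0.05,
                            d.subject.nunique()))
            except (DesignError, DegenerateInputError) as e:
                logger.warning("median-split ANOVA failed: %s", e)

    if not rows:
        raise InsufficientDataError("no test in the battery could be run")
    return pd.DataFrame(rows)
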