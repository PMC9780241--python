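"""Run the registered statistical battery on a simulated cohort.

Simulates a small wake/nap cohort, processes every subject's sessions into
condition and effect tables, attaches per-subject spindle summaries for the
nap group, and runs the battery: familiarity and memory repeated-measures
ANOVAs with Greenhouse-Geisser correction, group-wise one-sample tests at
the region-adjusted alpha (0.017 for three regions), spindle-ERP
correlations, and the dependent-correlation comparison.
"""

import pandas as pd

from nadsleep import (NoiseSpec, SpindleSimSpec, battery,
                      default_effect_spec, generate_erp_dataset,
                      generate_sleep_eeg, generate_trial_schedule,
                      process_erp_subject, run_spindle_analysis)

n_nap, n_wake = 8, 6
schedule = generate_trial_schedule(version=1, seed=7)
subjects = generate_erp_dataset(
    schedule, default_effect_spec(), NoiseSpec(),
    n_subjects=n_nap + n_wake, seed=3,
    groups=["nap"] * n_nap + ["wake"] * n_wake)

conds, effs, spin_rows = [], [], []
for s in subjects:
    c, e = process_erp_subject(s.recordings, s.events, s.subject, s.group)
    conds.append(c)
    effs.append(e)
    if s.group == "nap":
        rec, hyp, _ = generate_sleep_eeg(SpindleSimSpec(), seed=100 + s.subject)
        _, summary, _ = run_spindle_analysis(rec, hyp)
        summary = summary[summary.kind == "channel"].copy()
        summary.insert(0, "subject", s.subject)
        spin_rows.append(summary)

table = battery.run_battery(pd.concat(conds), pd.concat(effs),
                            pd.concat(spin_rows))
show = table[table.test.str.contains(
    "familiarity_anova\\[early\\]:Familiarity$|"
    "memory_anova\\[middle\\]:Regularity x group|"
    "memory\\[early\\]|spindle")]
pd.set_option("display.width", 120)
print(show[["test", "statistic", "df", "p", "effect_size",
            "alpha", "significant"]].to_string(index=False))
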