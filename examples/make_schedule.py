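"""Build a stimulus schedule and show its balance properties.

The encoding phase presents 16 verb stems in the two regular AXB/CXD frames
four times each; the memory test crosses regularity (regular/irregular) with
stem novelty (old/new), 32 sentences per cell.  Element frequencies and
adjacent-pair transitions are identical in every test cell, so only the
nonadjacent dependency differentiates the conditions.
"""

from nadsleep import generate_trial_schedule

schedule = generate_trial_schedule(version=1, seed=7)

enc = schedule[schedule.phase == "encoding"]
test = schedule[schedule.phase == "test"]
print(f"encoding: {len(enc)} sentences "
      f"({enc.groupby(['half']).size().to_dict()} per half)")
print(f"test:     {len(test)} sentences")
print("\ntest cells (regularity x novelty):")
print(test.groupby(["regularity", "stem_novelty"]).size().to_string())

print("\nfirst-element counts per cell (A vs C, equal by design):")
first = test.assign(first=test.frame.str.split("_").str[0])
print(first.groupby(["regularity", "stem_novelty", "first"])
      .size().unstack().to_string())
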