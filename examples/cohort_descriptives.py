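"""Characterize one drug's report cohort: sex, age bands, outcomes, countries.

The summarizer reproduces the descriptive block of a pharmacovigilance
paper: counts with percentages of the deduplicated primary-suspect cohort,
with unknown demographics kept as explicit categories.
"""

import json

from pvsignal import SyntheticConfig, deduplicate, generate, summarize

cfg = SyntheticConfig(
    seed=3,
    n_reports=20_000,
    drugs={"drugA": 0.1},
    events={"Dry eye": 0.02},
    duplicate_case_rate=0.08,
)
rs = deduplicate(generate(cfg))
s = summarize(rs, cfg.lexicon(), "drugA")

print(f"cohort size (deduplicated reports): {s.n_events}")
for block_name, block in (("sex", s.sex), ("age", s.age), ("serious outcomes", s.outcomes)):
    print(f"\n{block_name}:")
    for k, v in block.items():
        print(f"  {k:18s} {v:6d} ({s.pct(v)}%)")
print(f"\n  serious total      {s.serious_total:6d} ({s.pct(s.serious_total)}%)")
print("\nSex/age/country blocks sum to the cohort size; the serious-outcome")
print("rows can overlap, so their dedicated total counts each report once.")
print("\nmachine-readable form:", json.dumps(s.as_dict())[:80], "...")
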