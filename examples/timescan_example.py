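"""Track a signal's information component as the database grows quarter by quarter.

A constant planted association is streamed over 24 quarters; the cumulative
IC should stabilize while its ±2SD credibility band narrows as reports
accumulate — the signature of a stable signal.
"""

from pvsignal import SyntheticConfig, bandwidth, generate, ic_timescan

cfg = SyntheticConfig(
    seed=7,
    n_reports=30_000,
    drugs={"drugA": 0.08},
    events={"Retinal vasculitis": 0.005},
    planted_signals=[("drugA", "Retinal vasculitis", 15.0)],
    start_quarter="2016Q1",
    end_quarter="2021Q4",
)
rs = generate(cfg)
series = ic_timescan(rs, cfg.lexicon(), "drugA", "Retinal vasculitis")

print("quarter  a_cum    IC    band")
for p, (_, w) in list(zip(series.points, bandwidth(series)))[::4]:
    print(f"{p.quarter}  {p.a_cum:5d}  {p.ic:5.2f}  [{p.band_low:5.2f}, {p.band_high:5.2f}]")

first, last = bandwidth(series)[0], bandwidth(series)[-1]
print(f"\nband width: {first[1]:.2f} bits in {first[0]} -> {last[1]:.2f} bits in {last[0]}")
print("A narrowing band with a steady IC indicates a stable association,")
print("not an artifact of early sparse reporting.")
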