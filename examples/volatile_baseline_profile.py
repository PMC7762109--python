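"""Percent-of-baseline normalization and trend labels for volatile metabolites.

Generates synthetic raw GC-MS peak areas, expresses every later timepoint
as a percentage of the same patient's baseline area, and labels each
compound's week-2 to week-12 trend by cross-patient majority.
"""

from dietomics import (SynthConfig, Timepoint, generate_metabolite_tables,
                       make_meta, normalize_to_baseline, trend_classify)

cfg = SynthConfig(seed=5, n_metabolites=35)
_, volatile, _ = generate_metabolite_tables(cfg)
meta = make_meta(cfg)

profile = normalize_to_baseline(volatile, meta)
week2 = profile.xs("week2", axis=1, level="timepoint")
print("percent of baseline at week 2 (first 5 compounds):")
print(week2.head().round(1).to_string())
print("\n100 means unchanged from that patient's own baseline sample.")

trends = trend_classify(profile, Timepoint.WEEK2, Timepoint.WEEK12)
moving = {m: t for m, t in trends.items() if t != "none"}
print(f"\nweek2 -> week12 majority trends: {len(moving)} of {len(trends)} "
      f"compounds move; e.g. {dict(list(moving.items())[:4])}")
print("A compound is labelled when a strict majority of patients with both")
print("measurements moved the same way.")
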