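"""Group comparison of stool metabolite log2 peak areas.

Loads the bundled reference table (19 metabolites, five patients, baseline
vs week 2 on a strict specific carbohydrate diet), runs the pooled
two-sample t-test per metabolite and prints the result, sorted by p-value.
"""

from dietomics import Timepoint, group_ttest, significant_set
from dietomics.datasets import global_metabolites_baseline_week2
from dietomics.metabolomics import results_frame

matrix, meta = global_metabolites_baseline_week2()
baseline = [m.sample_id for m in meta if m.timepoint is Timepoint.BASELINE]
week2 = [m.sample_id for m in meta if m.timepoint is Timepoint.WEEK2]

results = group_ttest(matrix, baseline, week2)
frame = results_frame(results)
print(frame[["metabolite", "n1", "n2", "p_value", "pattern"]].to_string(index=False))

sig = significant_set(results, alpha=0.05)
print(f"\n{len(sig)} metabolites at p <= 0.05: {', '.join(sig)}")
print("Each row compares five baseline samples against five week-2 samples")
print("(stigmasterol has one missing week-2 value, so n2 = 4 there);")
print("'Up' means the week-2 mean log2 area exceeds the baseline mean.")
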