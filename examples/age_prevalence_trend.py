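"""CH prevalence by diagnostic age group.

Feeds the published per-age-group carrier counts through the trend
operation and prints the percentage table and Pearson correlation
between prevalence and age-group index; the near-unit r is the
age-dependence signature of clonal hematopoiesis.
"""

from chtriage import age_trend_from_counts

carriers = [179, 512, 1237, 1925, 1025, 217, 5]
totals = [684, 1685, 3207, 4015, 1795, 332, 7]

table, r = age_trend_from_counts(carriers, totals)
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nPearson r (prevalence vs age-group index) = {r:.3f}")
print("Prevalence climbs from ~26% below 40 to ~71% above 90: CH carrier")
print("probability rises almost linearly across these age groups.")
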