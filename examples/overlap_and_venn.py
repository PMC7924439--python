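"""Measure how much three resources' external-identifier sets overlap.

Counts distinct (scheme, value) pairs — never table rows — restricted to
the four audit schemes (NCBI, GBIF, IF, WoRMS), reports the pairwise
overlap in both directions, and decomposes the three sets into the seven
exclusive Venn regions.
"""

from taxograph import example_fixtures, overlap_metrics, scheme_counts, venn_partition

fx = example_fixtures()

report = overlap_metrics(fx["wd"], fx["ott"])
print(f"{report.resource_a}: {report.count_a} audit-scheme IDs; "
      f"{report.resource_b}: {report.count_b}; shared: {report.shared}")
print(f"fraction of {report.resource_a} covered by {report.resource_b}: "
      f"{100 * report.fraction_a:.1f}%")

part = venn_partition(fx["wd"], fx["ott"], fx["globi"])
print("\nVenn regions (exclusive, sum to the union):")
for region, count in part.as_dict().items():
    print(f"  {region:>16}: {count}")
print(f"  union size: {part.union_size}")

counts = scheme_counts([fx["ott"], fx["wd"], fx["globi"]], reference=fx["ott"])
print("\nper-scheme distinct-ID counts (% of the OTT reference):")
print(counts.to_text())
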