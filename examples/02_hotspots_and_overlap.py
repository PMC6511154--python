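"""Label breakpoint hotspots, compare hotspot sets, and overlap with regions.

Hotspots are the top p% of windows by breakpoint density. This example
labels two cancers at the same threshold, measures how similar their
hotspot sets are (Jaccard), prunes under-powered labelings, and reports
what share of hotspot windows fall in gene-associated regions.
"""

import io

import svhotspot as sv

fx = sv.end_to_end_fixture(sv.SimulationConfig(seed=2))
records = sv.filter_by_range(sv.impute_missing_ranges(
    sv.read_breakpoint_table(io.StringIO(fx["table"].to_csv(sep="\t", index=False)))))
ends = sv.explode_to_ends(records)
windows = fx["windows"]

labelings = []
for cancer, grp in ends.groupby("cancer_type"):
    profile = sv.breakpoint_density(grp, windows, cancer_type=cancer)
    for percent in (20.0, 30.0):  # desk-scale grid: 60 windows total
        labelings.append(sv.label_hotspots(profile, percent))

kept, dropped = sv.prune_and_dedupe(labelings, min_positives=10)
print(f"labelings: {len(labelings)} built, {len(kept)} kept "
      f"({len(dropped)} pruned as under-powered or duplicate)")

a, b = kept[0], kept[1]
print(f"{a.cancer_type} @{a.labeling_percent}%: {a.n_positives} hotspot windows")
print(f"{b.cancer_type} @{b.labeling_percent}%: {b.n_positives} hotspot windows")
print(f"Jaccard similarity of the two hotspot sets: {sv.jaccard(a, b):.3f}")
print("(1 = identical window sets, 0 = disjoint)")

regions = sv.RegionSet(fx["regions"])
stats = sv.region_overlap_stats(a, regions)
for row in stats.itertuples():
    print(f"hotspots overlapping a {row.category}: {row.percent:.0f}% "
          f"({row.n_overlap}/{row.n})")
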