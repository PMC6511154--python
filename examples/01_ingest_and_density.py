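"""Ingest an ICGC-style breakpoint table and build density profiles.

Generates a desk-scale synthetic input set, applies the positional-
uncertainty filters (impute missing ranges as 0, drop ranges > 10 bp),
explodes records into breakpoint-end intervals, and bins them into
10 kb windows, ending with the incidence-weighted general cancer profile.
"""

import io

import svhotspot as sv

fx = sv.end_to_end_fixture(sv.SimulationConfig(seed=1), out_dir="scratch/example_inputs")

report = sv.IngestReport()
records = sv.read_breakpoint_table(
    io.StringIO(fx["table"].to_csv(sep="\t", index=False)), report=report)
records = sv.filter_by_range(sv.impute_missing_ranges(records), report=report)
ends = sv.explode_to_ends(records, report=report)

print(f"rows parsed:            {report.n_parsed}")
print(f"excluded by range > 10: {report.n_range_excluded}")
print(f"breakpoint ends:        {len(ends)}  (2 per kept record)")

# ends per bp, the chromosome-level instability ranking
counts = sv.normalized_chrom_counts(ends, fx["windows"].chrom_lengths)
for chrom, value in sorted(counts.items(), key=lambda kv: -kv[1]):
    print(f"chromosome {chrom}: {value * 1e3:.3f} ends per kb")

windows = fx["windows"]
profiles = [sv.breakpoint_density(grp, windows, cancer_type=cancer)
            for cancer, grp in ends.groupby("cancer_type")]
weights = sv.load_incidence_weights("scratch/example_inputs/incidence.tsv",
                                    [p.cancer_type for p in profiles])
general = sv.general_profile(profiles, weights)
print(f"\ngeneral profile over {windows.n} windows of {windows.size} bp; "
      f"densities sum to {general.densities.sum():.4f}")
print("(a profile is the probability that a breakpoint falls in each window;")
print(" the general profile mixes cancers by incidence, total-probability style)")
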