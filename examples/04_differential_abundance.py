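"""Case/control differential abundance with longitudinal validation.

Simulates the full emulated study design at the count level (20 MS vs 40 HC
cross-sectional samples, 18 control subjects x 9 timepoints), filters to
species-level units at >= 0.1% mean relative abundance in a group, runs
Welch's t-test with Benjamini-Hochberg correction, and validates each
significant unit's log10(MS/HC) fold-change sign against every longitudinal
timepoint.
"""

import numpy as np

from refotu import (AbundanceTable, SimConfig, abundance_filter,
                    differential_abundance, generate_count_tables,
                    generate_reference_db, longitudinal_validation)

cfg = SimConfig(seed=3)
_records, truth = generate_reference_db(cfg)
counts, sheet = generate_count_tables(cfg, truth)
sheet = sheet.set_index("sample_id")
groups = sheet["group"]
cross = sheet.index[sheet.timepoint == 0]
longi = sheet.index[sheet.timepoint > 0]

table = AbundanceTable(counts[cross], groups[cross], depth=3000)
filtered, removed = abundance_filter(table)
result = differential_abundance(filtered)

planted = set(truth.planted)
sig = result.index[result["significant"]]
print(f"clusters tested      : {filtered.counts.shape[0]} "
      f"(of {counts.shape[0]}; {sum(removed.values())} below 0.1%)")
print(f"significant (p<0.05) : {len(sig)}")
print(f"planted recovered    : {len(planted & set(sig))} / {len(planted)}")
print("\nstrongest shifts (log10 MS/HC, Welch p, BH q):")
for cid in result.index[:3].tolist() + result.index[-3:].tolist():
    row = result.loc[cid]
    mark = "*planted*" if cid in planted else ""
    print(f"  {cid}: {row.log10_fc:+.2f}  p={row.p:.2e}  q={row.q:.2e} {mark}")

detected = sorted(planted & set(sig))
case_cols = [s for s in cross if groups[s] == "MS"]
checks = longitudinal_validation(
    table.counts.loc[detected, case_cols].mean(axis=1),
    result.loc[detected, "log10_fc"],
    counts[longi], sheet.loc[longi, "timepoint"], depth=3000)
consistency = float(np.mean([c.sign_consistency for c in checks]))
print(f"\nlongitudinal sign consistency of detected planted effects: "
      f"{consistency:.2f}")
print("A value of 1.0 means every significant species keeps the same "
      "direction of change against the control series at all 9 timepoints - "
      "the planted dysbiosis is persistent, not a sampling artefact.")
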