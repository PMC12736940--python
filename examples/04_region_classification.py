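"""CGI x NMI classification and CpG-count stratification.

Classifies a toy genome into the four region classes (A = CpG island
and non-methylated island, B = NMI only, C = CGI only, D = neither),
takes the central 147-bp window of each class-A region, and groups
random sequences by CpG count into the standard strata.
"""

import nucwrap as nw
from nucwrap.regions import (GenomicRegion, classify_regions,
                             central_windows, group_by_cpg_count,
                             ensemble_stats)

cgi = [GenomicRegion("chr1", 1000, 2400), GenomicRegion("chr1", 5000, 5400)]
nmi = [GenomicRegion("chr1", 1800, 3000), GenomicRegion("chr1", 7000, 7600)]
universe = [GenomicRegion("chr1", 0, 10_000)]

classes = classify_regions(cgi, nmi, universe)
for label, regs in classes.items():
    print(f"class {label}: {[(r.start, r.end) for r in regs]}")

windows = central_windows(classes["A"])
print(f"\ncentral 147-bp windows of class A: "
      f"{[(w.start, w.end) for w in windows]}")

seqs = [nw.random_sequence_with_cpg_range(147, 0, 40, s) for s in range(30)]
groups = group_by_cpg_count(seqs)
print("\nsequences per CpG stratum:",
      {str(k): len(v) for k, v in groups.items()})

counts = [nw.count_cpg(s) for s in seqs]
strata = [next((f"[{lo},{hi}]" for (lo, hi) in ((0, 4), (5, 14), (15, 24), (25, 34))
                if lo <= c <= hi), ">34") for c in counts]
print("\nCpG counts per stratum (mean, sd):")
print(ensemble_stats(counts, strata).to_string(index=False))
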