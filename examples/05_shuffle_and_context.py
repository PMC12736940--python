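"""Dinucleotide-preserving shuffles and CpG flanking context.

Shuffles a CpG-rich fragment with the Eulerian-path dinucleotide
shuffle (exact count preservation) and tallies the tetramer flanking
context of its CpG steps before and after shuffling.
"""

import numpy as np

import nucwrap as nw
from nucwrap.seqops import (altschul_erickson_shuffle, dinucleotide_counts,
                            tetramer_context_counts)

seq = nw.random_sequence_with_cpg_range(147, 15, 24, rng_seed=2)
shuffled = altschul_erickson_shuffle(seq, 5)

c1, c2 = dinucleotide_counts(seq), dinucleotide_counts(shuffled)
print("dinucleotide counts preserved exactly:", c1 == c2)
print("CpG steps:", nw.count_cpg(seq), "->", nw.count_cpg(shuffled))

for label, s in (("original", seq), ("shuffled", shuffled)):
    ctx = tetramer_context_counts([s])
    gc = (ctx["upstream"][1] + ctx["upstream"][2]).sum() / (4 * ctx["n_steps"])
    print(f"{label}: {ctx['n_steps']} CpG steps tallied, "
          f"{ctx['n_skipped']} too close to an end; "
          f"upstream C/G fraction {gc:.2f}")
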