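"""Wrapping energy of one 147-bp sequence.

Builds a synthetic parameter set and the ideal-superhelix constraint
geometry (28 histone-contact phosphates), then minimises the elastic
energy of a random 147-bp fragment subject to those contacts.  The
wrapping energy is the elastic cost (kT) of deforming the fragment from
its straight ground state into the nucleosomal configuration; ln rho is
the Gaussian log density at that configuration (larger = more likely to
be reached by thermal fluctuation).
"""

import numpy as np

import nucwrap as nw

params = nw.synthetic_parameter_set(seed=1)
constraints = nw.ideal_superhelix_constraints()
seq = nw.random_sequence_with_cpg_range(147, 5, 14, rng_seed=11)
print(f"sequence: {seq.bases[:40]}... ({nw.count_cpg(seq)} CpG steps)")

result = nw.minimize_wrap(seq, params, constraints)
print(f"wrapping energy U(w_opt) = {result.wrap_energy:8.2f} kT")
print(f"penalty sum at optimum   = {result.penalty_value:8.2f} kT")
print(f"ln rho(w_opt)            = {result.log_density:8.2f}")
print(f"max contact residual     = {result.residuals.max():8.2f} A")
print(f"converged: {result.converged} in {result.iterations} Newton steps")

ok, dmin, pair = nw.check_self_overlap(result)
print(f"two superhelical turns stay {dmin:.1f} A apart (clash check: "
      f"{'pass' if ok else 'FAIL'})")
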