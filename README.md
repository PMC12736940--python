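# nucwrap

Sequence-dependent nucleosome wrapping energies and nucleosomal
configuration probability densities from a coarse-grained
rigid-base-plus-phosphate model of double-stranded DNA.

## The problem

A nucleosome wraps 147 bp of DNA around the histone core; how easily a
given sequence does this depends on its mechanics. CpG islands — the
CpG-rich regions at most vertebrate promoters — and the epigenetic
modification state of their CpG steps (5-methyl or 5-hydroxymethyl
cytosine on both strands) change both the stiffness and the relaxed
shape of the double helix. `nucwrap` quantifies these effects with two
scalar read-outs per 147-bp fragment: the elastic energy needed to
reach a nucleosomal configuration, and the log probability density of
that configuration under the fragment's thermal ensemble. The package
is aimed at structural bioinformaticians and epigenomics groups who
want mechanics-based nucleosome propensity scores for large sequence
ensembles.

## The model

A linear fragment of *n* base pairs is a chain of rigid bases and
rigid phosphate groups with internal coordinates
`w ∈ R^N`, `N = 24 n − 18` (6 intra base-pair coordinates per bp and,
per junction, 6 inter base-pair coordinates plus 6 for each strand's
phosphate; rotations are scaled Cayley vectors). A parameter set `P`
assigns every dimer step — 16 unmodified steps plus the symmetrically
methylated `MpN` and hydroxymethylated `HpK` CpG steps — a symmetric
30×30 stiffness block and a weighted-mean block. Overlapping assembly
gives a banded SPD stiffness `K(S,P)` and ground state `μ(S,P)` with

```
U(w) = ½ (w − μ) · K (w − μ)          [kT]
ρ(w) = exp(−U(w)) / Z,   Z = (2π)^{N/2} det(K)^{−1/2}
ln ρ(w) = −U(w) + ½ ln det K − (N/2) ln 2π = −U(w) − H + N/2
```

where `H` is the Gaussian entropy. The nucleosomal configuration is

```
w_opt = argmin_w  U(w) + Σ_{i=1..28} c_i ‖p_i(w) − p̄_i‖²
```

with `p_i(w)` the Cartesian positions of the 28 phosphates closest to
the histone core, `p̄_i` reference positions (ensemble averages of
aligned nucleosome structures, or an ideal superhelix), and `c_i`
elastic penalty coefficients in kT/Å². The reported wrapping energy is
`U(w_opt)`; the penalty sum is reported separately. Minimisation is a
damped Newton iteration with exact chain-rule gradients through the
frame reconstruction; see `docs/methods.md` for the numerics.

Around this core sit the ensemble layers: CpG counting and symmetric
modification annotation, random sequences with prescribed CpG-count
ranges, the Altschul–Erickson dinucleotide shuffle, tetramer flanking
context counts, four-way CpG-island × non-methylated-island region
classification, central-147-bp windows, 1-bp sliding-window scans and
occupancy-track grouping. A fixtures module generates every input
synthetically (parameter sets, superhelix constraint geometries,
jittered structure ensembles), so the whole pipeline runs with no
external data.

## Worked example

`examples/02_methylation_effect.py` wraps one CpG-rich 147-bp fragment
(15 CpG steps) in three modification states, under a seeded synthetic
parameter set and the ideal-superhelix contact geometry:

```
           state   U(w_opt) kT      ln rho
      unmodified        354.24      195.30
      methylated        362.50      220.56
hydroxymethylated        359.36      215.81
```

The sequence is identical in all rows, so the differences isolate the
mechanical effect of the epigenetic mark: with this parameter set,
modification makes wrapping cost more energy (higher `U`) while the
stiffening narrows the thermal ensemble enough to raise the density at
the optimum (higher `ln ρ`). Absolute values depend on the synthetic
parameter set and penalty coefficients; with a fitted parameter set the
same code yields physical energies. The other scripts in `examples/`
demonstrate single-sequence wrapping diagnostics, constraint derivation
from structure ensembles, region classification and dinucleotide
shuffling — each prints what it computes and what the numbers mean.

A thin command-line interface exposes the same workflows
(`nucwrap wrap | scan | ensemble | classify-regions | shuffle |
make-fixtures`); `nucwrap make-fixtures --out fx` writes a complete
synthetic input bundle to experiment with.

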