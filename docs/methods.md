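# Methods

## Coordinates and conventions

A fragment of `n` base pairs has internal coordinates
`w = (y_1, η_1, y_2, η_2, …, η_{n−1}, y_n)`, `N = 24 n − 18`:

* `y_a ∈ R^6` — intra base-pair coordinates of bp `a`: rotation (3) and
  translation (3) from the Crick base frame to the Watson base frame.
* `η_j ∈ R^18` — junction `j` between bp `j` and `j+1`, ordered
  (Crick phosphate 6, inter base-pair 6, Watson phosphate 6).

Rotations are scaled Cayley (Gibbs) vectors `c = s·tan(θ/2)·axis` with
scale `s` declared in the parameter-set metadata (default 10, which
puts helical twists near 3). The Cayley map is rational, so the
embedding into absolute frames is exactly invertible, derivatives have
closed forms, and complex-step differentiation is exact; its only
restriction, rotations below 180° per junction, is never active for
DNA-like configurations. Translations are in Ångström; energies in kT.

Embedding conventions (all enforced by the round-trip tests):

* successive base-pair frames compose through the **mid-frame**: the
  inter translation is expressed in the half-rotated frame;
* the intra rotation is split symmetrically between the two base
  frames, the intra translation symmetrically between their origins;
* each phosphate is positioned and oriented relative to the 3′-side
  base frame on its own strand (Watson phosphate of junction `j` →
  Watson base of bp `j+1`; Crick phosphate → Crick base of bp `j`).
  The 3′ choice makes the convention invariant under strand relabeling.

### Strand-swap involution

Relabelling the strands (reverse complement) flips every frame by a
half turn about its x-axis and reverses the chain. Deriving the induced
coordinate map from the conventions above gives per-6-block signs
`(−1, 1, 1, −1, 1, 1)` for intra and inter blocks (relative coordinates
between objects that swap roles pick up an inversion) and
`(1, −1, −1, 1, −1, −1)` for phosphate blocks (phosphates stay attached
to their base and are only conjugated by the flip), with Crick and
Watson phosphate sub-blocks exchanged. Parameter sets must satisfy the
corresponding 30×30 block relation between each step and its
complement; this is validated at load time, and it implies
`μ(RC(S)) = E μ(S)` and `K(RC(S)) = E K(S) Eᵀ` exactly for the
assembled model. A practical consequence worth noting: the phosphate
sign pattern is what places the two backbones on opposite sides of the
base pair, so complement consistency and physical geometry are the same
constraint.

## Model assembly

Per-step 30×30 stiffness blocks are added with a 24-coordinate stride
(6-dimensional overlap on the shared intra block), plus optional 6×6
end corrections. The result is banded with half-bandwidth 29. The
ground state solves `K μ = σ` by banded Cholesky; `ln det K` is twice
the log-sum of Cholesky diagonals; no inverse or dense factor is ever
formed (a dense determinant appears only as a test oracle at `N ≤ 60`).
From these, `ln ρ(w) = −U(w) + ½ ln det K − (N/2) ln 2π`, the entropy
`H = (N/2)(1 + ln 2π) − ½ ln det K`, and the identity
`ln ρ = −U − H + N/2` holds to ~1e−13 (asserted at 1e−9).

## Wrapping objective and minimisation

Objective: `U(w) + Σ c_i ‖p_i(w) − p̄_i‖²` over the 28 histone-contact
phosphates (other counts allowed for toys). Gradients are exact chain
rules through the frame reconstruction: for each constrained phosphate
the Jacobian rows over upstream inter coordinates come from
transporting the lever arm `q = R_{j+1}ᵀ(p − o_{j+1})` through the
per-junction Cayley derivative tensors, plus local intra and phosphate
translation terms. The penalty Hessian uses the Gauss–Newton
approximation by default (PSD, robust far from the optimum); an exact
Hessian is available for small systems via complex-step
differentiation of the analytic gradient (exact to machine precision
because every map is rational), and is validated against finite
differences.

The minimiser is a damped line-search Newton in the trust-region-Newton
family: the Gauss–Newton Hessian is banded `K` plus a rank-`3k` update,
so Newton directions are computed exactly with a banded Cholesky of
`K + λI` and the Woodbury identity (cost ~`O(N·bw²)` per iteration),
globalised by Armijo backtracking with Levenberg damping `λ` on
rejection. Accepted steps are monotone in the objective. Convergence:
gradient infinity-norm ≤ 1e−6 kT/unit (default, configurable), max 500
iterations; non-convergence is flagged on the result, never raised.
A 147-bp wrap with 28 contacts converges in a few hundred iterations
(~8 s single-core); agreement with a generic finite-difference BFGS
oracle on small systems is ~1e−13 kT (asserted at 1e−6).

The mixed absolute/internal coordinate parameterisation used elsewhere
for this problem is treated as an implementation detail: the optimum is
defined by stationarity of the same objective, and both routes must and
do agree on toys, so we keep the single internal-coordinate layout.

**Initial configuration.** The shipped default bends the ground state
onto an ideal superhelix least-squares fitted to the constraint
references: axis from the smallest-variance principal direction,
winding rate and pitch from linear fits of unwrapped angle and height
against junction index. Because phosphates sit ~9 Å off the helical
axis, the axis-radius offset and the helical spin phase are then chosen
by a coarse grid search (9 radii × 12 phases) minimising the misfit of
the constrained phosphates; intra and phosphate coordinates stay at
ground state. Averaged experimental configurations can be supplied as
explicit starting vectors instead.

**Penalty coefficients.** One global default, 10 kT/Å², calibrated on
the synthetic superhelix fixture so contact residuals settle around
0.5–1.5 Å — the spread scale of phosphate clusters in aligned
nucleosome structures — without bringing the two DNA turns closer than
phosphate contact distance (checked by `check_self_overlap`, default
threshold 4 Å between phosphates more than 40 junctions apart; both
numbers configurable).

## Constraint derivation from structure ensembles

Aligned per-junction phosphate tracks are profiled by mean radial
distance to the nucleosome axis; strict local minima (with a 1e−8
numerical tolerance) are clustered per helical turn (gap = half the
period hint, default 10.2) and the smallest-radius member per cluster
is the bound index; reference positions are ensemble means at those
indices. The axis defaults to the smallest-variance principal direction
of the pooled cloud but should be supplied from the alignment when
known — for a partial (1.65-turn) superhelix the principal-axis
estimate is biased by the uneven angular coverage.

## Synthetic data

* **Parameter sets** — random SPD blocks (diagonal ~5 kT per squared
  scaled-Cayley unit for rotations, ~10 kT/Å² for translations, bounded
  random symmetric wobble), symmetrised under the complement involution,
  with a straight B-DNA-like ground state (twist 34.3°, rise 3.4 Å,
  phosphates ~9 Å off-axis on opposite sides). `MpN`/`HpK` blocks are
  stiffened (×1.20 / ×1.15) roll-up/twist-down variants of the CG
  block. These are structurally valid stand-ins, not fits: magnitudes
  of wrapping energies under them are internally consistent but not
  physical, which is why ensemble comparisons in tests are qualitative
  (modified vs unmodified) rather than numeric.
* **Constraint geometry** — 28 points exactly on an ideal superhelix
  (radius 41.9 Å, pitch 25.9 Å, 1.65 left-handed turns, contacts every
  ~10.2 junctions, strands half a turn apart): the textbook nucleosome
  numbers, used as fixture defaults only.
* **Structure ensembles** — superhelical phosphate tracks with a
  cosine radial modulation of amplitude 3 Å and integer period 10
  (first minimum at junction 6, so both strands plant exactly 14
  on-grid minima over 146 junctions and recovery under noise is well
  posed), plus isotropic Gaussian jitter.

What the synthetic conditions do **not** emulate: real sequence-step
stiffness anisotropies and couplings, sequence-dependent phosphate
geometry, experimental alignment error, and the length heterogeneity of
deposited nucleosome structures. Passing tests therefore demonstrate
correctness of the machinery (identities, derivatives, optima,
recovery), not predictive accuracy on genomic data — the latter needs a
fitted parameter set and a constraint file derived from experimental
structures, both of which the loaders accept.

## Interval layer

BED semantics throughout (0-based, half-open). Four-way classification:
A = CGI∩NMI, B = NMI∖CGI, C = CGI∖NMI, D = universe minus the union,
computed with pyranges after per-chromosome merging and verified
against per-bp brute force. Central windows use
`start + floor((len − width)/2)`; regions shorter than the window are
skipped with a logged warning. CpG strata are the inclusive bins
[0,4], [5,14], [15,24], [25,34] with an explicit overflow bucket.
Window-to-region membership for scan summaries uses the window's
central bp by default (full containment available) — the choice is a
convention, both are implemented. Windows containing non-A/C/G/T
letters are skipped and counted. Track attachment averages per-bp
scores over each item, flagging items with less than half their span
covered; for region-level methylation runs, classes C and D receive
`apply_symmetric_modification(…, "methyl")` when honouring the NMI
definition, and all classes support both modified and unmodified runs.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on synthetic
inputs at desk scale: 100-model identity sweeps, a 1e6-sample
Monte-Carlo normalisation of a 6-dimensional toy, 8–15-bp minimiser/
oracle comparisons, 1000 shuffled 147-mers, 100-structure ensembles,
and a handful of full 147-bp wraps (4 sequences × 3 modification
states in the acceptance script). These sizes keep a complete run in a
few minutes single-core while exercising every code path; all counts
are parameters, so larger studies only change arguments.

## Known limitations

* Gauss–Newton convergence is linear once residuals dominate; heavily
  over-constrained toys may report the (tiny) final gradient norm
  above tolerance rather than iterate further.
* The Cayley encoding excludes 180° junction rotations — irrelevant for
  DNA but a hard boundary for adversarial inputs.
* No steric terms in the objective: self-overlap is diagnosed after the
  fact, not prevented during minimisation.
* End base pairs are unrestrained; partial unwrapping of the outermost
  ~5 bp is expected behaviour, not corrected.
* Hemi-methylation, ambiguity codes and RNA are out of scope (the
  parameter alphabet has no such steps).
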