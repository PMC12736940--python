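"""Synthetic inputs: toy parameter sets, superhelical constraint
geometries and jittered structure ensembles.

These generators make every stage of the pipeline runnable and testable
without any external data.  The parameter sets are structurally valid
(symmetric, positive definite, complement-consistent, B-DNA-like ground
state) but are not fits to molecular dynamics data; the superhelix
defaults (radius 41.9 A, pitch 25.9 A, 1.65 left-handed turns, ~10.2
junctions between consecutive histone contacts on a strand) are the
textbook nucleosome geometry, used here purely as fixture defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import StructureEnsemble
from .model import (
    ParameterSet, complement_label, block_involution, S_PH, _DEFAULT_META,
)
from .wrap import ConstraintSet

__all__ = [
    "SuperhelixSpec",
    "synthetic_parameter_set",
    "ideal_superhelix_constraints",
    "synthetic_structure_ensemble",
]


@dataclass(frozen=True)
class SuperhelixSpec:
    """Ideal superhelix stand-in for the averaged nucleosome geometry."""

    radius: float = 41.9  # A
    pitch: float = 25.9  # A per superhelical turn
    turns: float = 1.65
    bp_per_turn: float = 10.2  # junctions between same-strand contacts
    handedness: str = "left"

    def __post_init__(self):
        if self.radius <= 0 or self.bp_per_turn <= 0:
            raise ValueError("radius and bp_per_turn must be positive")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")

    def point(self, phi):
        """Point(s) on the superhelix at winding angle(s) phi (radians)."""
        phi = np.asarray(phi, dtype=float)
        s = -1.0 if self.handedness == "left" else 1.0
        return np.stack(
            [self.radius * np.cos(phi), s * self.radius * np.sin(phi),
             -self.pitch * phi / (2.0 * np.pi)], axis=-1)

    def junction_angle(self, j, n_bp: int = 147):
        """Winding angle of junction j (1-based, at the bp midpoint)."""
        j = np.asarray(j, dtype=float)
        dphi = 2.0 * np.pi * self.turns / (n_bp - 1)
        return (j + 0.5 - (n_bp + 1) / 2.0) * dphi


# ---------------------------------------------------------------------------
# Parameter sets


def _spd_block(rng, diag, wobble=0.12):
    d = np.sqrt(diag)
    W = rng.normal(0.0, 1.0, (30, 30))
    W = 0.5 * (W + W.T)
    # bound the spectral radius so I + wobble*W stays well conditioned
    W *= wobble / max(1e-9, np.linalg.norm(W, 2))
    A = np.eye(30) + W
    return (A * d).T * d  # diag(d) A diag(d)


def synthetic_parameter_set(seed: int = 0, block_scale: float = 1.0,
                            scale: float = 10.0) -> ParameterSet:
    """Random complement-consistent SPD parameter set over all 18 steps.

    Stiffness blocks are diagonally dominant random SPD matrices with
    rotation stiffnesses ~5 kT per squared scaled-Cayley unit and
    translation stiffnesses ~10 kT/A^2; ground-state blocks encode a
    straight B-DNA-like helix (twist ~34.3 deg, rise 3.4 A, phosphates
    ~9 A off axis).  The methylated (MN) and hydroxymethylated (HK)
    blocks are stiffened, ground-state-shifted variants of the CG block.
    """
    rng = np.random.default_rng(seed)
    P = block_involution()

    rot_d, tr_d = 5.0, 10.0
    base_diag = np.concatenate([
        [rot_d] * 3, [tr_d] * 3,        # intra a
        [rot_d] * 3, [tr_d] * 3,        # crick phosphate
        [rot_d] * 3, [tr_d] * 3,        # inter
        [rot_d] * 3, [tr_d] * 3,        # watson phosphate
        [rot_d] * 3, [tr_d] * 3,        # intra a+1
    ])

    twist = scale * np.tan(np.deg2rad(34.3) / 2.0)
    intra_mu = np.zeros(6)
    inter_mu = np.array([0.0, 0.0, twist, 0.0, 0.0, 3.4])
    wph_mu = np.array([0.0, 0.0, 0.0, 1.8, 8.7, -2.0])
    # Crick phosphate mean: image of the Watson one under the strand swap
    # (phosphate sign pattern), which puts the two backbones on opposite
    # sides of the base pair as in B-DNA
    cph_mu = np.diag(S_PH) * wph_mu
    mu_template = np.concatenate([intra_mu, cph_mu, inter_mu, wph_mu, intra_mu])

    def make_block(r):
        K = _spd_block(r, base_diag * (block_scale * r.uniform(0.85, 1.15)))
        mu = mu_template + r.normal(0.0, 0.05, 30)
        return K, mu

    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    done = set()
    for label in [a + b for a in "ACGT" for b in "ACGT"]:
        if label in done:
            continue
        comp = complement_label(label)
        K, mu = make_block(rng)
        if comp == label:
            K = 0.5 * (K + P @ K @ P.T)
            mu = 0.5 * (mu + P @ mu)
            blocks[label] = (K, K @ mu)
        else:
            blocks[label] = (K, K @ mu)
            blocks[comp] = (P @ K @ P.T, P @ (K @ mu))
        done.update({label, comp})

    # modified CpG steps: stiffer, with a roll-up / twist-down mean shift
    K_cg, s_cg = blocks["CG"]
    mu_cg = np.linalg.solve(K_cg, s_cg)
    for label, stiffen, droll, dtwist in (("MN", 1.20, 0.35, -0.30),
                                          ("HK", 1.15, 0.30, -0.25)):
        K = stiffen * K_cg
        mu = mu_cg.copy()
        mu[13] += droll  # inter roll  (junction offset 6 + rot index 1)
        mu[14] += dtwist  # inter twist
        mu = 0.5 * (mu + P @ mu)
        K = 0.5 * (K + P @ K @ P.T)
        blocks[label] = (K, K @ mu)

    meta = dict(_DEFAULT_META)
    meta["scale"] = scale
    meta["provenance"] = f"synthetic_parameter_set(seed={seed})"
    return ParameterSet(blocks, None, meta)


# ---------------------------------------------------------------------------
# Constraint geometries and structure ensembles


def ideal_superhelix_constraints(
    spec: SuperhelixSpec | None = None,
    n_contacts: int = 28,
    n_bp: int = 147,
    coefficient: float = 10.0,
) -> ConstraintSet:
    """Histone-contact reference points evenly spaced along an ideal
    superhelix, alternating Watson/Crick strands (defaults give two DNA
    turns with 14 contacts per strand)."""
    spec = spec or SuperhelixSpec()
    if n_contacts % 2:
        raise ValueError("n_contacts must be even")
    per_strand = n_contacts // 2
    span = (per_strand - 1) * spec.bp_per_turn
    j0 = ((n_bp - 2) - span) / 2.0 + 1.0
    if j0 < 1:
        raise ValueError("contact spacing infeasible for this sequence length")
    watson_j = np.rint(j0 + np.arange(per_strand) * spec.bp_per_turn).astype(int)
    crick_j = np.rint(j0 + spec.bp_per_turn / 2.0
                      + np.arange(per_strand) * spec.bp_per_turn).astype(int)
    crick_j = np.clip(crick_j, 1, n_bp - 1)
    records = []
    for jw, jc in zip(watson_j, crick_j):
        records.append(("W", int(jw)))
        records.append(("C", int(jc)))
    strands = [s for s, _ in records]
    junctions = [j for _, j in records]
    refs = spec.point(spec.junction_angle(np.array(junctions, dtype=float), n_bp))
    return ConstraintSet(
        strands=strands, junctions=junctions, refs=refs,
        coefficients=np.full(n_contacts, float(coefficient)),
        provenance=f"ideal superhelix r={spec.radius} pitch={spec.pitch} "
                   f"turns={spec.turns}",
    )


def synthetic_structure_ensemble(
    spec: SuperhelixSpec | None = None,
    n_structures: int = 100,
    noise_sd: float = 0.5,
    radial_amplitude: float = 3.0,
    period: float = 10.0,
    first_minimum: float = 6.0,
    n_junctions: int = 146,
    seed: int = 0,
):
    """Jittered phosphate tracks on a superhelix with periodic radial
    modulation (minima = histone-bound positions).

    The default integer modulation period plants the radial minima on
    the junction grid (14 per strand over 146 junctions), so recovery
    is well posed under noise.  Returns ``(StructureEnsemble, truth)``
    where ``truth`` records the planted per-strand radial-minimum
    junction indices (1-based) and the alignment axis.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    spec = spec or SuperhelixSpec()
    rng = np.random.default_rng(seed)
    n_bp = n_junctions + 1

    j = np.arange(1, n_junctions + 1, dtype=float)
    phi = spec.junction_angle(j, n_bp)

    def strand_points(j_min0):
        r = spec.radius - radial_amplitude * np.cos(
            2.0 * np.pi * (j - j_min0) / period)
        s = -1.0 if spec.handedness == "left" else 1.0
        pts = np.stack([r * np.cos(phi), s * r * np.sin(phi),
                        -spec.pitch * phi / (2.0 * np.pi)], axis=-1)
        minima = []
        m = j_min0
        while m <= n_junctions:
            idx = int(np.rint(m))
            if 2 <= idx <= n_junctions - 1:
                minima.append(idx)
            m += period
        return pts, minima

    w_pts, w_minima = strand_points(first_minimum)
    # integer half-period offset keeps the sampled minima strictly away
    # from midpoints between junction indices
    c_pts, c_minima = strand_points(first_minimum + round(period / 2.0))

    watson = w_pts[None] + rng.normal(0.0, noise_sd, (n_structures, n_junctions, 3))
    crick = c_pts[None] + rng.normal(0.0, noise_sd, (n_structures, n_junctions, 3))
    truth = {"watson_minima": w_minima, "crick_minima": c_minima,
             "period": period, "spec": spec,
             "axis": (np.zeros(3), np.array([0.0, 0.0, 1.0]))}
    return StructureEnsemble(watson, crick), truth
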