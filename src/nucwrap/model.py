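"""Sequence-dependent Gaussian model of a linear DNA fragment.

A parameter set supplies, for every dimer step over the extended alphabet
(16 unmodified steps plus the symmetrically methylated ``MN`` and
hydroxymethylated ``HK`` CpG steps), a symmetric 30x30 stiffness block and
a length-30 weighted-mean block spanning (intra_a 6, junction 18,
intra_{a+1} 6).  For an n base-pair sequence the blocks are added with a
24-coordinate overlap, giving a banded symmetric positive-definite
stiffness matrix K (units kT per squared coordinate) of size
N = 24 n - 18 and a weighted-mean vector sigma; the ground state solves
K mu = sigma.  The configuration distribution is the Gaussian

    rho(w) = exp(-U(w)) / Z,     U(w) = (1/2) (w - mu) . K (w - mu)  [kT]

with Z = (2 pi)^{N/2} det(K)^{-1/2}, so that

    ln rho(w) = -U(w) + (1/2) ln det K - (N/2) ln 2 pi
              = -U(w) - H + N/2

where H = (N/2)(1 + ln 2 pi) - (1/2) ln det K is the differential
entropy.  All determinant work goes through a banded Cholesky
factorisation (half-bandwidth 29); no inverse is ever formed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .seqops import ModSequence, step_labels, reverse_complement

__all__ = [
    "ParameterSet",
    "GaussianModel",
    "load_parameter_set",
    "build_model",
    "energy",
    "log_partition",
    "log_density",
    "entropy",
    "involution",
    "block_involution",
    "complement_label",
]

BLOCK_DIM = 30
OVERLAP = 6
HALF_BANDWIDTH = BLOCK_DIM - 1  # 29

_COMP = str.maketrans("ACGT", "TGCA")

#: strand-swap sign patterns, derived from the frame conventions in
#: :mod:`nucwrap.geometry`.  Relabelling the strands flips every frame by
#: a half-turn about its x-axis (F = diag(1,-1,-1)) and reverses the
#: chain.  Relative coordinates between objects that swap roles (intra,
#: inter) pick up an inversion on top of the conjugation by F, giving
#: (-rot1, rot2, rot3, -tr1, tr2, tr3); phosphate coordinates stay with
#: their base (only conjugated by F), giving (rot1, -rot2, -rot3,
#: tr1, -tr2, -tr3).
S_REL = np.diag([-1.0, 1.0, 1.0, -1.0, 1.0, 1.0])
S_PH = np.diag([1.0, -1.0, -1.0, 1.0, -1.0, -1.0])


def complement_label(label: str) -> str:
    """Dimer-step label of the complementary strand (MN/HK self-map)."""
    if label in ("MN", "HK"):
        return label
    return label.translate(_COMP)[::-1]


def block_involution() -> np.ndarray:
    """30x30 involution relating a dimer block to its complement's block.

    Maps (y_a, crick_ph, inter, watson_ph, y_b) to
    (S_REL y_b, S_PH watson_ph, S_REL inter, S_PH crick_ph, S_REL y_a).
    """
    P = np.zeros((BLOCK_DIM, BLOCK_DIM))
    P[0:6, 24:30] = S_REL
    P[6:12, 18:24] = S_PH
    P[12:18, 12:18] = S_REL
    P[18:24, 6:12] = S_PH
    P[24:30, 0:6] = S_REL
    return P


_P30 = block_involution()

_UNMODIFIED_STEPS = [a + b for a in "ACGT" for b in "ACGT"]
STANDARD_STEPS = _UNMODIFIED_STEPS + ["MN", "HK"]

_DEFAULT_META = {
    "ordering": "intra-junction interleaved (y_1, eta_1, ..., eta_{n-1}, y_n)",
    "junction_layout": "crick_phosphate(6), inter(6), watson_phosphate(6)",
    "rotation": "cayley",
    "scale": 10.0,
    "units": "kT, angstrom",
    "phosphate_ref": "3prime",
}


@dataclass
class ParameterSet:
    """Per-dimer-step stiffness and weighted-mean blocks plus conventions.

    ``dimer_blocks`` maps a step label to ``(stiffness (30,30),
    weighted_mean (30,))``.  ``end_blocks`` optionally corrects the first
    and last intra block: ``{"first"|"last": (K6 (6,6), s6 (6,))}``.
    """

    dimer_blocks: dict[str, tuple[np.ndarray, np.ndarray]]
    end_blocks: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    meta: dict = field(default_factory=lambda: dict(_DEFAULT_META))

    def __post_init__(self):
        self.validate()

    @property
    def scale(self) -> float:
        return float(self.meta.get("scale", 10.0))

    def validate(self, tol: float = 1e-8) -> None:
        for label, (K, s) in self.dimer_blocks.items():
            K = np.asarray(K, dtype=float)
            s = np.asarray(s, dtype=float)
            if K.shape != (BLOCK_DIM, BLOCK_DIM) or s.shape != (BLOCK_DIM,):
                raise ValueError(f"step {label!r}: block dimensions must be 30")
            scale = max(1.0, np.abs(K).max())
            if np.abs(K - K.T).max() > tol * scale:
                raise ValueError(f"step {label!r}: stiffness block not symmetric")
        for label in self.dimer_blocks:
            comp = complement_label(label)
            if comp not in self.dimer_blocks:
                continue
            K, s = self.dimer_blocks[label]
            Kc, sc = self.dimer_blocks[comp]
            scale = max(1.0, np.abs(K).max())
            if (np.abs(Kc - _P30 @ K @ _P30.T).max() > 1e-6 * scale
                    or np.abs(sc - _P30 @ s).max() > 1e-6 * max(1.0, np.abs(s).max())):
                raise ValueError(
                    f"steps {label!r}/{comp!r} violate complement consistency")
        if self.end_blocks is not None:
            for key, (K6, s6) in self.end_blocks.items():
                if key not in ("first", "last"):
                    raise ValueError(f"unknown end-block key {key!r}")
                K6 = np.asarray(K6, dtype=float)
                if K6.shape != (6, 6) or np.asarray(s6).shape != (6,):
                    raise ValueError("end blocks must be (6,6) and (6,)")
        if not isinstance(self.meta, dict) or "scale" not in self.meta:
            raise ValueError("meta must be a dict declaring at least 'scale'")

    def save(self, path) -> None:
        """Write a single-file archive: JSON metadata + float64 arrays."""
        arrays = {}
        for label, (K, s) in self.dimer_blocks.items():
            arrays[f"K_{label}"] = np.asarray(K, dtype=np.float64)
            arrays[f"s_{label}"] = np.asarray(s, dtype=np.float64)
        if self.end_blocks:
            for key, (K6, s6) in self.end_blocks.items():
                arrays[f"endK_{key}"] = np.asarray(K6, dtype=np.float64)
                arrays[f"ends_{key}"] = np.asarray(s6, dtype=np.float64)
        arrays["meta_json"] = np.frombuffer(
            json.dumps(self.meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)


def load_parameter_set(path) -> ParameterSet:
    """Load and validate a parameter-set archive written by
    :meth:`ParameterSet.save`."""
    with np.load(path) as data:
        if "meta_json" not in data:
            raise ValueError("parameter archive has no metadata record")
        meta = json.loads(bytes(data["meta_json"]).decode())
        dimer_blocks = {}
        end_blocks = {}
        for name in data.files:
            if name.startswith("K_"):
                label = name[2:]
                if f"s_{label}" not in data.files:
                    raise ValueError(f"step {label!r}: missing weighted-mean block")
                dimer_blocks[label] = (data[name], data[f"s_{label}"])
            elif name.startswith("endK_"):
                key = name[5:]
                end_blocks[key] = (data[name], data[f"ends_{key}"])
    return ParameterSet(dimer_blocks, end_blocks or None, meta)


@dataclass
class GaussianModel:
    """Ground state and banded stiffness of one sequence."""

    seq: ModSequence
    n: int
    N: int
    mu: np.ndarray
    K: sp.csr_matrix
    K_banded: np.ndarray  # upper banded storage for scipy.linalg
    meta: dict

    @property
    def scale(self) -> float:
        return float(self.meta.get("scale", 10.0))

    @cached_property
    def _chol_banded(self) -> np.ndarray:
        try:
            return sla.cholesky_banded(self.K_banded, lower=False)
        except sla.LinAlgError as exc:
            raise ValueError("stiffness matrix is not positive definite") from exc

    @cached_property
    def log_det_K(self) -> float:
        return 2.0 * float(np.sum(np.log(self._chol_banded[-1])))


def _assemble(labels, params: ParameterSet, n: int):
    N = 24 * n - 18
    missing = sorted({lb for lb in labels if lb not in params.dimer_blocks})
    if missing:
        raise ValueError(f"parameter set lacks blocks for steps: {missing}")
    rows, cols, vals = [], [], []
    sigma = np.zeros(N)
    idx_template = np.arange(BLOCK_DIM)
    rr, cc = np.meshgrid(idx_template, idx_template, indexing="ij")
    for j, label in enumerate(labels):
        Kb, sb = params.dimer_blocks[label]
        off = 24 * j
        rows.append((rr + off).ravel())
        cols.append((cc + off).ravel())
        vals.append(np.asarray(Kb, dtype=float).ravel())
        sigma[off : off + BLOCK_DIM] += sb
    if params.end_blocks:
        for key, (K6, s6) in params.end_blocks.items():
            off = 0 if key == "first" else N - 6
            rows.append((rr[:6, :6] + off).ravel())
            cols.append((cc[:6, :6] + off).ravel())
            vals.append(np.asarray(K6, dtype=float).ravel())
            sigma[off : off + 6] += np.asarray(s6, dtype=float)
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    ).tocsr()
    return K, sigma


def _to_banded_upper(K: sp.csr_matrix, bw: int) -> np.ndarray:
    N = K.shape[0]
    ab = np.zeros((bw + 1, N))
    for d in range(bw + 1):
        diag = K.diagonal(d)
        ab[bw - d, d:] = diag
    return ab


def build_model(seq: ModSequence | str, params: ParameterSet) -> GaussianModel:
    """Assemble mu and K for a sequence under a parameter set.

    Modified CpG steps use the ``MN`` (methyl) / ``HK`` (hydroxymethyl)
    blocks.  Raises if the assembled stiffness is not positive definite
    or the parameter set does not cover the sequence's steps.
    """
    if isinstance(seq, str):
        seq = ModSequence(seq)
    n = len(seq.bases)
    if n < 2:
        raise ValueError("need at least 2 base pairs")
    labels = step_labels(seq)
    K, sigma = _assemble(labels, params, n)
    ab = _to_banded_upper(K, HALF_BANDWIDTH)
    try:
        mu = sla.solveh_banded(ab, sigma, lower=False)
    except sla.LinAlgError as exc:
        raise ValueError("assembled stiffness matrix is not positive definite") from exc
    model = GaussianModel(
        seq=seq, n=n, N=24 * n - 18, mu=mu, K=K, K_banded=ab, meta=dict(params.meta)
    )
    return model


def energy(w, model: GaussianModel) -> float:
    """Elastic energy U(w) = 1/2 (w-mu).K(w-mu) in kT."""
    w = np.asarray(w)
    if w.shape != (model.N,):
        raise ValueError(f"configuration must have length {model.N}")
    d = w - model.mu
    return 0.5 * float(d @ (model.K @ d))


def log_partition(model: GaussianModel) -> float:
    """ln Z = (N/2) ln 2 pi - (1/2) ln det K."""
    return 0.5 * model.N * np.log(2.0 * np.pi) - 0.5 * model.log_det_K


def log_density(w, model: GaussianModel) -> float:
    """Gaussian log density ln rho(w) at a configuration."""
    return -energy(w, model) + 0.5 * model.log_det_K - 0.5 * model.N * np.log(2.0 * np.pi)


def entropy(model: GaussianModel) -> float:
    """Differential entropy H = (N/2)(1 + ln 2 pi) - (1/2) ln det K."""
    return 0.5 * model.N * (1.0 + np.log(2.0 * np.pi)) - 0.5 * model.log_det_K


def involution(n: int):
    """Index permutation and signs of the reverse-complement involution E.

    Returns ``(perm, sign)`` such that ``(E w)[i] = sign[i] * w[perm[i]]``
    relates coordinates of a sequence and its reverse complement:
    mu(RC(s)) = E mu(s) and K(RC(s)) = E K(s) E^T for any
    complement-consistent parameter set.
    """
    N = 24 * n - 18
    perm = np.empty(N, dtype=int)
    sign = np.empty(N)
    s_rel = np.diag(S_REL)
    s_ph = np.diag(S_PH)
    for a in range(n):
        src = 24 * (n - 1 - a)
        dst = 24 * a
        perm[dst : dst + 6] = np.arange(src, src + 6)
        sign[dst : dst + 6] = s_rel
    for j in range(n - 1):
        src = 24 * (n - 2 - j) + 6
        dst = 24 * j + 6
        # new crick <- old watson, inter <- inter, new watson <- old crick
        perm[dst : dst + 6] = np.arange(src + 12, src + 18)
        perm[dst + 6 : dst + 12] = np.arange(src + 6, src + 12)
        perm[dst + 12 : dst + 18] = np.arange(src, src + 6)
        sign[dst : dst + 6] = s_ph
        sign[dst + 6 : dst + 12] = s_rel
        sign[dst + 12 : dst + 18] = s_ph
    return perm, sign


def apply_involution(w, n: int):
    perm, sign = involution(n)
    return sign * np.asarray(w)[perm]
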