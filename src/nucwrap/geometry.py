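"""Rigid-body geometry for the coarse-grained DNA chain.

The internal-coordinate vector ``w`` of an ``n`` base-pair fragment has
length ``N = 24 n - 18`` and is laid out as

    w = (y_1, eta_1, y_2, eta_2, ..., eta_{n-1}, y_n)

where each intra block ``y_a`` (6 numbers) holds the rotation (3, scaled
Cayley vector) and translation (3, Angstrom) from the Crick base frame to
the Watson base frame of base pair ``a``, and each junction block
``eta_j`` (18 numbers) holds, in order, the Crick phosphate (6), the
inter base-pair step (6) and the Watson phosphate (6) coordinates of
junction ``j`` (between base pairs ``j`` and ``j+1``).

Rotations are encoded as Cayley (Gibbs) vectors ``c = s * tan(theta/2) *
axis`` with a declared scale ``s`` (default 10, so typical helical twists
are order-one numbers).  All maps here are rational functions of the
coordinates, which keeps them exactly invertible and makes complex-step
differentiation exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidFrame",
    "EmbeddedConfiguration",
    "StructureEnsemble",
    "cayley",
    "cayley_inverse",
    "half_vector",
    "coords_to_frames",
    "frames_to_coords",
    "phosphate_positions",
    "phosphate_position_jacobian",
    "superpose",
    "cylindrical_profile",
    "fit_axis",
    "read_structure_ensemble",
    "write_structure_ensemble",
]

DEFAULT_CAYLEY_SCALE = 10.0

# ---------------------------------------------------------------------------
# Coordinate layout helpers (0-based internally, 1-based in the public API)


def coord_count(n: int) -> int:
    """Number of internal coordinates for an n base-pair fragment."""
    if n < 2:
        raise ValueError("need at least 2 base pairs")
    return 24 * n - 18


def intra_slice(a: int) -> slice:
    """Slice of the intra block of base pair ``a`` (0-based)."""
    return slice(24 * a, 24 * a + 6)


def eta_offset(j: int) -> int:
    """Start offset of junction block ``j`` (0-based)."""
    return 24 * j + 6


# within a junction block
CRICK_PH_ROT = slice(0, 3)
CRICK_PH_TRANS = slice(3, 6)
INTER_ROT = slice(6, 9)
INTER_TRANS = slice(9, 12)
WATSON_PH_ROT = slice(12, 15)
WATSON_PH_TRANS = slice(15, 18)


# ---------------------------------------------------------------------------
# Cayley rotations


def _skew(c):
    z = c[0] * 0.0
    return np.array(
        [[z, -c[2], c[1]], [c[2], z, -c[0]], [-c[1], c[0], z]]
    )


def cayley(c):
    """Rotation matrix of an (unscaled) Cayley vector c = tan(theta/2)*axis."""
    c = np.asarray(c)
    cc = c @ c
    a = 1.0 + cc
    M = (1.0 - cc) * np.eye(3) + 2.0 * np.outer(c, c) + 2.0 * _skew(c)
    return M / a


def cayley_inverse(R):
    """Unscaled Cayley vector of a rotation matrix (theta < pi)."""
    t = 1.0 + R[0, 0] + R[1, 1] + R[2, 2]
    if abs(t) < 1e-12:
        raise ValueError("rotation angle at or beyond pi: Cayley encoding out of range")
    return np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / t


def half_vector(c):
    """Cayley vector of the half rotation: cay(half_vector(c))^2 = cay(c)."""
    c = np.asarray(c)
    g = np.sqrt(1.0 + c @ c)
    return c / (1.0 + g)


def d_cayley(c):
    """Tensor T[k] = d cay(c) / d c_k, shape (3, 3, 3)."""
    c = np.asarray(c)
    cc = c @ c
    a = 1.0 + cc
    M = (1.0 - cc) * np.eye(3) + 2.0 * np.outer(c, c) + 2.0 * _skew(c)
    eye = np.eye(3)
    T = np.empty((3, 3, 3), dtype=np.result_type(c, float))
    for k in range(3):
        e = eye[k]
        dM = -2.0 * c[k] * eye + 2.0 * (np.outer(e, c) + np.outer(c, e)) + 2.0 * _skew(e)
        T[k] = dM / a - M * (2.0 * c[k] / a**2)
    return T


def d_half_vector(c):
    """Jacobian d half_vector(c) / d c, shape (3, 3)."""
    c = np.asarray(c)
    g = np.sqrt(1.0 + c @ c)
    return np.eye(3) / (1.0 + g) - np.outer(c, c) / (g * (1.0 + g) ** 2)


# Batched versions of the rotation primitives (vectorised over the
# leading axis; complex-safe for complex-step differentiation).


def cayley_many(C):
    """Rotation matrices of Cayley vectors, shape (m, 3) -> (m, 3, 3)."""
    C = np.asarray(C)
    x, y, z = C[:, 0], C[:, 1], C[:, 2]
    cc = x * x + y * y + z * z
    a = 1.0 + cc
    out = np.empty(C.shape[:1] + (3, 3), dtype=np.result_type(C, float))
    out[:, 0, 0] = 1.0 - cc + 2.0 * x * x
    out[:, 0, 1] = 2.0 * (x * y - z)
    out[:, 0, 2] = 2.0 * (x * z + y)
    out[:, 1, 0] = 2.0 * (x * y + z)
    out[:, 1, 1] = 1.0 - cc + 2.0 * y * y
    out[:, 1, 2] = 2.0 * (y * z - x)
    out[:, 2, 0] = 2.0 * (x * z - y)
    out[:, 2, 1] = 2.0 * (y * z + x)
    out[:, 2, 2] = 1.0 - cc + 2.0 * z * z
    out /= a[:, None, None]
    return out


def half_vector_many(C):
    C = np.asarray(C)
    g = np.sqrt(1.0 + (C * C).sum(axis=-1))
    return C / (1.0 + g)[:, None]


def d_cayley_many(C):
    """Derivative tensors d cay / d c, shape (m, 3) -> (m, 3, 3, 3)."""
    C = np.asarray(C)
    m = C.shape[0]
    dtype = np.result_type(C, float)
    cc = (C * C).sum(axis=-1)
    a = 1.0 + cc
    M = cayley_many(C) * a[:, None, None]
    eye = np.eye(3)
    skew_e = np.array([_skew(e) for e in np.eye(3)])
    out = np.empty((m, 3, 3, 3), dtype=dtype)
    for k in range(3):
        e = eye[k]
        dM = (-2.0 * C[:, k, None, None] * eye
              + 2.0 * (np.einsum("i,mj->mij", e, C) + np.einsum("mi,j->mij", C, e))
              + 2.0 * skew_e[k])
        out[:, k] = (dM / a[:, None, None]
                     - M * (2.0 * C[:, k] / a**2)[:, None, None])
    return out


def d_half_vector_many(C):
    C = np.asarray(C)
    g = np.sqrt(1.0 + (C * C).sum(axis=-1))
    return (np.eye(3) / (1.0 + g)[:, None, None]
            - np.einsum("mi,mj->mij", C, C) / (g * (1.0 + g) ** 2)[:, None, None])


# ---------------------------------------------------------------------------
# Frames


@dataclass
class RigidFrame:
    """A right-handed orthonormal frame: origin (Angstrom) + orientation."""

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        R = self.orientation
        if self.origin.shape != (3,) or R.shape != (3, 3):
            raise ValueError("RigidFrame needs a 3-vector origin and 3x3 orientation")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8:
            raise ValueError("orientation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("orientation is a reflection, not a rotation")

    def transform_points(self, pts):
        return np.asarray(pts) @ self.orientation.T + self.origin


@dataclass
class EmbeddedConfiguration:
    """Absolute frames and phosphate positions of an embedded configuration.

    Arrays: base-pair, Watson-base and Crick-base frames have shape
    (n, 3) / (n, 3, 3); phosphate origins/orientations have shape
    (n-1, 3) / (n-1, 3, 3).  ``watson_phosphates`` / ``crick_phosphates``
    are the Cartesian positions entering the histone-contact constraints.
    """

    n: int
    bp_origins: np.ndarray
    bp_orientations: np.ndarray
    watson_base_origins: np.ndarray
    watson_base_orientations: np.ndarray
    crick_base_origins: np.ndarray
    crick_base_orientations: np.ndarray
    watson_phosphates: np.ndarray
    watson_phosphate_orientations: np.ndarray
    crick_phosphates: np.ndarray
    crick_phosphate_orientations: np.ndarray

    def base_pair_frame(self, a: int) -> RigidFrame:
        return RigidFrame(self.bp_origins[a], self.bp_orientations[a])


def _decode_rot(c_scaled, scale):
    return cayley(np.asarray(c_scaled) / scale)


def _gather(w, n, offset, width=3):
    """Coordinates w[24*j + offset : +width] for j = 0..n-2, shape (n-1, width)."""
    idx = (24 * np.arange(n - 1))[:, None] + (offset + np.arange(width))
    return w[idx]


def _chain_frames(w, n, scale, anchor, Lam=None, V=None):
    """Base-pair frames from the inter coordinates (complex-safe).

    ``Lam`` (relative rotations) and ``V`` (mid-frame translations in
    the preceding bp frame) may be passed in precomputed.
    """
    dtype = np.result_type(w, float)
    if Lam is None:
        cr = _gather(w, n, 12) / scale
        ct = _gather(w, n, 15)
        Lam = cayley_many(cr)
        V = np.einsum("jik,jk->ji", cayley_many(half_vector_many(cr)), ct)
    R = np.empty((n, 3, 3), dtype=dtype)
    o = np.empty((n, 3), dtype=dtype)
    if anchor is None:
        R[0] = np.eye(3)
        o[0] = 0.0
    else:
        R[0] = anchor.orientation
        o[0] = anchor.origin
    for j in range(n - 1):
        o[j + 1] = o[j] + R[j] @ V[j]
        R[j + 1] = R[j] @ Lam[j]
    return R, o


def coords_to_frames(w, n: int, scale: float = DEFAULT_CAYLEY_SCALE,
                     anchor: RigidFrame | None = None) -> EmbeddedConfiguration:
    """Embed internal coordinates into absolute frames.

    Successive base-pair frames are placed by the mid-frame construction
    (the translation is expressed in the half-rotated frame), each base
    pair is split into Watson and Crick base frames by the half intra
    rotation, and each phosphate is placed relative to its 3'-side base
    frame on its own strand.
    """
    w = np.asarray(w)
    N = coord_count(n)
    if w.shape != (N,):
        raise ValueError(f"expected {N} coordinates for n={n}, got {w.shape}")
    R, o = _chain_frames(w, n, scale, anchor)

    iu = (24 * np.arange(n))[:, None]
    ur = w[iu + np.arange(3)] / scale
    ut = w[iu + np.arange(3, 6)]
    h = half_vector_many(ur)
    Dh = cayley_many(h)
    Dh_inv = cayley_many(-h)
    wR = np.einsum("aij,ajk->aik", R, Dh)
    cR = np.einsum("aij,ajk->aik", R, Dh_inv)
    shift = np.einsum("aij,aj->ai", R, 0.5 * ut)
    wo = o + shift
    co = o - shift

    # Crick phosphate of junction j rides on the Crick base of bp j;
    # Watson phosphate of junction j rides on the Watson base of bp j+1
    cp = co[:-1] + np.einsum("jik,jk->ji", cR[:-1], _gather(w, n, 9))
    cpR = np.einsum("jik,jkl->jil", cR[:-1], cayley_many(_gather(w, n, 6) / scale))
    wp = wo[1:] + np.einsum("jik,jk->ji", wR[1:], _gather(w, n, 21))
    wpR = np.einsum("jik,jkl->jil", wR[1:], cayley_many(_gather(w, n, 18) / scale))

    return EmbeddedConfiguration(
        n=n,
        bp_origins=o, bp_orientations=R,
        watson_base_origins=wo, watson_base_orientations=wR,
        crick_base_origins=co, crick_base_orientations=cR,
        watson_phosphates=wp, watson_phosphate_orientations=wpR,
        crick_phosphates=cp, crick_phosphate_orientations=cpR,
    )


def _check_orthonormal(R, what):
    if np.max(np.abs(np.einsum("...ji,...jk->...ik", R, R) - np.eye(3))) > 1e-6:
        raise ValueError(f"{what} frames are not orthonormal")


def frames_to_coords(config: EmbeddedConfiguration,
                     scale: float = DEFAULT_CAYLEY_SCALE) -> np.ndarray:
    """Exact inverse of :func:`coords_to_frames` (uses base and phosphate
    frames only; the stored base-pair frames are re-derived)."""
    n = config.n
    _check_orthonormal(config.watson_base_orientations, "Watson base")
    _check_orthonormal(config.crick_base_orientations, "Crick base")
    w = np.empty(coord_count(n))

    bpR = np.empty((n, 3, 3))
    bpo = np.empty((n, 3))
    for a in range(n):
        Rw = config.watson_base_orientations[a]
        Rc = config.crick_base_orientations[a]
        D = Rc.T @ Rw
        u = cayley_inverse(D)
        h = half_vector(u)
        bpR[a] = Rc @ cayley(h)
        ow = config.watson_base_origins[a]
        oc = config.crick_base_origins[a]
        bpo[a] = 0.5 * (ow + oc)
        w[intra_slice(a)][:3] = scale * u
        w[intra_slice(a)][3:] = bpR[a].T @ (ow - oc)

    for j in range(n - 1):
        base = eta_offset(j)
        Lam = bpR[j].T @ bpR[j + 1]
        cr = cayley_inverse(Lam)
        Rmid = bpR[j] @ cayley(half_vector(cr))
        w[base + 6 : base + 9] = scale * cr
        w[base + 9 : base + 12] = Rmid.T @ (bpo[j + 1] - bpo[j])
        # phosphates
        Rc = config.crick_base_orientations[j]
        w[base + 0 : base + 3] = scale * cayley_inverse(
            Rc.T @ config.crick_phosphate_orientations[j])
        w[base + 3 : base + 6] = Rc.T @ (
            config.crick_phosphates[j] - config.crick_base_origins[j])
        Rw = config.watson_base_orientations[j + 1]
        w[base + 12 : base + 15] = scale * cayley_inverse(
            Rw.T @ config.watson_phosphate_orientations[j])
        w[base + 15 : base + 18] = Rw.T @ (
            config.watson_phosphates[j] - config.watson_base_origins[j + 1])
    return w


# ---------------------------------------------------------------------------
# Phosphate positions and their Jacobian


def _validate_bound(bound, n):
    recs = []
    for strand, j in bound:
        s = str(strand).upper()[:1]
        if s not in ("W", "C"):
            raise ValueError(f"unknown strand {strand!r}")
        j = int(j)
        if not 1 <= j <= n - 1:
            raise ValueError(f"junction index {j} out of range 1..{n - 1}")
        recs.append((s, j))
    return recs


def phosphate_positions(w, n: int, bound,
                        scale: float = DEFAULT_CAYLEY_SCALE,
                        anchor: RigidFrame | None = None) -> np.ndarray:
    """Cartesian positions (Angstrom) of the listed (strand, junction)
    phosphates, junctions 1-based, in input order."""
    recs = _validate_bound(bound, n)
    emb = coords_to_frames(w, n, scale=scale, anchor=anchor)
    out = np.empty((len(recs), 3), dtype=np.result_type(w, float))
    for k, (s, j) in enumerate(recs):
        out[k] = emb.watson_phosphates[j - 1] if s == "W" else emb.crick_phosphates[j - 1]
    return out


def phosphate_position_jacobian(w, n: int, bound,
                                scale: float = DEFAULT_CAYLEY_SCALE,
                                anchor: RigidFrame | None = None):
    """Positions and analytic Jacobian of the listed phosphates.

    Returns ``(positions (k,3), J (k,3,N))`` with exact chain-rule
    derivatives through the frame reconstruction.
    """
    recs = _validate_bound(bound, n)
    w = np.asarray(w)
    dtype = np.result_type(w, float)
    N = coord_count(n)
    emb = coords_to_frames(w, n, scale=scale, anchor=anchor)
    k = len(recs)
    P = np.empty((k, 3), dtype=dtype)
    J = np.zeros((k, 3, N), dtype=dtype)
    R, o = emb.bp_orientations, emb.bp_origins

    # reference base pair (0-based) of each phosphate
    ref_bp = np.array([j if s == "W" else j - 1 for s, j in recs])

    for idx, (s, j1) in enumerate(recs):
        j = j1 - 1  # junction, 0-based
        b = ref_bp[idx]
        base = eta_offset(j)
        y = w[intra_slice(b)]
        u = y[:3] / scale
        h = half_vector(u)
        dh = d_half_vector(u)
        if s == "W":
            t = w[base + 15 : base + 18]
            Dh = cayley(h)
            P[idx] = emb.watson_phosphates[j]
            # d/d intra translation: p = o_b + R_b (0.5 ut) + R_b Dh t
            J[idx, :, intra_slice(b)][:, 3:6] = 0.5 * R[b]
            dD = np.einsum("mij,mk->kij", d_cayley(h), dh)
            J[idx, :, intra_slice(b)][:, 0:3] = (
                np.einsum("xi,kij,j->xk", R[b], dD, t) / scale)
            J[idx, :, base + 15 : base + 18] = R[b] @ Dh
        else:
            t = w[base + 3 : base + 6]
            Dh_inv = cayley(-h)
            P[idx] = emb.crick_phosphates[j]
            J[idx, :, intra_slice(b)][:, 3:6] = -0.5 * R[b]
            dDinv = np.einsum("mij,mk->kij", d_cayley(-h), -dh)
            J[idx, :, intra_slice(b)][:, 0:3] = (
                np.einsum("xi,kij,j->xk", R[b], dDinv, t) / scale)
            J[idx, :, base + 3 : base + 6] = R[b] @ Dh_inv

    # inter-coordinate blocks: junction jj affects phosphates with ref_bp > jj
    if k:
        cr_all = _gather(w, n, 12) / scale
        ct_all = _gather(w, n, 15)
        hv_all = half_vector_many(cr_all)
        Lh_all = cayley_many(hv_all)
        dLam_all = d_cayley_many(cr_all)
        dLh_all = np.einsum("jmil,jmk->jkil",
                            d_cayley_many(hv_all), d_half_vector_many(cr_all))
        dLh_ct_all = np.einsum("jail,jl->jia", dLh_all, ct_all)  # (j, i, a)
        RmLh = np.einsum("jik,jkl->jil", R[:-1], Lh_all)  # mid-frame rotations
    for jj in range(int(ref_bp.max()) if k else 0):
        sel = np.nonzero(ref_bp > jj)[0]
        if sel.size == 0:
            continue
        base = eta_offset(jj)
        Q = (P[sel] - o[jj + 1]) @ R[jj + 1]  # rows: q_k in frame jj+1
        B = np.einsum("aij,kj->kia", dLam_all[jj], Q)  # (k, i, a)
        block = np.einsum("xi,kia->kxa", R[jj],
                          dLh_ct_all[jj][None, :, :] + B) / scale
        J[sel, :, base + 6 : base + 9] = block
        J[np.ix_(sel, range(3), range(base + 9, base + 12))] = RmLh[jj][None]
    return P, J


# ---------------------------------------------------------------------------
# Superposition and cylindrical coordinates


def superpose(mobile, reference):
    """Least-squares rigid superposition (no reflection) of point sets.

    Returns ``(RigidFrame motion, rmsd)`` with ``motion`` mapping mobile
    points onto the reference: x -> R x + t.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("superpose needs two equal-shape (k,3) point sets")
    if mob.shape[0] < 3:
        raise ValueError("need at least 3 points")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    mob0, ref0 = mob - mc, ref - rc
    if np.linalg.matrix_rank(mob0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry")
    rot, rssd = Rotation.align_vectors(ref0, mob0)
    R = rot.as_matrix()
    t = rc - R @ mc
    rmsd = rssd / np.sqrt(mob.shape[0])
    return RigidFrame(t, R), float(rmsd)


def fit_axis(points):
    """Symmetry axis of a flat point cloud: centroid + smallest-variance
    principal direction (deterministic sign)."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    vals, vecs = np.linalg.eigh(cov)
    d = vecs[:, 0]
    i = int(np.argmax(np.abs(d)))
    if d[i] < 0:
        d = -d
    return c, d


def cylindrical_profile(points, axis=None) -> pd.DataFrame:
    """Per-point cylindrical coordinates (radius, angle, height) about an
    axis; default axis is the fitted symmetry axis of the cloud."""
    pts = np.asarray(points, dtype=float)
    if axis is None:
        c, d = fit_axis(pts)
    else:
        c, d = (np.asarray(x, dtype=float) for x in axis)
        nd = np.linalg.norm(d)
        if nd < 1e-12:
            raise ValueError("zero-length axis direction")
        d = d / nd
    # deterministic in-plane reference directions
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ d) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    rel = pts - c
    height = rel @ d
    perp = rel - np.outer(height, d)
    radius = np.linalg.norm(perp, axis=1)
    angle = np.arctan2(perp @ e2, perp @ e1)
    return pd.DataFrame({"radius": radius, "angle": angle, "height": height})


# ---------------------------------------------------------------------------
# Structure ensembles (aligned phosphate tracks)


@dataclass
class StructureEnsemble:
    """Aligned phosphate positions: arrays (n_structures, n_junctions, 3)."""

    watson: np.ndarray
    crick: np.ndarray
    structure_ids: list[str] | None = None

    def __post_init__(self):
        self.watson = np.asarray(self.watson, dtype=float)
        self.crick = np.asarray(self.crick, dtype=float)
        if self.watson.shape != self.crick.shape or self.watson.ndim != 3:
            raise ValueError("watson/crick arrays must have equal (S, J, 3) shapes")
        if self.structure_ids is None:
            self.structure_ids = [f"s{i}" for i in range(self.watson.shape[0])]

    @property
    def n_structures(self) -> int:
        return self.watson.shape[0]

    @property
    def n_junctions(self) -> int:
        return self.watson.shape[1]


def write_structure_ensemble(ensemble: StructureEnsemble, path) -> None:
    rows = []
    for s, sid in enumerate(ensemble.structure_ids):
        for strand, arr in (("W", ensemble.watson), ("C", ensemble.crick)):
            for j in range(ensemble.n_junctions):
                x, y, z = arr[s, j]
                rows.append((sid, strand, j + 1, x, y, z))
    df = pd.DataFrame(rows, columns=["structure_id", "strand", "index", "x", "y", "z"])
    df.to_csv(path, sep="\t", index=False)


def read_structure_ensemble(path) -> StructureEnsemble:
    df = pd.read_csv(path, sep="\t")
    need = {"structure_id", "strand", "index", "x", "y", "z"}
    if not need.issubset(df.columns):
        raise ValueError(f"ensemble table must have columns {sorted(need)}")
    ids = list(dict.fromkeys(df["structure_id"]))
    nj = int(df["index"].max())
    S = len(ids)
    watson = np.full((S, nj, 3), np.nan)
    crick = np.full((S, nj, 3), np.nan)
    pos = {sid: i for i, sid in enumerate(ids)}
    for _, r in df.iterrows():
        arr = watson if str(r["strand"]).upper().startswith("W") else crick
        arr[pos[r["structure_id"]], int(r["index"]) - 1] = (r["x"], r["y"], r["z"])
    if np.isnan(watson).any() or np.isnan(crick).any():
        raise ValueError("missing coordinates in ensemble table")
    return StructureEnsemble(watson, crick, structure_ids=[str(i) for i in ids])
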