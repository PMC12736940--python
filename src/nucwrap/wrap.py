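"""Nucleosome wrapping energy: constrained minimisation of the Gaussian
model energy under elastic phosphate constraints.

The wrapped configuration of an n = 147 bp fragment is modelled as

    w_opt = argmin_w  U(w) + sum_i c_i || p_i(w) - pbar_i ||^2

where ``p_i(w)`` are the Cartesian positions of the 28 phosphates closest
to the histone core, ``pbar_i`` their reference positions (averages over
aligned experimental structures, or a synthetic superhelix), and ``c_i``
penalty coefficients in kT/A^2.  The reported wrapping energy is the
elastic part U(w_opt) alone; the penalty sum at the optimum is returned
separately.  Minimisation is a trust-region Newton iteration on the
internal coordinates with exact chain-rule gradients; the penalty block
of the Hessian uses the Gauss-Newton approximation by default (the
exact second-order term is available via complex-step differentiation
of the analytic gradient).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator

from . import geometry as G
from .model import GaussianModel, ParameterSet, build_model, energy, log_density
from .seqops import ModSequence

__all__ = [
    "ConstraintSet",
    "WrapResult",
    "objective",
    "minimize_wrap",
    "superhelix_initial_configuration",
    "identify_bound_indices",
    "build_constraints",
    "residual_report",
    "check_self_overlap",
]


@dataclass
class ConstraintSet:
    """Elastic constraints on histone-bound phosphate positions."""

    strands: list[str]
    junctions: list[int]
    refs: np.ndarray  # (k, 3) A
    coefficients: np.ndarray  # (k,) kT/A^2
    provenance: str = ""

    def __post_init__(self):
        self.strands = [str(s).upper()[:1] for s in self.strands]
        self.junctions = [int(j) for j in self.junctions]
        self.refs = np.asarray(self.refs, dtype=float).reshape(-1, 3)
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        k = len(self.strands)
        if not (len(self.junctions) == self.refs.shape[0]
                == self.coefficients.shape[0] == k):
            raise ValueError("inconsistent constraint record lengths")
        if any(s not in ("W", "C") for s in self.strands):
            raise ValueError("strand must be W(atson) or C(rick)")
        if np.any(self.coefficients <= 0):
            raise ValueError("penalty coefficients must be positive")
        pairs = list(zip(self.strands, self.junctions))
        if len(set(pairs)) != k:
            raise ValueError("duplicate (strand, junction) constraint")

    @property
    def k(self) -> int:
        return len(self.strands)

    @property
    def bound(self) -> list[tuple[str, int]]:
        return list(zip(self.strands, self.junctions))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# nucwrap constraint set; units: A, kT/A^2\n")
            fh.write(f"# provenance: {self.provenance}\n")
            fh.write("strand\tjunction\tx\ty\tz\tc\n")
            for i in range(self.k):
                x, y, z = (float(v) for v in self.refs[i])
                fh.write(f"{self.strands[i]}\t{self.junctions[i]}\t"
                         f"{x!r}\t{y!r}\t{z!r}\t{float(self.coefficients[i])!r}\n")

    @classmethod
    def read_tsv(cls, path) -> "ConstraintSet":
        provenance = ""
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                if "provenance:" in line:
                    provenance = line.split("provenance:", 1)[1].strip()
            else:
                body.append(line)
        import io
        df = pd.read_csv(io.StringIO("".join(body)), sep="\t",
                         dtype={"strand": str}, float_precision="round_trip")
        return cls(list(df["strand"]), list(df["junction"]),
                   df[["x", "y", "z"]].to_numpy(),
                   df["c"].to_numpy(), provenance=provenance)


@dataclass
class WrapResult:
    """Optimal wrapped configuration and diagnostics."""

    w_opt: np.ndarray
    wrap_energy: float  # U(w_opt), kT — the reported wrapping energy
    penalty_value: float  # sum_i C_i(w_opt), kT, reported separately
    residuals: np.ndarray  # per-constraint distances, A
    log_density: float
    iterations: int
    grad_norm: float  # final infinity-norm of the objective gradient
    converged: bool
    objective_history: list = field(default_factory=list)
    model: GaussianModel | None = None

    def summary(self) -> dict:
        return {
            "wrap_energy_kT": self.wrap_energy,
            "penalty_kT": self.penalty_value,
            "log_density": self.log_density,
            "max_residual_A": float(self.residuals.max()) if self.residuals.size else 0.0,
            "iterations": self.iterations,
            "grad_inf_norm": self.grad_norm,
            "converged": self.converged,
        }

    def to_json(self, path, include_configuration: bool = False) -> None:
        out = self.summary()
        out["residuals_A"] = [float(r) for r in self.residuals]
        if include_configuration:
            out["w_opt"] = [float(x) for x in self.w_opt]
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


# ---------------------------------------------------------------------------
# Objective


class _PenalizedHessian(LinearOperator):
    """K plus the Gauss-Newton penalty block 2 sum_i c_i J_i^T J_i."""

    def __init__(self, K: sp.csr_matrix, J: np.ndarray, coeff: np.ndarray,
                 extra: np.ndarray | None = None):
        self.K = K
        self.J = J  # (k, 3, N)
        self.coeff = coeff
        self.extra = extra  # optional exact second-order correction (N, N)
        N = K.shape[0]
        super().__init__(dtype=float, shape=(N, N))

    def _matvec(self, v):
        v = np.asarray(v).ravel()
        out = self.K @ v
        if self.J.size:
            Jv = np.einsum("kin,n->ki", self.J, v)
            out = out + 2.0 * np.einsum("k,kin,ki->n", self.coeff, self.J, Jv)
        if self.extra is not None:
            out = out + self.extra @ v
        return out

    def toarray(self) -> np.ndarray:
        H = self.K.toarray()
        if self.J.size:
            k, _, N = self.J.shape
            Jf = self.J.reshape(3 * k, N)
            C = np.repeat(self.coeff, 3)
            H = H + 2.0 * (Jf.T * C) @ Jf
        if self.extra is not None:
            H = H + self.extra
        return H


def _penalty_exact_correction(w, model, constraints, anchor):
    """Second-order penalty term 2 sum c_i r_i . d2 p_i via complex step
    on the analytic first-order data (small systems only)."""
    N = model.N
    if N > 800:
        raise ValueError("exact Hessian is limited to small systems; use Gauss-Newton")
    h = 1e-200
    base_p = G.phosphate_positions(w, model.n, constraints.bound,
                                   scale=model.scale, anchor=anchor)
    r = base_p - constraints.refs
    H2 = np.empty((N, N))
    for l in range(N):
        e = np.zeros(N, dtype=complex)
        e[l] = 1j * h
        _, Jc = G.phosphate_position_jacobian(
            np.asarray(w, dtype=complex) + e, model.n, constraints.bound,
            scale=model.scale, anchor=anchor)
        dJ = Jc.imag / h  # (k, 3, N)
        H2[l] = 2.0 * np.einsum("k,ki,kin->n", constraints.coefficients, r, dJ)
    return 0.5 * (H2 + H2.T)


def objective(w, model: GaussianModel, constraints: ConstraintSet,
              hessian: str = "gauss-newton",
              anchor: G.RigidFrame | None = None):
    """Value (kT), gradient and Hessian operator of the wrap objective."""
    w = np.asarray(w, dtype=float)
    U = energy(w, model)
    grad = model.K @ (w - model.mu)
    if constraints.k:
        pos, J = G.phosphate_position_jacobian(
            w, model.n, constraints.bound, scale=model.scale, anchor=anchor)
        r = pos - constraints.refs
        c = constraints.coefficients
        value = U + float(c @ np.einsum("ki,ki->k", r, r))
        grad = grad + 2.0 * np.einsum("k,ki,kin->n", c, r, J)
    else:
        J = np.zeros((0, 3, model.N))
        value = U
    extra = None
    if hessian == "exact" and constraints.k:
        extra = _penalty_exact_correction(w, model, constraints, anchor)
    elif hessian not in ("gauss-newton", "exact"):
        raise ValueError("hessian must be 'gauss-newton' or 'exact'")
    H = _PenalizedHessian(model.K, J, constraints.coefficients
                          if constraints.k else np.zeros(0), extra)
    return value, grad, H


def _newton_minimize(model, constraints, w0, gtol, maxiter, anchor):
    """Damped line-search Newton with exact Gauss-Newton solves.

    The Gauss-Newton Hessian is banded K plus a rank-3k update, so the
    Newton direction is computed exactly via a banded Cholesky of
    (K + lambda I) and the Woodbury identity; Armijo backtracking plus
    Levenberg damping globalise the iteration.  Objective values along
    accepted steps are monotonically non-increasing.
    """
    import scipy.linalg as sla

    k = constraints.k
    coeff = constraints.coefficients if k else np.zeros(0)
    D = np.repeat(2.0 * coeff, 3)  # penalty curvature weights

    def full_eval(w):
        v, g, H = objective(w, model, constraints, anchor=anchor)
        return v, g, H.J.reshape(3 * k, model.N) if k else np.zeros((0, model.N))

    def value_only(w):
        U = energy(w, model)
        if not k:
            return U
        pos = G.phosphate_positions(w, model.n, constraints.bound,
                                    scale=model.scale, anchor=anchor)
        r = pos - constraints.refs
        return U + float(coeff @ np.einsum("ki,ki->k", r, r))

    def make_solver(lam, Jf):
        ab = model.K_banded.copy()
        ab[-1] += lam
        cb = sla.cholesky_banded(ab, lower=False)

        def ksolve(b):
            return sla.cho_solve_banded((cb, False), b)

        if not k:
            return ksolve
        B = ksolve(Jf.T)  # (N, 3k)
        S = np.diag(1.0 / D) + Jf @ B
        Sf = sla.cho_factor(S)

        def solve(b):
            a = ksolve(b)
            return a - B @ sla.cho_solve(Sf, Jf @ a)

        return solve

    w = np.asarray(w0, dtype=float).copy()
    f, g, Jf = full_eval(w)
    history = [f]
    lam = 0.0
    n_accept = 0
    for _ in range(maxiter):
        gnorm = float(np.max(np.abs(g))) if g.size else 0.0
        if gnorm <= gtol:
            return w, gnorm, n_accept, True, history
        d = -make_solver(lam, Jf)(g)
        gd = float(g @ d)
        if gd >= 0:  # numerically non-descent: increase damping
            lam = max(10.0 * lam, 1e-4)
            continue
        t = 1.0
        accepted = False
        for _ in range(40):
            fn = value_only(w + t * d)
            if fn <= f + 1e-4 * t * gd:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            lam = max(10.0 * lam, 1e-4)
            if lam > 1e10:
                break
            continue
        w = w + t * d
        f, g, Jf = full_eval(w)
        history.append(f)
        n_accept += 1
        lam = 0.0 if t == 1.0 else lam / 3.0
    gnorm = float(np.max(np.abs(g))) if g.size else 0.0
    return w, gnorm, n_accept, bool(gnorm <= gtol), history


def _bend_onto_superhelix(model: GaussianModel, frame_geom, dr: float,
                          tau0: float) -> np.ndarray:
    """Ground state with inter coordinates replaced so the base-pair
    axis follows a superhelix at radius (fitted + dr), with helical spin
    phase tau0.  Intra and phosphate coordinates stay at ground state."""
    c0, d, e1, e2, radius, dphi, phi0, dz, z0, tau = frame_geom
    n = model.n
    r_axis = radius + dr
    a_idx = np.arange(1, n + 1, dtype=float)
    phi = phi0 + dphi * (a_idx - 0.5)  # bp a sits half a step before junction a
    origins = (c0[None]
               + r_axis * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
               + np.outer(z0 + dz * (a_idx - 0.5), d))
    R = np.empty((n, 3, 3))
    for i, p in enumerate(phi):
        tangent = r_axis * dphi * (-np.sin(p) * e1 + np.cos(p) * e2) + dz * d
        d3 = tangent / np.linalg.norm(tangent)
        radial = -(np.cos(p) * e1 + np.sin(p) * e2)
        d1 = radial - (radial @ d3) * d3
        d1 /= np.linalg.norm(d1)
        d2 = np.cross(d3, d1)
        base = np.stack([d1, d2, d3], axis=1)
        ct, st = np.cos(tau * i + tau0), np.sin(tau * i + tau0)
        spin = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
        R[i] = base @ spin

    w0 = model.mu.copy()
    for j in range(n - 1):
        Lam = R[j].T @ R[j + 1]
        cr = G.cayley_inverse(Lam)
        Rmid = R[j] @ G.cayley(G.half_vector(cr))
        off = G.eta_offset(j)
        w0[off + 6 : off + 9] = model.scale * cr
        w0[off + 9 : off + 12] = Rmid.T @ (origins[j + 1] - origins[j])
    return w0


def superhelix_initial_configuration(model: GaussianModel,
                                     constraints: ConstraintSet) -> np.ndarray:
    """Starting configuration: the ground state bent onto an ideal
    superhelix least-squares fitted to the constraint reference points.

    The axis is the smallest-variance principal direction of the
    references; winding rate and pitch come from linear fits of
    unwrapped angle and height against junction index.  Because the
    constrained phosphates sit off the base-pair axis, the axis radius
    offset and the helical spin phase are then chosen by a coarse grid
    search minimising the misfit of the constrained phosphates to their
    references.  Intra and phosphate coordinates are kept at their
    ground-state values; only the inter coordinates are replaced.
    """
    if constraints.k < 4:
        return model.mu.copy()
    refs = constraints.refs
    c0, d = G.fit_axis(refs)
    prof = G.cylindrical_profile(refs, axis=(c0, d))
    radius = float(prof["radius"].mean())
    jidx = np.asarray(constraints.junctions, dtype=float)
    order = np.argsort(jidx)
    ang = np.unwrap(prof["angle"].to_numpy()[order])
    js = jidx[order]
    dphi, phi0 = np.polyfit(js, ang, 1)
    dz, z0 = np.polyfit(js, prof["height"].to_numpy()[order], 1)

    n = model.n
    # mean helical twist of the ground state (angle about the bp axis)
    tw = []
    for j in range(n - 1):
        c = model.mu[G.eta_offset(j) + 6 : G.eta_offset(j) + 9] / model.scale
        tw.append(2.0 * np.arctan(c[2]))
    tau = float(np.mean(tw))

    e1 = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ d) > 0.9:
        e1 = np.array([0.0, 1.0, 0.0])
    e1 = e1 - (e1 @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    geom = (c0, d, e1, e2, radius, dphi, phi0, dz, z0, tau)

    best = (np.inf, None)
    for dr in np.linspace(-12.0, 12.0, 9):
        for tau0 in np.linspace(0.0, 2.0 * np.pi, 12, endpoint=False):
            w0 = _bend_onto_superhelix(model, geom, dr, tau0)
            pos = G.phosphate_positions(w0, n, constraints.bound,
                                        scale=model.scale)
            cost = float(np.sum((pos - refs) ** 2))
            if cost < best[0]:
                best = (cost, (dr, tau0))
    dr, tau0 = best[1]
    return _bend_onto_superhelix(model, geom, dr, tau0)


def minimize_wrap(seq: ModSequence | str, params: ParameterSet,
                  constraints: ConstraintSet,
                  init="superhelix", gtol: float = 1e-6,
                  maxiter: int = 500,
                  anchor: G.RigidFrame | None = None) -> WrapResult:
    """Minimise the wrap objective for one sequence.

    ``init`` is ``"superhelix"`` (default: ground state bent onto a
    superhelix fitted to the constraint references), ``"ground"`` (the
    straight ground state) or an explicit configuration vector.
    Deterministic given (seq, params, constraints, init).
    """
    model = build_model(seq, params)
    if isinstance(init, str):
        if init == "ground" or constraints.k == 0:
            w0 = model.mu.copy()
        elif init == "superhelix":
            w0 = superhelix_initial_configuration(model, constraints)
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        w0 = np.asarray(init, dtype=float)
        if w0.shape != (model.N,):
            raise ValueError(f"init configuration must have length {model.N}")

    w_opt, gnorm, n_iter, converged, history = _newton_minimize(
        model, constraints, w0, gtol=gtol, maxiter=maxiter, anchor=anchor)
    if constraints.k:
        pos = G.phosphate_positions(w_opt, model.n, constraints.bound,
                                    scale=model.scale, anchor=anchor)
        residuals = np.linalg.norm(pos - constraints.refs, axis=1)
        penalty = float(constraints.coefficients @ residuals**2)
    else:
        residuals = np.zeros(0)
        penalty = 0.0
    return WrapResult(
        w_opt=w_opt,
        wrap_energy=energy(w_opt, model),
        penalty_value=penalty,
        residuals=residuals,
        log_density=log_density(w_opt, model),
        iterations=n_iter,
        grad_norm=gnorm,
        converged=converged,
        objective_history=history,
        model=model,
    )


# ---------------------------------------------------------------------------
# Constraint derivation from structure ensembles


@dataclass
class BoundIndexResult:
    watson_indices: list[int]
    crick_indices: list[int]
    watson_mean_radius: np.ndarray
    crick_mean_radius: np.ndarray
    watson_radius_sd: np.ndarray
    crick_radius_sd: np.ndarray


def _radial_profiles(points, axis):
    c, d = axis
    rel = points - c
    h = rel @ d
    perp = rel - h[..., None] * d
    return np.linalg.norm(perp, axis=-1)


def identify_bound_indices(ensemble: G.StructureEnsemble,
                           period_hint: float = 10.2,
                           axis=None) -> BoundIndexResult:
    """Histone-bound phosphate indices from an aligned structure ensemble.

    For each strand the mean (over structures) radial distance to the
    nucleosome axis is profiled against junction index; strict local
    minima are clustered per helical turn (cluster gap = half the period
    hint) and the smallest-radius member of each cluster is reported.
    Also returns the per-index standard-deviation profiles.
    """
    if ensemble.n_structures < 2:
        raise ValueError("need at least 2 aligned structures")
    pooled = np.concatenate(
        [ensemble.watson.reshape(-1, 3), ensemble.crick.reshape(-1, 3)])
    if axis is None:
        axis = G.fit_axis(pooled)

    def strand(points):
        radii = _radial_profiles(points, axis)  # (S, J)
        mean = radii.mean(axis=0)
        sd = radii.std(axis=0, ddof=1)
        tol = 1e-8 * max(1.0, float(np.max(np.abs(mean))))
        minima = [i for i in range(1, len(mean) - 1)
                  if mean[i] < mean[i - 1] - tol and mean[i] < mean[i + 1] - tol]
        if not minima:
            raise ValueError("radial profile has no strict local minima")
        clusters = [[minima[0]]]
        for m in minima[1:]:
            if m - clusters[-1][-1] < period_hint / 2.0:
                clusters[-1].append(m)
            else:
                clusters.append([m])
        picked = [min(cl, key=lambda i: mean[i]) for cl in clusters]
        return [i + 1 for i in picked], mean, sd  # 1-based junctions

    w_idx, w_mean, w_sd = strand(ensemble.watson)
    c_idx, c_mean, c_sd = strand(ensemble.crick)
    return BoundIndexResult(w_idx, c_idx, w_mean, c_mean, w_sd, c_sd)


def build_constraints(ensemble: G.StructureEnsemble, bound_indices,
                      coefficients=10.0) -> ConstraintSet:
    """Constraint references = ensemble-mean positions at bound indices.

    ``bound_indices`` is a list of (strand, junction) pairs or a
    :class:`BoundIndexResult`; ``coefficients`` a global value or
    per-record array (kT/A^2).
    """
    if isinstance(bound_indices, BoundIndexResult):
        pairs = ([("W", j) for j in bound_indices.watson_indices]
                 + [("C", j) for j in bound_indices.crick_indices])
    else:
        pairs = [(str(s).upper()[:1], int(j)) for s, j in bound_indices]
    nj = ensemble.n_junctions
    refs = []
    for s, j in pairs:
        if not 1 <= j <= nj:
            raise ValueError(f"junction {j} outside ensemble range 1..{nj}")
        arr = ensemble.watson if s == "W" else ensemble.crick
        refs.append(arr[:, j - 1].mean(axis=0))
    coeff = np.broadcast_to(np.asarray(coefficients, dtype=float),
                            (len(pairs),)).copy()
    return ConstraintSet(
        strands=[s for s, _ in pairs], junctions=[j for _, j in pairs],
        refs=np.array(refs), coefficients=coeff,
        provenance=f"ensemble mean over {ensemble.n_structures} structures")


def residual_report(result: WrapResult, constraints: ConstraintSet,
                    ranges=None) -> pd.DataFrame:
    """Per-constraint residual table, flagging residuals outside the
    optional per-record (low, high) distance ranges."""
    df = pd.DataFrame({
        "strand": constraints.strands,
        "junction": constraints.junctions,
        "residual_A": result.residuals,
    })
    if ranges is not None:
        lo = np.array([r[0] for r in ranges], dtype=float)
        hi = np.array([r[1] for r in ranges], dtype=float)
        df["flagged"] = (df["residual_A"] < lo) | (df["residual_A"] > hi)
    else:
        df["flagged"] = False
    return df


def min_cross_turn_distance(points, junctions, separation: int = 40):
    """Minimum distance between points whose junction indices differ by
    more than ``separation`` (i.e. lie on different superhelical turns).

    Returns ``(min_distance, (i, j))`` over the point list, or
    ``(inf, None)`` if no pair qualifies.
    """
    pts = np.asarray(points, dtype=float)
    jun = np.asarray(junctions)
    diff = np.abs(jun[:, None] - jun[None, :])
    dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    mask = diff > separation
    if not mask.any():
        return np.inf, None
    dist_masked = np.where(mask, dist, np.inf)
    imin = np.unravel_index(np.argmin(dist_masked), dist.shape)
    return float(dist_masked[imin]), imin


def check_self_overlap(result: WrapResult, min_distance: float = 4.0,
                       separation: int = 40,
                       anchor: G.RigidFrame | None = None):
    """Steric check between the two superhelical turns.

    Considers all phosphate pairs (both strands) whose junction indices
    differ by more than ``separation``; returns ``(passed, min_pair_
    distance, worst_pair)`` with worst_pair = ((strand, junction),
    (strand, junction)).  The default threshold is a phosphate-contact
    distance; the separation window is a configurable heuristic for
    "different turn".
    """
    model = result.model
    if model is None:
        raise ValueError("result carries no model; rerun minimize_wrap")
    emb = G.coords_to_frames(result.w_opt, model.n, scale=model.scale,
                             anchor=anchor)
    pts = np.concatenate([emb.watson_phosphates, emb.crick_phosphates])
    nj = model.n - 1
    labels = [("W", j + 1) for j in range(nj)] + [("C", j + 1) for j in range(nj)]
    dmin, pair = min_cross_turn_distance(pts, [j for _, j in labels], separation)
    if pair is None:
        return True, np.inf, None
    worst = (labels[pair[0]], labels[pair[1]])
    return dmin >= min_distance, dmin, worst
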