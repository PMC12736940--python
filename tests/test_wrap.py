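"""Constrained wrapping: objective, minimiser, constraint derivation."""

import numpy as np
import pytest
import scipy.optimize

import nucwrap as nw
from nucwrap import fixtures as F
from nucwrap import wrap as W
from nucwrap.seqops import ModSequence
from conftest import mild_constraints


@pytest.fixture(scope="module")
def toy(params):
    model = nw.build_model(ModSequence("ACGTACGTACGT"), params)
    cons = mild_constraints(model, [("W", 3), ("C", 8)],
                            [[2.0, 1.0, -1.0], [0.0, 2.0, 1.0]])
    return model, cons


def empty_constraints():
    return W.ConstraintSet([], [], np.zeros((0, 3)), np.zeros(0))


class TestConstraintSet:
    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            W.ConstraintSet(["W"], [3], np.zeros((1, 3)), [0.0])
        with pytest.raises(ValueError, match="duplicate"):
            W.ConstraintSet(["W", "W"], [3, 3], np.zeros((2, 3)), [1.0, 1.0])
        with pytest.raises(ValueError, match="strand"):
            W.ConstraintSet(["X"], [3], np.zeros((1, 3)), [1.0])

    def test_tsv_roundtrip_bit_exact(self, tmp_path):
        cons = F.ideal_superhelix_constraints(n_contacts=6, n_bp=60)
        p = tmp_path / "cons.tsv"
        cons.write_tsv(p)
        back = W.ConstraintSet.read_tsv(p)
        assert np.array_equal(back.refs, cons.refs)
        assert np.array_equal(back.coefficients, cons.coefficients)
        assert back.bound == cons.bound
        assert back.provenance == cons.provenance


class TestObjective:
    def test_empty_constraints_is_pure_energy(self, toy):
        model, _ = toy
        w = model.mu + 0.1
        v, g, H = W.objective(w, model, empty_constraints())
        assert v == pytest.approx(nw.energy(w, model), rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_gradient_matches_central_differences(self, toy, seed):
        model, cons = toy
        w = model.mu + np.random.default_rng(seed).normal(0, 0.3, model.N)
        _, g, _ = W.objective(w, model, cons)
        h = 1e-6
        gfd = np.zeros_like(g)
        for l in range(model.N):
            e = np.zeros(model.N)
            e[l] = h
            gfd[l] = (W.objective(w + e, model, cons)[0]
                      - W.objective(w - e, model, cons)[0]) / (2 * h)
        assert np.max(np.abs(g - gfd)) / max(1.0, np.max(np.abs(gfd))) < 1e-6

    def test_gauss_newton_penalty_part_symmetric_psd(self, toy):
        model, cons = toy
        w = model.mu + 0.2
        _, _, H = W.objective(w, model, cons)
        P = H.toarray() - model.K.toarray()
        assert np.max(np.abs(P - P.T)) < 1e-10
        vals = np.linalg.eigvalsh(P)
        assert vals.min() > -1e-10

    def test_exact_hessian_matches_fd_of_gradient(self, toy):
        model, cons = toy
        w = model.mu + np.random.default_rng(7).normal(0, 0.2, model.N)
        _, _, H = W.objective(w, model, cons, hessian="exact")
        Hd = H.toarray()
        h = 1e-5
        rng = np.random.default_rng(8)
        for _ in range(5):  # random directional checks
            v = rng.normal(0, 1, model.N)
            gp = W.objective(w + h * v, model, cons)[1]
            gm = W.objective(w - h * v, model, cons)[1]
            assert np.allclose(Hd @ v, (gp - gm) / (2 * h), rtol=1e-5, atol=1e-6)

    def test_hessp_consistent_with_dense(self, toy):
        model, cons = toy
        _, _, H = W.objective(model.mu + 0.1, model, cons)
        v = np.random.default_rng(1).normal(0, 1, model.N)
        assert np.allclose(H @ v, H.toarray() @ v)


class TestMinimizeWrap:
    def test_no_constraints_returns_ground_state(self, params):
        seq = ModSequence("ACGTACGTACGT")
        r = W.minimize_wrap(seq, params, empty_constraints())
        assert r.wrap_energy == 0.0
        assert r.converged
        model = nw.build_model(seq, params)
        assert np.max(np.abs(r.w_opt - model.mu)) < 1e-12

    def test_matches_quasi_newton_oracle_on_toy(self, params, toy):
        model, cons = toy
        r = W.minimize_wrap(model.seq, params, cons, init="ground")
        assert r.converged
        # independent oracle: generic finite-difference quasi-Newton
        res = scipy.optimize.minimize(
            lambda w: W.objective(w, model, cons)[0], model.mu,
            method="BFGS", options={"gtol": 1e-9, "maxiter": 5000})
        ours = r.wrap_energy + r.penalty_value
        assert abs(res.fun - ours) < 1e-6

    def test_deterministic(self, params, toy):
        model, cons = toy
        r1 = W.minimize_wrap(model.seq, params, cons, init="ground")
        r2 = W.minimize_wrap(model.seq, params, cons, init="ground")
        assert np.array_equal(r1.w_opt, r2.w_opt)

    def test_monotone_descent(self, params, toy):
        model, cons = toy
        r = W.minimize_wrap(model.seq, params, cons, init="ground")
        hist = r.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_penalty_scaling_reduces_residuals(self, params, toy):
        model, cons = toy
        strong = W.ConstraintSet(cons.strands, cons.junctions, cons.refs,
                                 cons.coefficients * 10.0)
        r1 = W.minimize_wrap(model.seq, params, cons, init="ground")
        r2 = W.minimize_wrap(model.seq, params, strong, init="ground")
        assert r2.residuals.max() <= r1.residuals.max() + 1e-9

    def test_vanishing_coefficients_limit(self, params, toy):
        model, cons = toy
        energies = []
        dists = []
        for scale in [1.0, 0.1, 0.01, 0.001]:
            c = W.ConstraintSet(cons.strands, cons.junctions, cons.refs,
                                cons.coefficients * scale)
            r = W.minimize_wrap(model.seq, params, c, init="ground")
            energies.append(r.wrap_energy)
            dists.append(np.max(np.abs(r.w_opt - model.mu)))
        assert all(b < a for a, b in zip(energies, energies[1:]))
        assert all(b < a for a, b in zip(dists, dists[1:]))
        assert energies[-1] < 1e-3 * energies[0]

    def test_anchor_invariance_with_cotransformed_constraints(self, params, toy):
        model, cons = toy
        anchor = nw.RigidFrame(np.array([10.0, -5.0, 3.0]),
                               nw.coords_to_frames(
                                   np.zeros(30), 2).bp_orientations[0])
        import nucwrap.geometry as G
        anchor = nw.RigidFrame(np.array([10.0, -5.0, 3.0]),
                               G.cayley(np.array([0.2, 0.5, -0.1])))
        moved = W.ConstraintSet(cons.strands, cons.junctions,
                                anchor.transform_points(cons.refs),
                                cons.coefficients)
        r0 = W.minimize_wrap(model.seq, params, cons, init="ground")
        r1 = W.minimize_wrap(model.seq, params, moved, init="ground",
                             anchor=anchor)
        assert r1.wrap_energy == pytest.approx(r0.wrap_energy, abs=1e-6)

    def test_bad_init_length(self, params, toy):
        model, cons = toy
        with pytest.raises(ValueError):
            W.minimize_wrap(model.seq, params, cons, init=np.zeros(5))


class TestBoundIndices:
    def test_noise_free_recovery(self):
        ens, truth = F.synthetic_structure_ensemble(noise_sd=0.0, n_structures=3)
        res = W.identify_bound_indices(ens, axis=truth["axis"])
        assert res.watson_indices == truth["watson_minima"]
        assert res.crick_indices == truth["crick_minima"]
        assert len(res.watson_indices) == 14

    def test_constant_radius_errors(self):
        ens, truth = F.synthetic_structure_ensemble(noise_sd=0.0, n_structures=3,
                                                    radial_amplitude=0.0)
        with pytest.raises(ValueError, match="minima"):
            W.identify_bound_indices(ens, axis=truth["axis"])

    def test_minima_match_brute_force_scan(self):
        ens, truth = F.synthetic_structure_ensemble(noise_sd=0.3, n_structures=50,
                                                    seed=4)
        res = W.identify_bound_indices(ens, axis=truth["axis"])
        mean = res.watson_mean_radius
        brute = [i + 1 for i in range(1, len(mean) - 1)
                 if mean[i] < mean[i - 1] and mean[i] < mean[i + 1]]
        assert set(res.watson_indices).issubset(brute)

    def test_single_structure_rejected(self):
        ens, _ = F.synthetic_structure_ensemble(n_structures=1)
        with pytest.raises(ValueError, match="2 aligned"):
            W.identify_bound_indices(ens)


class TestBuildConstraints:
    def test_single_structure_mean_is_itself(self):
        ens, _ = F.synthetic_structure_ensemble(noise_sd=0.0, n_structures=2)
        cons = W.build_constraints(ens, [("W", 3), ("C", 8)], 2.0)
        assert np.allclose(cons.refs[0], ens.watson[0, 2])
        assert np.allclose(cons.refs[1], ens.crick[0, 7])

    def test_two_mirrored_structures_give_midpoint(self):
        base = np.random.default_rng(0).normal(0, 5, (1, 10, 3))
        ens = nw.StructureEnsemble(np.concatenate([base, -base]),
                                   np.concatenate([base + 1, -base + 1]))
        cons = W.build_constraints(ens, [("W", 4)], 1.0)
        assert np.allclose(cons.refs[0], 0.0)

    def test_means_match_brute_force(self):
        ens, _ = F.synthetic_structure_ensemble(noise_sd=1.0, n_structures=20,
                                                seed=9)
        pairs = [("W", 5), ("W", 50), ("C", 30)]
        cons = W.build_constraints(ens, pairs)
        for i, (s, j) in enumerate(pairs):
            arr = ens.watson if s == "W" else ens.crick
            assert np.allclose(cons.refs[i], arr[:, j - 1].mean(axis=0))

    def test_out_of_range_index(self):
        ens, _ = F.synthetic_structure_ensemble(n_structures=2)
        with pytest.raises(ValueError, match="outside"):
            W.build_constraints(ens, [("W", 999)])


class TestResidualReport:
    def test_exact_satisfaction_unflagged(self, params):
        model = nw.build_model(ModSequence("ACGTACGTACGT"), params)
        cons = mild_constraints(model, [("W", 3)], [[0.0, 0.0, 0.0]])
        r = W.minimize_wrap(model.seq, params, cons, init="ground")
        rep = W.residual_report(r, cons)
        assert rep["residual_A"].max() < 1e-6
        assert not rep["flagged"].any()

    def test_zero_range_flags_nonzero_residual(self, params, toy):
        model, cons = toy
        r = W.minimize_wrap(model.seq, params, cons, init="ground")
        rep = W.residual_report(r, cons, ranges=[(0.0, 0.0)] * cons.k)
        assert rep["flagged"].sum() == (r.residuals > 0).sum()

    def test_flag_count_matches_brute_force(self, params, toy):
        model, cons = toy
        r = W.minimize_wrap(model.seq, params, cons, init="ground")
        ranges = [(0.0, float(np.median(r.residuals)))] * cons.k
        rep = W.residual_report(r, cons, ranges=ranges)
        brute = sum(1 for x in r.residuals if x > np.median(r.residuals))
        assert rep["flagged"].sum() == brute


class TestSelfOverlap:
    def test_ideal_superhelix_turns_separated(self):
        spec = F.SuperhelixSpec()  # pitch 25.9 A
        j = np.arange(1, 147)
        pts = spec.point(spec.junction_angle(j, 147))
        dmin, _ = W.min_cross_turn_distance(pts, j, separation=40)
        assert dmin >= 15.0

    def test_collapsed_pitch_fails(self):
        spec = F.SuperhelixSpec(pitch=1e-9)
        j = np.arange(1, 147)
        pts = spec.point(spec.junction_angle(j, 147))
        dmin, _ = W.min_cross_turn_distance(pts, j, separation=40)
        assert dmin < 4.0

    def test_worst_pair_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 20, (60, 3))
        j = np.arange(1, 61)
        dmin, pair = W.min_cross_turn_distance(pts, j, separation=40)
        brute = min((np.linalg.norm(pts[a] - pts[b]), (a, b))
                    for a in range(60) for b in range(60)
                    if abs(j[a] - j[b]) > 40)
        assert dmin == pytest.approx(brute[0])
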