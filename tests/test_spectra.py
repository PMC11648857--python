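"""Jacobian blocks, eigenvalue reduction, verdicts, correlated pairs."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import trophicstab as ts
from trophicstab._rng import child_rng


def _matched_max_error(a, b):
    """Max distance under the optimal matching of two complex multisets."""
    a, b = np.asarray(a, complex), np.asarray(b, complex)
    assert a.shape == b.shape
    D = np.abs(a[:, None] - b[None, :])
    r, c = linear_sum_assignment(D)
    return float(D[r, c].max())


def _force_identity_selfreg(community, a_eff=1.0):
    """Re-solve supply so the prey block is exactly -a_eff * I (logistic)."""
    community.supply_g = a_eff / community.R_star
    delta, K, _ = ts.solve_consistent_parameters(
        community.C, community.Y, community.H, community.P, community.epsilon,
        community.S_star, community.R_star, "logistic", community.supply_g,
    )
    community.delta, community.supply_K = delta, K
    return community


class TestBuildJacobian:
    def test_unit_community_closed_form(self, unit_community):
        J, parts = ts.build_jacobian(unit_community)
        np.testing.assert_allclose(J, [[0.0, 0.15], [-0.5, -1.0]])
        assert parts.a_eff == pytest.approx(1.0)
        assert np.all(np.linalg.eigvals(J).real < 0)

    def test_blocks_without_H_and_P(self, small_community):
        c = small_community
        assert c.H is None and c.P is None
        _, parts = ts.build_jacobian(c)
        np.testing.assert_allclose(parts.Lambda, c.S_star[:, None] * c.C * c.Y)
        np.testing.assert_allclose(parts.V, -c.C * c.R_star[None, :])

    def test_supply_models_differ_only_in_prey_diagonal(self, rng):
        spec_l = ts.EnsembleSpec(N=5, M=8, sigma_Y=0.2, seed=6)
        c_l = ts.sample_community(spec_l, child_rng(6))
        c_c = ts.sample_community(spec_l.replace(supply_model="chemostat"), child_rng(6))
        # same rng stream -> identical C, Y and fixed point
        np.testing.assert_array_equal(c_l.C, c_c.C)
        J_l, _ = ts.build_jacobian(c_l)
        J_c, _ = ts.build_jacobian(c_c)
        off_diag_mask = ~np.eye(13, dtype=bool)
        np.testing.assert_allclose(J_l[off_diag_mask], J_c[off_diag_mask])
        assert not np.allclose(np.diag(J_l)[5:], np.diag(J_c)[5:])

    def test_prey_selfreg_positive_both_models(self):
        for model in ("logistic", "chemostat"):
            spec = ts.EnsembleSpec(N=4, M=8, sigma_Y=0.3, supply_model=model, seed=15)
            c = ts.sample_community(spec, child_rng(15))
            _, parts = ts.build_jacobian(c)
            assert np.all(parts.prey_selfreg > 0)

    def test_epsilon_fills_predator_diagonal(self):
        spec = ts.EnsembleSpec(N=4, M=8, sigma_Y=0.2, epsilon=0.3, seed=16)
        c = ts.sample_community(spec, child_rng(16))
        J, parts = ts.build_jacobian(c)
        np.testing.assert_allclose(np.diag(J)[:4], -0.3 * c.S_star)
        np.testing.assert_allclose(parts.pred_selfreg, 0.3 * c.S_star)


class TestReducedMatrices:
    def test_ab_ba_nonzero_spectra_agree(self, small_community):
        _, parts = ts.build_jacobian(small_community)
        LVt, VtL = ts.reduced_matrices(parts)
        e_small = np.linalg.eigvals(LVt)  # N=8 < M=16
        e_big = np.linalg.eigvals(VtL)
        e_big_nonzero = e_big[np.argsort(np.abs(e_big))][-e_small.size:]
        assert _matched_max_error(e_small, e_big_nonzero) < 1e-8

    def test_single_pair_reduction_is_negative_scalar(self, unit_community):
        # classic Lotka-Volterra pair: interpredator interaction stable,
        # but the full fixed point need not be
        _, parts = ts.build_jacobian(unit_community)
        LVt, _ = ts.reduced_matrices(parts)
        assert LVt.shape == (1, 1)
        assert LVt[0, 0] < 0

    def test_uniform_positive_yields_give_stable_reduction(self):
        # Y = mu_Y > 0 constant: LVt = -mu_Y D(S*) C D(R*) C^T, similar to
        # negative semidefinite -> all eigenvalue real parts <= 0
        for k in range(20):
            spec = ts.EnsembleSpec(N=6, M=12, sigma_Y=0.0, mu_Y=0.7, seed=500 + k)
            c = ts.sample_community(spec, child_rng(spec.seed))
            _, parts = ts.build_jacobian(c)
            LVt, _ = ts.reduced_matrices(parts)
            assert np.max(np.linalg.eigvals(LVt).real) < 1e-12

    def test_eigenvalue_magnitude_scales_inversely_with_size(self):
        # median |eig(Lambda V^T)| ~ 1/M at fixed N/M: log-log slope -1 +/- 0.2
        Ms = np.array([32, 64, 128, 256])
        med = []
        for M in Ms:
            vals = []
            for k in range(4):
                spec = ts.EnsembleSpec(N=M // 2, M=int(M), sigma_Y=0.4, seed=700 + k)
                c = ts.sample_community(spec, child_rng(spec.seed, M))
                _, parts = ts.build_jacobian(c)
                LVt, _ = ts.reduced_matrices(parts)
                vals.append(np.median(np.abs(np.linalg.eigvals(LVt))))
            med.append(np.mean(vals))
        slope = np.polyfit(np.log(Ms), np.log(med), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)


class TestQuadraticReduction:
    def test_predator_excess_gives_structural_zeros(self):
        out = ts.quadratic_reduction_spectrum(np.array([-1.0, -2.0, -3.0]), 1.0, 5, 3)
        assert out.shape == (8,)
        assert np.sum(out == 0) == 2

    def test_prey_excess_gives_degenerate_selfreg_modes(self):
        out = ts.quadratic_reduction_spectrum(np.array([-1.0, -2.0, -3.0]), 1.0, 3, 5)
        assert out.shape == (8,)
        assert np.sum(out == -1.0) >= 2

    @pytest.mark.parametrize("N,M", [(8, 24), (24, 8), (16, 16), (3, 5), (5, 3)])
    def test_matches_dense_eigensolver_under_identity_selfreg(self, N, M):
        spec = ts.EnsembleSpec(N=N, M=M, sigma_Y=0.5, seed=41)
        c = _force_identity_selfreg(ts.sample_community(spec, child_rng(41, N, M)))
        J, parts = ts.build_jacobian(c)
        LVt, VtL = ts.reduced_matrices(parts)
        lv = np.linalg.eigvals(LVt if N <= M else VtL)
        reduced = ts.quadratic_reduction_spectrum(lv, parts.a_eff, N, M)
        direct = np.linalg.eigvals(J)
        assert _matched_max_error(reduced, direct) < 1e-8

    def test_rejects_wrong_input_length(self):
        with pytest.raises(ValueError):
            ts.quadratic_reduction_spectrum(np.zeros(5), 1.0, 5, 3)


class TestStabilityVerdict:
    def test_diagonal_stable(self):
        report = ts.stability_verdict(np.diag([-1.0, -2.0]))
        assert report.verdict == "stable"
        assert report.spectral_abscissa == pytest.approx(-1.0)

    def test_pure_rotation_marginal(self):
        report = ts.stability_verdict(np.array([[0.0, 1.0], [-1.0, 0.0]]))
        assert report.verdict == "marginal"

    def test_conjugate_symmetry_of_spectrum(self, small_community):
        J, _ = ts.build_jacobian(small_community)
        eigs = ts.stability_verdict(J).eigenvalues
        assert _matched_max_error(eigs, np.conj(eigs)) < 1e-9

    def test_structural_zero_modes_do_not_destabilize(self):
        spec = ts.EnsembleSpec(N=24, M=8, sigma_Y=0.0, seed=44)
        c = ts.sample_community(spec, child_rng(44))
        J, _ = ts.build_jacobian(c)
        report = ts.stability_verdict(J, n_structural=16)
        assert report.n_zero_modes >= 16
        assert report.verdict == "stable"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ts.stability_verdict(np.array([np.nan + 0j, -1.0 + 0j]))

    def test_full_vs_reduced_agreement_on_panel(self):
        # identity-self-regulation approximation: the reduced-matrix verdict
        # agrees with the full Jacobian for >= 95% of mid-size communities
        agree = total = 0
        for k in range(60):
            N, M = (16, 32) if k % 2 else (32, 16)
            spec = ts.EnsembleSpec(N=N, M=M, sigma_Y=0.45, seed=4000 + k)
            c = ts.sample_community(spec, child_rng(spec.seed))
            J, parts = ts.build_jacobian(c)
            full = ts.stability_verdict(J, n_structural=max(0, N - M))
            LVt, VtL = ts.reduced_matrices(parts)
            red_mat = LVt if N <= M else VtL
            reduced = ts.stability_verdict(red_mat)
            if full.verdict == "marginal" or reduced.verdict == "marginal":
                continue
            total += 1
            agree += int(full.verdict == reduced.verdict)
        assert total >= 40
        assert agree >= 0.95 * total


class TestSampleCorrelatedPair:
    def test_perfect_anticorrelation(self, rng):
        L, V = ts.sample_correlated_pair(10, 20, 1.0, rng)
        np.testing.assert_array_equal(L, -V)

    def test_independence_at_rho_zero(self, rng):
        L, V = ts.sample_correlated_pair(300, 400, 0.0, rng)
        corr = np.corrcoef(L.ravel(), V.ravel())[0, 1]
        assert abs(corr) < 3.0 / np.sqrt(L.size)

    def test_aligned_correlation_matches_rho(self, rng):
        L, V = ts.sample_correlated_pair(300, 300, 0.6, rng)
        corr = np.corrcoef(L.ravel(), V.ravel())[0, 1]
        assert corr == pytest.approx(-0.6, abs=0.01)

    def test_element_variance_is_one_over_M(self, rng):
        L, V = ts.sample_correlated_pair(200, 400, 0.5, rng)
        assert np.var(L) == pytest.approx(1 / 400, rel=0.05)
        assert np.var(V) == pytest.approx(1 / 400, rel=0.05)

    def test_rho_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            ts.sample_correlated_pair(4, 4, 1.5, rng)
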