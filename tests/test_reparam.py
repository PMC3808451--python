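"""Reparametrization of interaction coefficients into directed influences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pycape.reparam import (
    InfluenceEstimate,
    influence_jacobian,
    influence_table,
    propagate_errors,
    reparametrize_pairs,
    solve_influences,
    standardized_effects,
)
from pycape.scans import pair_scan
from pycape.simdata import simulate_backcross

from conftest import make_basis, make_cross


def lstsq_oracle(beta1, beta2, beta12):
    """Independent normal-equations solve of the N x 2 system."""
    M = np.column_stack([beta2, beta1])
    return np.linalg.solve(M.T @ M, M.T @ np.asarray(beta12))


def numeric_jacobian(beta1, beta2, beta12, h=1e-6):
    theta0 = np.ravel(np.column_stack([beta1, beta2, beta12]))
    N = len(beta1)

    def f(theta):
        t = theta.reshape(N, 3)
        return solve_influences(t[:, 0], t[:, 1], t[:, 2], cond_tol=1e15)

    J = np.zeros((2, 3 * N))
    for i in range(3 * N):
        hp = theta0.copy(); hp[i] += h * max(abs(theta0[i]), 1.0)
        hm = theta0.copy(); hm[i] -= h * max(abs(theta0[i]), 1.0)
        J[:, i] = (f(hp) - f(hm)) / (hp[i] - hm[i])
    return J


class TestSolveInfluences:
    def test_zero_rhs_gives_zero_influences(self):
        m = solve_influences([1.0, 0.3], [0.2, 1.0], [0.0, 0.0])
        np.testing.assert_allclose(m, [0.0, 0.0], atol=1e-14)

    def test_hand_solved_identity_system(self):
        # M = [[beta2, beta1]] rows = [[0,1],[1,0]]: m12 takes ET2's beta12
        m = solve_influences([1.0, 0.0], [0.0, 1.0], [0.5, -0.2])
        np.testing.assert_allclose(m, [-0.2, 0.5], atol=1e-14)

    def test_forward_generated_system_inverts(self):
        m12, m21 = 0.3, -0.1
        b1, b2 = np.array([2.0, 1.0]), np.array([1.0, 3.0])
        b12 = m12 * b2 + m21 * b1  # = (0.1, 0.8)
        np.testing.assert_allclose(b12, [0.1, 0.8], atol=1e-14)
        np.testing.assert_allclose(solve_influences(b1, b2, b12),
                                   [0.3, -0.1], atol=1e-12)

    @pytest.mark.parametrize("n_ets", [3, 4, 5])
    def test_matches_least_squares_oracle(self, n_ets):
        rng = np.random.default_rng(n_ets)
        for _ in range(50):
            b1 = rng.standard_normal(n_ets)
            b2 = rng.standard_normal(n_ets)
            b12 = rng.standard_normal(n_ets)
            m = solve_influences(b1, b2, b12)
            np.testing.assert_allclose(m, lstsq_oracle(b1, b2, b12),
                                       atol=1e-10)

    def test_least_squares_residual_is_minimal(self):
        rng = np.random.default_rng(9)
        b1, b2, b12 = (rng.standard_normal(4) for _ in range(3))
        M = np.column_stack([b2, b1])
        m = solve_influences(b1, b2, b12)
        best = np.sum((b12 - M @ m) ** 2)
        for g1 in np.linspace(-2, 2, 21):
            for g2 in np.linspace(-2, 2, 21):
                assert best <= np.sum((b12 - M @ [g1, g2]) ** 2) + 1e-12

    def test_near_parallel_system_unresolved(self):
        # beta1 parallel to beta2: direction unidentifiable
        assert solve_influences([1.0, 2.0], [0.5, 1.0 + 1e-12],
                                [0.3, 0.6]) is None

    def test_exactness_two_ets(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            b1, b2, b12 = (rng.standard_normal(2) for _ in range(3))
            m = solve_influences(b1, b2, b12)
            if m is None:
                continue
            recon = m[0] * np.asarray(b2) + m[1] * np.asarray(b1)
            np.testing.assert_allclose(recon, b12, atol=1e-10)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            solve_influences([1.0], [1.0], [1.0])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False, allow_infinity=False),
                    min_size=6, max_size=6))
    def test_exactness_property_any_two_et_system(self, vals):
        b1, b2, b12 = (np.array(vals[i:i + 2]) for i in (0, 2, 4))
        m = solve_influences(b1, b2, b12)
        if m is None:  # ill-conditioned inputs are legitimately unresolved
            return
        np.testing.assert_allclose(m[0] * b2 + m[1] * b1, b12,
                                   atol=1e-6, rtol=1e-6)


class TestRefitEquivalence:
    def test_reduced_model_reproduces_fitted_values(self):
        # with 2 ETs the reparametrization is exact, so replacing beta12 by
        # m12*beta2 + m21*beta1 leaves fitted values and residuals unchanged
        rng = np.random.default_rng(11)
        n = 60
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        E = rng.standard_normal((n, 2))
        cross = make_cross({"a": x1, "b": x2})
        res = pair_scan(cross, make_basis(E), [("a", "b")])
        b1, b2, b12 = res.coef[0, :, 0], res.coef[0, :, 1], res.coef[0, :, 2]
        m = solve_influences(b1, b2, b12)
        b12_recon = m[0] * b2 + m[1] * b1
        X = np.column_stack([np.ones(n), x1, x2, x1 * x2])
        for e in range(2):
            fit_orig = X @ np.r_[res.intercept[0, e], b1[e], b2[e], b12[e]]
            fit_reduced = X @ np.r_[res.intercept[0, e], b1[e], b2[e],
                                    b12_recon[e]]
            np.testing.assert_allclose(fit_reduced, fit_orig, atol=1e-10)


class TestPropagateErrors:
    def test_zero_covariance_gives_zero_se(self):
        b1, b2, b12 = [1.0, 0.2], [0.1, 1.0], [0.4, -0.3]
        m = solve_influences(b1, b2, b12)
        se = propagate_errors(b1, b2, b12, [np.zeros((3, 3))] * 2, m)
        assert se == (0.0, 0.0)

    def test_pass_through_configuration(self):
        # identity-like system: only var(beta12^(j)) nonzero
        b1, b2 = [1.0, 0.0], [0.0, 1.0]
        v1, v2 = 0.04, 0.09
        covs = [np.diag([0.0, 0.0, v1]), np.diag([0.0, 0.0, v2])]
        b12 = [0.5, -0.2]
        m = solve_influences(b1, b2, b12)
        se = propagate_errors(b1, b2, b12, covs, m)
        np.testing.assert_allclose(se, [np.sqrt(v2), np.sqrt(v1)], atol=1e-12)

    @pytest.mark.parametrize("n_ets", [2, 3])
    def test_analytic_jacobian_matches_central_differences(self, n_ets):
        rng = np.random.default_rng(12 + n_ets)
        for _ in range(20):
            b1 = rng.uniform(-2, 2, n_ets)
            b2 = rng.uniform(-2, 2, n_ets)
            b12 = rng.uniform(-1, 1, n_ets)
            m = solve_influences(b1, b2, b12)
            if m is None:
                continue
            J = influence_jacobian(b1, b2, b12, m)
            np.testing.assert_allclose(J, numeric_jacobian(b1, b2, b12),
                                       rtol=1e-5, atol=1e-7)

    def test_delta_method_close_to_monte_carlo(self):
        # small-noise regime where first-order propagation is valid
        rng = np.random.default_rng(13)
        for _ in range(5):
            b1 = rng.uniform(0.5, 2.0, 2) * rng.choice([-1, 1], 2)
            b2 = rng.uniform(0.5, 2.0, 2) * rng.choice([-1, 1], 2)
            if abs(np.linalg.det(np.column_stack([b2, b1]))) < 0.5:
                continue
            b12 = rng.uniform(-0.5, 0.5, 2)
            covs = []
            for _ in range(2):
                A = rng.standard_normal((3, 3)) * 0.02
                covs.append(A @ A.T)
            m = solve_influences(b1, b2, b12)
            se = propagate_errors(b1, b2, b12, covs, m)
            th = np.column_stack([b1, b2, b12])
            d1 = rng.multivariate_normal(th[0], covs[0], size=100_000)
            d2 = rng.multivariate_normal(th[1], covs[1], size=100_000)
            # closed-form 2x2 solve, vectorized (independent of solver path)
            det = d1[:, 1] * d2[:, 0] - d1[:, 0] * d2[:, 1]
            m12 = (d1[:, 2] * d2[:, 0] - d2[:, 2] * d1[:, 0]) / det
            m21 = (d1[:, 1] * d2[:, 2] - d2[:, 1] * d1[:, 2]) / det
            np.testing.assert_allclose(se, [m12.std(), m21.std()], rtol=0.05)


class TestStandardizedEffects:
    def test_definition_and_sign(self):
        est = InfluenceEstimate(("a", "b"), m12=1.0, m21=0.0,
                                se_m12=0.5, se_m21=2.0, status="resolved")
        z12, z21 = standardized_effects(est)
        assert z12 == 2.0 and z21 == 0.0

    def test_zero_se_rejected(self):
        est = InfluenceEstimate(("a", "b"), m12=1.0, m21=1.0,
                                se_m12=0.0, se_m21=1.0, status="resolved")
        with pytest.raises(ValueError):
            standardized_effects(est)

    def test_unit_rescaling_leaves_z_unchanged(self):
        b1, b2, b12 = np.array([1.0, 0.3]), np.array([0.2, 1.0]), \
            np.array([0.4, -0.3])
        covs = [np.diag([0.01, 0.02, 0.03]), np.diag([0.02, 0.01, 0.04])]
        m = solve_influences(b1, b2, b12)
        se = propagate_errors(b1, b2, b12, covs, m)
        # doubling phenotype units doubles betas and quadruples covariances
        m2 = solve_influences(2 * b1, 2 * b2, 2 * b12)
        se2 = propagate_errors(2 * b1, 2 * b2, 2 * b12,
                               [4 * c for c in covs], m2)
        np.testing.assert_allclose(np.asarray(m) / np.asarray(se),
                                   np.asarray(m2) / np.asarray(se2),
                                   atol=1e-10)


class TestDirectionSemantics:
    def test_source_with_private_phenotype_wins_orientation(self):
        # source A affects both phenotypes, target B only the first; the
        # generative influence runs A -> B, so the recovered standardized
        # effect must favor that direction at large n
        rng = np.random.default_rng(14)
        n = 4000
        G, mmap = simulate_backcross(n, [(1, 0.0), (1, 0.0)], 99)
        xa = G["M1_1"].to_numpy()
        xb = G["M2_1"].to_numpy()
        xb_eff = xb * (1 - 0.5 * xa)
        p1 = xa + xb_eff + 0.3 * rng.standard_normal(n)
        p2 = xa + 0.3 * rng.standard_normal(n)
        cross = make_cross({"A": xa, "B": xb},
                           phen={"p1": p1, "p2": p2})
        basis = make_basis(np.column_stack([p1, p2]))
        res = pair_scan(cross, basis, [("A", "B")])
        est = reparametrize_pairs(res)[0]
        assert est.status == "resolved"
        assert abs(est.z_m12) > abs(est.z_m21)
        assert est.m12 < 0  # suppressive


def test_reparametrize_pairs_table(edge_cross):
    from pycape.eigentraits import decompose, normalize_phenotypes
    cross, _ = edge_cross
    Pn, rec = normalize_phenotypes(cross.phenotypes)
    basis = decompose(Pn, rec)
    res = pair_scan(cross, basis, [("M1_3", "M2_3"), ("M1_1", "M2_1")])
    tab = influence_table(reparametrize_pairs(res))
    assert list(tab.columns) == ["marker_1", "marker_2", "m12", "m21",
                                 "se_m12", "se_m21", "z_m12", "z_m21",
                                 "status"]
    assert (tab.status == "resolved").all()
    planted = tab[tab.marker_1 == "M1_3"].iloc[0]
    assert planted.m12 < 0
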