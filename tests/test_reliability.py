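"""Exact reliability, Taylor approximations and their closed-form expectations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gsrel import (
    GenotypeData,
    MarkerPanel,
    ShrinkageMoments,
    UndefinedReliabilityError,
    UShapedModel,
    VarianceSpec,
    approx1_expectation,
    approx1_expectation_standardized,
    approx1_on_genotypes,
    approx2_expectation,
    approx2_expectation_sire_closed,
    approx2_expectation_unrelated_closed,
    approx2_on_genotypes,
    exact_reliability,
    generate_genotypes,
    matrix_T,
    preset_relationship,
    sample_frequencies,
    taylor_series_inverse,
)
from gsrel.moments import UnsupportedRelationshipError


def _random_geno(rng, n_r=60, n_M=80, preset="unrelated"):
    p = sample_frequencies(n_M, n_r, rng=rng)
    return generate_genotypes(preset, p, n_r, rng)


class TestMatrixT:
    def test_identity_relationship(self):
        gamma = 2 / 3
        T = matrix_T(np.eye(5), gamma)
        assert np.allclose(T, np.eye(5) / (1 + gamma))

    def test_sire_block_off_diagonal(self):
        """Direct 2x2 inversion of [[1+g, g/2],[g/2, 1+g]]."""
        g = 2 / 3
        A = np.eye(2)
        A[0, 1] = A[1, 0] = 0.5
        T = matrix_T(A, g)
        expected = -(g / 2) / ((1 + g) ** 2 - g**2 / 4)
        assert T[0, 1] == pytest.approx(expected)

    def test_half_sib_reference_has_xi_i_plus_psi_j_structure(self):
        g = 0.5
        n = 6
        A = np.where(np.eye(n) == 1.0, 1.0, 0.25)
        T = matrix_T(A, g)
        xi_expected = 4.0 / (4.0 + 3.0 * g)
        off = T[~np.eye(n, dtype=bool)]
        psi = off.mean()
        assert np.allclose(off, psi)  # xi I + psi J structure
        assert np.allclose(np.diag(T), T[0, 1] + (xi_expected))

    def test_non_pd_rejected(self):
        A = -2.0 * np.eye(3)
        with pytest.raises(np.linalg.LinAlgError):
            matrix_T(A, 1.0)


class TestTaylorSeries:
    def test_zero_perturbation_is_exact_at_any_order(self):
        base = np.diag([2.0, 3.0, 4.0])
        S, rho = taylor_series_inverse(np.zeros((3, 3)), order=0, base=base)
        assert np.allclose(S, base)
        assert rho == 0.0

    def test_order10_matches_direct_inverse_when_contracting(self, rng):
        """Neumann truncation vs direct inverse on random 50x50 instances.

        The truncation error scales as rho^(order+1); instances are scaled well
        inside the convergent regime so that ten terms reach 1e-8."""
        for _ in range(5):
            Q = rng.standard_normal((50, 50))
            P = 0.15 * Q / np.abs(np.linalg.eigvals(Q)).max()
            S, rho = taylor_series_inverse(P, order=10)
            direct = np.linalg.inv(np.eye(50) + P)
            assert rho < 0.5
            rel = np.abs(S - direct).max() / np.abs(direct).max()
            assert rel < 1e-8


class TestExactReliability:
    def test_limit_small_ridge_full_column_rank(self, rng):
        """lambda -> 0+ with X_r of full column rank projects onto the row space."""
        n_r, n_M = 80, 20
        p = np.full(n_M, 0.5)
        geno = generate_genotypes("unrelated", p, n_r, rng)
        vs = VarianceSpec(nu2=1 - 1e-9)  # gamma -> inf, lambda -> 0
        res = exact_reliability(geno, vs)
        assert res.estimate == pytest.approx(1.0, abs=1e-5)

    def test_zero_candidate_rejected(self, rng):
        p = np.full(10, 0.5)
        geno = generate_genotypes("unrelated", p, 20, rng)
        geno.X[0] = 0.0
        with pytest.raises(UndefinedReliabilityError):
            exact_reliability(geno, VarianceSpec(nu2=0.4))

    def test_both_solver_sides_agree(self, rng, vs04):
        geno = _random_geno(rng, n_r=50, n_M=70)
        res_a = exact_reliability(geno, vs04)
        sub = GenotypeData(X=geno.X[:, :40], panel=MarkerPanel(p=geno.panel.p[:40]))
        # same code path exercised on both branch shapes; cross-check via identity
        lam = vs04.with_tau(geno.tau).lambda_beta
        Xr, xc = geno.X_r, geno.x_c
        direct = xc @ Xr.T @ np.linalg.solve(
            Xr @ Xr.T + lam * np.eye(Xr.shape[0]), Xr @ xc
        ) / (xc @ xc)
        assert res_a.estimate == pytest.approx(direct, rel=1e-10)
        assert 0.0 <= res_a.estimate <= 1.0
        _ = exact_reliability(sub, vs04)  # marker-side branch runs

    @given(seed=st.integers(0, 10**6))
    @settings(derandomize=True, max_examples=10, deadline=None)
    def test_invariance_under_marker_permutation_and_allele_flip(self, seed):
        rng = np.random.default_rng(seed)
        vs = VarianceSpec(nu2=0.4)
        geno = _random_geno(rng, n_r=30, n_M=40)
        base = exact_reliability(geno, vs).estimate
        perm = rng.permutation(geno.n_markers)
        g2 = GenotypeData(X=geno.X[:, perm], panel=MarkerPanel(p=geno.panel.p[perm]))
        assert exact_reliability(g2, vs).estimate == pytest.approx(base, rel=1e-9)
        flip = geno.X.copy()
        flip[:, 0] = -flip[:, 0]  # count the other allele at locus 1
        pf = geno.panel.p.copy()
        pf[0] = 1 - pf[0]
        g3 = GenotypeData(X=flip, panel=MarkerPanel(p=pf))
        assert exact_reliability(g3, vs).estimate == pytest.approx(base, rel=1e-9)


class TestApproximationsOnGenotypes:
    def test_zero_noise_makes_series_order_free(self, vs04):
        """When G* = A tau exactly, D = 0 and all truncation orders coincide."""
        n_r, n_M = 6, 8
        rel = preset_relationship("unrelated", n_r)
        # orthogonal rows scaled so that X X' = I * tau
        X = np.eye(n_r + 1, n_M)
        panel = MarkerPanel(p=np.full(n_M, 0.5))
        X = X * np.sqrt(panel.tau)
        geno = GenotypeData(X=X, panel=panel)
        r0 = approx1_on_genotypes(geno, rel, vs04, order=0, compute_radius=False)
        r10 = approx1_on_genotypes(geno, rel, vs04, order=10, compute_radius=False)
        assert r0.estimate == pytest.approx(r10.estimate, rel=1e-12)

    def test_approx2_order10_equals_exact_when_series_converges(self, rng, vs04):
        """The full Neumann series reproduces (X_r'X_r + I lambda)^{-1}."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            geno = _random_geno(r, n_r=150, n_M=60)
            res = approx2_on_genotypes(geno, vs04, order=40, compute_radius=True)
            if res.spectral_radius >= 0.9:
                continue
            exact = exact_reliability(geno, vs04)
            assert res.estimate == pytest.approx(exact.estimate, abs=1e-6)

    def test_divergent_series_flagged_not_raised(self, rng):
        vs = VarianceSpec(nu2=0.7)
        geno = _random_geno(rng, n_r=100, n_M=50)
        rel = preset_relationship("unrelated", 100)
        res = approx1_on_genotypes(geno, rel, vs, order=10)
        assert res.spectral_radius > 1.0
        assert res.converged is False
        assert res.divergence_warning


class TestClosedFormExpectations:
    def test_approx1_expectation_arithmetic(self):
        """n_r / M_e = 1 at nu2 = 0.4 gives 0.4 / 1.16."""
        rel = preset_relationship("unrelated", 100)
        vs = VarianceSpec(nu2=0.4)
        res = approx1_expectation(rel, vs, tau=100.0, tau2=100.0, n_r=100)
        assert res.estimate == pytest.approx(0.4 / 1.16)

    def test_approx1_expectation_vanishes_with_nu2(self):
        rel = preset_relationship("unrelated", 500)
        res = approx1_expectation(rel, VarianceSpec(nu2=1e-9), tau=50.0, tau2=10.0)
        assert res.estimate == pytest.approx(0.0, abs=1e-6)

    def test_approx1_expectation_unsupported_preset(self):
        rel = preset_relationship("both_parents", 10)
        with pytest.raises(UnsupportedRelationshipError):
            approx1_expectation(rel, VarianceSpec(nu2=0.4), tau=5.0, tau2=1.0)

    def test_eq3_collapses_to_unrelated_closed_form(self):
        vs = VarianceSpec(nu2=0.4)
        n_r, n_M = 1000, 1000
        rel = preset_relationship("unrelated", n_r)
        m = ShrinkageMoments.from_model(UShapedModel(n_r), vs, n_r, n_M)
        general = approx2_expectation(rel, vs, m).estimate
        closed = approx2_expectation_unrelated_closed(vs, n_r, n_M).estimate
        assert general == pytest.approx(closed, rel=1e-12)

    def test_eq3_with_sire_coefficients_equals_sire_closed_form(self):
        vs = VarianceSpec(nu2=0.4)
        n_r, n_M = 1000, 1500
        rel = preset_relationship("sire_in_reference", n_r)
        m = ShrinkageMoments.from_model(UShapedModel(n_r), vs, n_r, n_M)
        general = approx2_expectation(rel, vs, m).estimate
        closed = approx2_expectation_sire_closed(vs, n_r, n_M).estimate
        assert general == pytest.approx(closed, rel=1e-12)

    def test_sire_correction_vanishes_for_large_reference(self):
        """The sire-specific term is O(1/n_r^2)."""
        vs = VarianceSpec(nu2=0.4)
        diffs = []
        for n_r in (1000, 10_000):
            u = approx2_expectation_unrelated_closed(vs, n_r, 500).estimate
            s = approx2_expectation_sire_closed(vs, n_r, 500).estimate
            diffs.append(abs(s - u))
        # explicit factor is 1/n_r^2 but k(Ne=n_r) and h also drift with n_r,
        # so the decay over a decade sits between 1/n_r and 1/n_r^2
        assert diffs[1] < diffs[0] / 20

    def test_no_markers_means_no_shrinkage(self):
        vs = VarianceSpec(nu2=0.4)
        res = approx2_expectation_unrelated_closed(vs, 1000, n_M=0)
        assert res.estimate == pytest.approx(1.0)

    def test_standardized_expectation_consistency(self):
        """zeta = 1 (all p = 0.5) reduces to the centered formula with M_e = n_M."""
        vs = VarianceSpec(nu2=0.4)
        n_M, n_r = 200, 100
        res = approx1_expectation_standardized(vs, zeta=1.0, n_M=n_M, n_r=n_r)
        ratio = (1.0 + n_r - 1.0) / n_M
        assert res.estimate == pytest.approx(0.4 * ratio / (1 + 0.16 * ratio))
        tiny = approx1_expectation_standardized(VarianceSpec(nu2=1e-9), 1.0, n_M, n_r)
        assert tiny.estimate == pytest.approx(0.0, abs=1e-6)
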