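"""GRM construction, PCA, REML, heritability and variance explained."""

import warnings

import numpy as np
import pandas as pd
import pytest

import heightrez as hr
from heightrez.varcomp import _reml_ll_parts


def grm_from_dosages(dosages):
    d = np.asarray(dosages, float)
    meta = pd.DataFrame({
        "variant_id": [f"rs{j}" for j in range(d.shape[1])],
        "chrom": 1, "pos": np.arange(d.shape[1]) + 1,
        "allele1": "A", "allele2": "G", "freq": d.mean(axis=0) / 2})
    geno = hr.GenotypeMatrix(dosages=d, snp_meta=meta,
                             ids=np.arange(d.shape[0]).astype(str))
    return hr.compute_grm(geno)[0]


class TestGrm:
    def test_duplicate_individuals(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 3, size=40).astype(float)
        other = rng.integers(0, 3, size=(3, 40)).astype(float)
        g = grm_from_dosages(np.vstack([row, row, other]))
        assert g[0, 1] == pytest.approx(g[0, 0])

    def test_single_snp_hand_computation(self):
        # dosages (0,2), p=0.5: z = (d-2p)/sqrt(2p(1-p)) = (-sqrt2, sqrt2),
        # so G = zz'/1 = [[2,-2],[-2,2]]
        g = grm_from_dosages(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(g, [[2, -2], [-2, 2]], atol=1e-12)

    def test_monomorphic_dropped_with_warning(self):
        d = np.array([[0.0, 2.0], [0.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="monomorphic"):
            g = grm_from_dosages(d)
        assert g.shape == (3, 3)

    def test_all_monomorphic_errors(self):
        with pytest.raises(hr.DataError):
            grm_from_dosages(np.ones((3, 2)) * 2)


class TestTopPcs:
    def test_identity_grm_unit_eigenvalues(self):
        pcs, vals = hr.top_pcs(np.eye(6), 3)
        np.testing.assert_allclose(vals, 1.0, atol=1e-12)
        np.testing.assert_allclose(pcs.T @ pcs, np.eye(3), atol=1e-8)

    def test_rank_one_grm(self):
        v = np.array([3.0, 1.0, -2.0, 0.5])
        v /= np.linalg.norm(v)
        pcs, vals = hr.top_pcs(np.outer(v, v), 2)
        assert abs(abs(pcs[:, 0] @ v) - 1.0) < 1e-10
        assert vals[1] == pytest.approx(0.0, abs=1e-10)
        # sign convention: largest-magnitude loading positive
        assert pcs[np.argmax(np.abs(pcs[:, 0])), 0] > 0

    def test_orthogonality(self, small_grm):
        g, _ = small_grm
        pcs, _ = hr.top_pcs(g, 5)
        np.testing.assert_allclose(pcs.T @ pcs, np.eye(5), atol=1e-8)

    def test_invalid_k(self):
        with pytest.raises(hr.InvalidParameterError):
            hr.top_pcs(np.eye(4), 0)


class TestReml:
    def test_balanced_one_way_closed_form(self):
        rng = np.random.default_rng(2)
        a, nper = 25, 8
        groups = np.repeat(np.arange(a), nper)
        y = 3.0 + rng.normal(0, np.sqrt(1.5), a)[groups] + rng.normal(0, 1, a * nper)
        fit = hr.reml_fit(y, np.ones((a * nper, 1)), [groups],
                          kernel_names=["group"])
        gm = np.array([y[groups == i].mean() for i in range(a)])
        msw = sum(((y[groups == i] - gm[i]) ** 2).sum() for i in range(a)) / (a * (nper - 1))
        msb = nper * ((gm - gm.mean()) ** 2).sum() / (a - 1)
        assert fit.varcomp["group"] == pytest.approx(max((msb - msw) / nper, 0), abs=1e-6)
        assert fit.varcomp["error"] == pytest.approx(msw, abs=1e-6)

    def test_identity_kernel_non_identifiable_total_matches_ols(self):
        rng = np.random.default_rng(3)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(0, 1.3, n)
        with pytest.warns(UserWarning, match="identifiab"):
            fit = hr.reml_fit(y, X, [np.eye(n)], kernel_names=["g"], method="ai")
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        ols_var = ((y - X @ b) ** 2).sum() / (n - 2)
        total = fit.varcomp["g"] + fit.varcomp["error"]
        assert total == pytest.approx(ols_var, rel=1e-4)

    def test_eigen_path_matches_generic(self, small_sim, small_grm):
        _, _, cohort, _ = small_sim
        g, _ = small_grm
        z = hr.standardize_height(cohort["height_cm"].to_numpy(),
                                  cohort["sex"].to_numpy())
        X = np.column_stack([np.ones(len(z)),
                             (cohort["sex"] == "M").astype(float)])
        fe = hr.reml_fit(z, X, [g], method="eigen")
        fa = hr.reml_fit(z, X, [g], method="ai")
        for k in ("k0", "error"):
            assert fe.varcomp[k] == pytest.approx(fa.varcomp[k], abs=1e-5)
        np.testing.assert_allclose(fe.beta, fa.beta, atol=1e-6)

    def test_kernel_order_and_permutation_invariance(self):
        rng = np.random.default_rng(4)
        n = 120
        groups = rng.integers(0, 12, n)
        blocks = rng.integers(0, 6, n)
        y = (rng.normal(0, 1.0, 12)[groups] + rng.normal(0, 0.8, 6)[blocks]
             + rng.normal(0, 1, n))
        X = np.ones((n, 1))
        f1 = hr.reml_fit(y, X, [groups, blocks], kernel_names=["g", "b"])
        f2 = hr.reml_fit(y, X, [blocks, groups], kernel_names=["b", "g"])
        assert f1.varcomp["g"] == pytest.approx(f2.varcomp["g"], abs=1e-5)
        assert f1.varcomp["b"] == pytest.approx(f2.varcomp["b"], abs=1e-5)
        perm = rng.permutation(n)
        f3 = hr.reml_fit(y[perm], X[perm], [groups[perm], blocks[perm]],
                         kernel_names=["g", "b"])
        assert f3.varcomp["g"] == pytest.approx(f1.varcomp["g"], abs=1e-5)
        assert f3.loglik == pytest.approx(f1.loglik, abs=1e-5)

    def test_rank_deficient_design_names_columns(self):
        n = 40
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(hr.RankDeficiencyError):
            hr.reml_fit(np.zeros(n) + np.arange(n) * 0.01, X,
                        [np.repeat(np.arange(8), 5)])

    def test_haseman_elston_agrees_with_reml(self, small_sim, small_grm):
        _, _, cohort, _ = small_sim
        g, _ = small_grm
        z = hr.standardize_height(cohort["height_cm"].to_numpy(),
                                  cohort["sex"].to_numpy())
        X = np.column_stack([np.ones(len(z)),
                             (cohort["sex"] == "M").astype(float)])
        fit = hr.reml_fit(z, X, [g], kernel_names=["grm"])
        reml_sig = fit.varcomp["grm"]
        reml_se = np.sqrt(fit.varcomp_cov[0, 0])
        he_sig, he_se = hr.haseman_elston(z, g, X)
        joint = np.sqrt(reml_se**2 + he_se**2)
        assert abs(he_sig - reml_sig) < 3 * joint

    def test_gls_orthogonality_at_convergence(self, small_sim, small_grm):
        _, _, cohort, truth = small_sim
        g, _ = small_grm
        n = len(cohort)
        z = hr.standardize_height(cohort["height_cm"].to_numpy(),
                                  cohort["sex"].to_numpy())
        pcs, _ = hr.top_pcs(g, 3)
        X = np.column_stack([np.ones(n), (cohort["sex"] == "M").astype(float), pcs])
        kernels = [g, cohort["household_id"].to_numpy()]
        fit = hr.reml_fit(z, X, kernels, kernel_names=["grm", "hh"])
        V = (fit.varcomp["grm"] * g
             + fit.varcomp["hh"] * (cohort["household_id"].to_numpy()[:, None]
                                    == cohort["household_id"].to_numpy()[None, :])
             + fit.varcomp["error"] * np.eye(n))
        r = z - X @ fit.beta
        score = X.T @ np.linalg.solve(V, r)
        assert np.max(np.abs(score)) < 1e-6


class TestHeritability:
    def _fit(self, sig):
        names = ["grm", "hh", "error"]
        return hr.VarCompFit(beta=np.zeros(1), beta_cov=np.eye(1),
                             beta_names=["intercept"],
                             varcomp=dict(zip(names, sig)),
                             varcomp_cov=np.eye(3) * 1e-4,
                             varcomp_names=names, loglik=0.0,
                             converged=True, n_iter=1)

    def test_zero_genetic_component(self):
        h2, (lo, hi), _ = hr.heritability(self._fit([0.0, 0.2, 0.8]))
        assert h2 == 0.0 and lo == 0.0

    def test_equal_split_grm_plus_error(self):
        h2, _, _ = hr.heritability(self._fit([0.5, 0.3, 0.5]),
                                   denominator="grm_plus_error")
        assert h2 == pytest.approx(0.5)

    def test_denominator_choice_differs(self):
        fit = self._fit([0.5, 0.3, 0.5])
        h_all, _, _ = hr.heritability(fit, denominator="all_components")
        assert h_all == pytest.approx(0.5 / 1.3)


class TestVarianceExplained:
    def test_orthogonal_addition_near_zero(self):
        rng = np.random.default_rng(5)
        n = 500
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        x_add = rng.normal(size=n)
        assert abs(hr.variance_explained(y, X, x_add)) < 0.02

    def test_perfect_predictor(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        r2 = hr.variance_explained(x, np.ones((100, 1)), x)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_collinear_addition_warns_zero(self):
        n = 50
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        with pytest.warns(UserWarning, match="collinear"):
            r2 = hr.variance_explained(np.arange(n, dtype=float), X,
                                       2 * np.arange(n, dtype=float))
        assert r2 == 0.0

    def test_recovery_of_generative_r2(self):
        # PGS == true genetic value at h2=0.36: incremental R2 over
        # intercept+sex recovers the generative share
        reps = []
        for seed in range(5):
            p = hr.SimParams(n_participants=800, n_snps=150, n_families=100,
                             h2_true=0.36, seed=300 + seed)
            geno, cohort, truth = hr.simulate_cohort(p)
            z = hr.standardize_height(cohort["height_cm"].to_numpy(),
                                      cohort["sex"].to_numpy())
            X = np.column_stack([np.ones(len(z)),
                                 (cohort["sex"] == "M").astype(float)])
            reps.append(hr.variance_explained(
                z, X, truth.table["true_genetic_value"].to_numpy()))
        reps = np.array(reps)
        mc_se = reps.std(ddof=1) / np.sqrt(len(reps))
        assert abs(reps.mean() - 0.36) < 3 * mc_se + 0.01
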