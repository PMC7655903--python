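"""REML estimation and BLUP prediction: oracles, invariants, recovery."""

import numpy as np
import pandas as pd
import pytest

import popgs
from popgs import synthetic_data as sd
from popgs.core import ConvergenceError, InvalidParameterError, RelationshipMatrix
from popgs.mixed_model import (fit_multitrait, fit_reml, heritability,
                               predict_gebv, _emreml_mme)


@pytest.fixture(scope="module")
def gmat(popdata):
    return popgs.g_matrix(popdata["geno"])


def _mvn_trait(K, sigma_a, sigma_e, seed, mean=0.0):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(K.values + 1e-9 * np.eye(K.n))
    g = L @ rng.normal(size=K.n) * np.sqrt(sigma_a)
    y = mean + g + rng.normal(size=K.n) * np.sqrt(sigma_e)
    return pd.Series(y, index=K.ids), pd.Series(g, index=K.ids)


class TestFitReml:
    def test_null_signal_shrinks_additive_variance(self, gmat):
        """Pure-noise phenotypes on a real G: additive variance pinned near 0."""
        h2s = []
        for rep in range(10):
            y = pd.Series(np.random.default_rng(rep).normal(size=gmat.n),
                          index=gmat.ids)
            m = fit_reml(y, [("additive", gmat)])
            h2s.append(m.heritability())
        assert np.mean(h2s) < 0.05
        assert np.median(h2s) < 0.02

    def test_scale_equivariance(self, popdata):
        A = popdata["A"]
        y, _ = _mvn_trait(A, 1.0, 1.0, seed=3, mean=5.0)
        m1 = fit_reml(y, [("additive", A)])
        m2 = fit_reml(2.0 * y, [("additive", A)])
        assert m2.vc.components["additive"] == pytest.approx(
            4 * m1.vc.components["additive"], rel=1e-4)
        assert m2.vc.components["residual"] == pytest.approx(
            4 * m1.vc.components["residual"], rel=1e-4)
        assert np.allclose(m2.gebv, 2 * m1.gebv, rtol=1e-4, atol=1e-8)
        assert m2.heritability() == pytest.approx(m1.heritability(), rel=1e-4)

    def test_loglik_trace_is_monotone(self, popdata, gmat):
        A = popdata["A"]
        y, _ = _mvn_trait(A, 1.0, 1.0, seed=4)
        for terms in ([("additive", A)], [("additive", gmat)]):
            m = fit_reml(y, terms)
            assert np.all(np.diff(m.loglik_trace) >= -1e-8)
        D = popgs.regularize(popgs.d_matrix_pedigree(popdata["ped"]), 1e-6)
        m2 = fit_reml(y, [("additive", popgs.regularize(A, 1e-6)),
                          ("dominance", D)])
        assert np.all(np.diff(m2.loglik_trace) >= -1e-8)

    def test_h2_recovery_is_unbiased(self, popdata):
        """Mean REML h2 over replicate traits drawn from A recovers truth."""
        A = popdata["A"]
        h2s = []
        for rep in range(15):
            y, _ = _mvn_trait(A, 1.0, 1.0, seed=100 + rep)  # true h2 = 0.5
            h2s.append(fit_reml(y, [("additive", A)]).heritability())
        assert abs(np.mean(h2s) - 0.5) < 0.07

    def test_nonconvergence_raises_with_last_iterate(self, popdata):
        A = popdata["A"]
        y, _ = _mvn_trait(A, 1.0, 1.0, seed=5)
        with pytest.raises(ConvergenceError) as err:
            fit_reml(y, [("additive", A)], max_iter=1, tol_loglik=1e-16,
                     tol_var=1e-16)
        assert err.value.model is not None
        assert err.value.model.converged is False

    def test_too_few_phenotypes_rejected(self, popdata):
        y = pd.Series([1.0], index=[popdata["A"].ids[0]])
        with pytest.raises(InvalidParameterError):
            fit_reml(y, [("additive", popdata["A"])])

    def test_aic_prefers_additive_when_no_dominance(self, popdata):
        """AIC(additive) <= AIC(additive+dominance) for additive-only truth."""
        ids = popdata["A"].ids[:150]
        A = popgs.regularize(popdata["A"].submatrix(ids), 1e-6)
        D = popgs.regularize(
            popgs.d_matrix_pedigree(popdata["ped"]).submatrix(ids), 1e-6)
        wins = 0
        n_rep = 30
        for rep in range(n_rep):
            y, _ = _mvn_trait(A, 1.0, 1.0, seed=200 + rep)
            m_add = fit_reml(y, [("additive", A)])
            m_dom = fit_reml(y, [("additive", A), ("dominance", D)],
                             raise_on_nonconvergence=False)
            if m_add.aic <= m_dom.aic:
                wins += 1
        assert wins >= 0.8 * n_rep


class TestBlupPrediction:
    def test_unconnected_individual_predicts_zero(self):
        V = np.eye(4)
        V[:3, :3] += 0.4
        K = RelationshipMatrix(ids=list("abcd"), values=V)
        y = pd.Series([1.0, 2.0, 0.5], index=list("abc"))
        m = fit_reml(y, [("additive", K)], raise_on_nonconvergence=False)
        assert m.gebv.loc["d"] == pytest.approx(0.0, abs=1e-10)

    def test_unknown_id_rejected(self, popdata):
        A = popdata["A"]
        y, _ = _mvn_trait(A, 1.0, 1.0, seed=6)
        m = fit_reml(y, [("additive", A)])
        with pytest.raises(InvalidParameterError):
            predict_gebv(m, ["not-an-id"])

    def test_gblup_equals_snp_blup_ridge_oracle(self):
        """G-BLUP GEBVs match ridge-regression SNP-BLUP with matched scaling."""
        rng = np.random.default_rng(11)
        n, m_markers = 200, 1000
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, m_markers),
                           size=(n, m_markers)).astype(float)
        geno = popgs.GenotypeMatrix(
            ids=[f"i{k}" for k in range(n)], dosages=dos,
            markers=pd.DataFrame({"marker": [f"m{j}" for j in range(m_markers)],
                                  "chrom": "c1",
                                  "pos_bp": np.arange(m_markers) + 1}))
        G = popgs.g_matrix(geno)
        qtl = rng.choice(m_markers, 50, replace=False)
        Mc = dos - dos.mean(axis=0)
        g_true = Mc[:, qtl] @ rng.normal(size=50) * 0.2
        y = pd.Series(g_true + rng.normal(size=n) * g_true.std(),
                      index=geno.ids)
        fit = fit_reml(y, [("additive", G)])
        sa, se = (fit.vc.components["additive"],
                  fit.vc.components["residual"])
        # independent SNP-BLUP oracle: ridge with lambda = c * se / sa
        lam = G.scale * se / sa
        mu = fit.beta[0]
        a_hat = np.linalg.solve(Mc.T @ Mc + lam * np.eye(m_markers),
                                Mc.T @ (y.to_numpy() - mu))
        snp_gebv = Mc @ a_hat
        r = np.corrcoef(fit.gebv.loc[geno.ids], snp_gebv)[0, 1]
        assert r > 0.999

    def test_masked_prediction_tracks_genetic_value_not_noise(self, popdata):
        A = popdata["A"]
        y, g = _mvn_trait(A, 1.0, 1.0, seed=7)  # h2 = 0.5
        rng = np.random.default_rng(8)
        masked = list(rng.choice(A.ids, 60, replace=False))
        train = y.drop(masked)
        m = fit_reml(train, [("additive", A)])
        pred = m.gebv.loc[masked]
        noise = (y - g).loc[masked]
        r_tbv = np.corrcoef(pred, g.loc[masked])[0, 1]
        r_noise = np.corrcoef(pred, noise)[0, 1]
        assert r_tbv > abs(r_noise)
        assert r_tbv > 0.3

    def test_a_and_g_models_agree_on_progeny_tested_parents(self, popdata):
        """Expected (A) and realized (G) relationships carry the same
        information at the family level: parental GEBVs coincide."""
        ped, founders = popdata["ped"], popdata["founders"]
        big = sd.simulate_founders(12, 11, 10_000, n_chromosomes=19, seed=21,
                                   sire_ids=popdata["design"].sires,
                                   dam_ids=popdata["design"].dams)
        geno = sd.drop_genes(ped, big, seed=22)
        A, G = popdata["A"], popgs.g_matrix(geno)
        y, _ = _mvn_trait(A, 1.0, 1.0, seed=23)
        mA = fit_reml(y, [("additive", A)])
        mG = fit_reml(y, [("additive", G)])
        parents = popdata["design"].founders
        r_par = np.corrcoef(mA.gebv.loc[parents], mG.gebv.loc[parents])[0, 1]
        r_all = np.corrcoef(mA.gebv, mG.gebv.loc[mA.gebv.index])[0, 1]
        assert r_par > 0.99
        assert r_all > 0.9


class TestHeritability:
    @pytest.mark.parametrize("comps,expected", [
        ({"additive": 1.0, "residual": 1.0}, 0.5),
        ({"additive": 0.0, "residual": 2.0}, 0.0),
        ({"additive": 3.0, "dominance": 1.0, "residual": 1.0}, 0.6),
    ])
    def test_arithmetic(self, comps, expected):
        assert heritability(comps) == pytest.approx(expected)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            heritability({"additive": 0.0, "residual": 0.0})


@pytest.fixture(scope="module")
def big_A(study_design):
    crosses = [(s, d, max(2, int(round(n * 0.8))))
               for s, d, n in study_design.crosses]
    des = sd.MatingDesign(sires=study_design.sires,
                          dams=study_design.dams, crosses=crosses)
    ped = sd.simulate_pedigree(des)
    return popgs.a_matrix(ped)


class TestMultitrait:
    def _mvn_traits(self, K, G0, R0, seed):
        rng = np.random.default_rng(seed)
        t = G0.shape[0]
        L = np.linalg.cholesky(K.values + 1e-9 * np.eye(K.n))
        U = L @ rng.normal(size=(K.n, t)) @ np.linalg.cholesky(G0).T
        E = rng.normal(size=(K.n, t)) @ np.linalg.cholesky(R0).T
        return pd.DataFrame(U + E, index=K.ids,
                            columns=[f"t{j}" for j in range(t)]), U

    def test_independent_traits_estimate_near_zero_correlation(self, big_A):
        Y, _ = self._mvn_traits(big_A, np.eye(2), np.eye(2), seed=31)
        m = fit_multitrait(Y, big_A, raise_on_nonconvergence=False)
        assert abs(m.vc.genetic_correlations()[0, 1]) < 0.2

    def test_strong_genetic_correlation_recovered(self, big_A):
        G0 = np.array([[1.0, 0.8], [0.8, 1.0]])
        Y, _ = self._mvn_traits(big_A, G0, np.eye(2), seed=32)
        m = fit_multitrait(Y, big_A, raise_on_nonconvergence=False)
        assert m.vc.genetic_correlations()[0, 1] == pytest.approx(0.8,
                                                                  abs=0.15)

    def test_duplicated_trait_hits_correlation_boundary(self, popdata):
        A = popdata["A"]
        y, _ = _mvn_trait(A, 1.0, 0.5, seed=33)
        Y = pd.DataFrame({"t1": y, "t2": y})
        with pytest.warns(UserWarning, match="boundary"):
            m = fit_multitrait(Y, A, raise_on_nonconvergence=False)
        assert m.diagnostics["correlation_at_boundary"]
        assert m.vc.genetic_correlations()[0, 1] > 0.99

    def test_missing_values_handled_traitwise(self, popdata):
        A = popdata["A"].submatrix(popdata["A"].ids[:120])
        G0 = np.array([[1.0, 0.6], [0.6, 1.0]])
        Y, U = self._mvn_traits(A, G0, 0.5 * np.eye(2), seed=34)
        rng = np.random.default_rng(35)
        Y_miss = Y.mask(rng.uniform(size=Y.shape) < 0.25)
        m = fit_multitrait(Y_miss, A, raise_on_nonconvergence=False)
        assert np.all(np.diff(m.loglik_trace) >= -1e-7)
        # predictions still track the true genetic values of both traits
        for j in range(2):
            r = np.corrcoef(m.blups[f"t{j}"].loc[A.ids], U[:, j])[0, 1]
            assert r > 0.5

    def test_per_trait_gebvs_returned_for_all_ids(self, popdata):
        A = popdata["A"]
        Y, _ = self._mvn_traits(A.submatrix(A.ids[:100]), np.eye(2),
                                np.eye(2), seed=36)
        m = fit_multitrait(Y, A, raise_on_nonconvergence=False)
        assert len(m.blups["t0"]) == A.n


class TestMmeEngine:
    def test_solution_satisfies_normal_equations(self):
        rng = np.random.default_rng(44)
        ng, nb, c = 40, 3, 8
        B = rng.normal(size=(ng, 80))
        Kg = B @ B.T / 80 + 0.05 * np.eye(ng)
        Zg = np.tile(np.eye(ng), (nb, 1))
        Zs = rng.uniform(size=(ng * nb, c))
        y = (Zg @ (np.linalg.cholesky(Kg) @ rng.normal(size=ng))
             + Zs @ rng.normal(size=c) * 0.5 + rng.normal(size=ng * nb))
        X = np.ones((ng * nb, 1))
        Kinv = np.linalg.inv(Kg)
        theta, ll, trace, conv, nit, sol, offs = _emreml_mme(
            y, X, [Zg, Zs], [Kg, None], [Kinv, np.eye(c)],
            [np.linalg.slogdet(Kg)[1], 0.0])
        assert conv
        assert np.all(np.diff(trace) >= -1e-8)
        # residual of the mixed-model equations at the solution
        W = np.hstack([X, Zg, Zs])
        M = W.T @ W / theta[-1]
        M[offs[0]:offs[1], offs[0]:offs[1]] += Kinv / theta[0]
        M[offs[1]:offs[2], offs[1]:offs[2]] += np.eye(c) / theta[1]
        rhs = W.T @ y / theta[-1]
        rel = np.linalg.norm(M @ sol - rhs) / np.linalg.norm(rhs)
        assert rel < 1e-6
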