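"""Mixed-model equations, leverages, and EM-REML."""

import numpy as np
import pytest
import scipy.sparse as sp

import uniblup as ub
from uniblup.dhglm import compute_dispersion_response
from uniblup.mme import (
    MMEState,
    RandomTerm,
    fit_univariate_reml,
    reml_update,
    solve_mixed_model,
)


def _one_way(n_groups, per, s2g, s2e, seed):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per)
    y = rng.normal(0, np.sqrt(s2g), n_groups)[g] + rng.normal(0, np.sqrt(s2e), len(g))
    Z = sp.csr_matrix((np.ones(len(g)), (np.arange(len(g)), g)))
    return y, np.ones((len(g), 1)), Z


class TestSolve:
    def test_weighted_mean_and_leverages(self):
        y = np.array([1.0, 2.0, 4.0])
        w = np.array([1.0, 2.0, 1.0])
        sol = solve_mixed_model(y, np.ones((3, 1)), [], {}, 1.0, residual_weights=w)
        assert sol.fixed[0] == pytest.approx(np.sum(w * y) / w.sum())
        assert sol.hat_values == pytest.approx(w / w.sum())

    def test_ridge_limit_shrinks_random_solutions(self):
        y, X, Z = _one_way(8, 5, 1.0, 1.0, seed=0)
        norms = []
        for ratio in (1.0, 10.0, 100.0):
            sol = solve_mixed_model(y, X, [RandomTerm("g", Z)], {"g": 1.0 / ratio}, 1.0)
            norms.append(np.abs(sol.random["g"]).max())
        assert norms[0] > norms[1] > norms[2]

    def test_solutions_match_dense_gls(self):
        """MME solutions equal explicit GLS with V = Z K Z' s2 + R at n=30."""
        rng = np.random.default_rng(1)
        n, q = 30, 6
        K = rng.standard_normal((q, q))
        K = K @ K.T + q * np.eye(q)
        Z = sp.csr_matrix(rng.binomial(1, 0.4, size=(n, q)).astype(float))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        w = rng.uniform(0.5, 2.0, n)
        s2a, s2e = 0.7, 1.3
        y = rng.standard_normal(n) * 2
        sol = solve_mixed_model(
            y, X, [RandomTerm("a", Z, np.linalg.inv(K))], {"a": s2a}, s2e,
            residual_weights=w,
        )
        V = (Z @ (s2a * K) @ Z.T).toarray() if sp.issparse(Z @ (s2a * K) @ Z.T) else Z.toarray() @ (s2a * K) @ Z.toarray().T
        V = Z.toarray() @ (s2a * K) @ Z.toarray().T + np.diag(s2e / w)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = s2a * K @ Z.toarray().T @ Vi @ (y - X @ beta)
        assert np.abs(sol.fixed - beta).max() < 1e-8
        assert np.abs(sol.random["a"] - u).max() < 1e-8

    def test_confounded_design_raises(self):
        X = np.column_stack([np.ones(4), np.ones(4)])  # duplicated intercept
        with pytest.raises(np.linalg.LinAlgError, match="confounded"):
            solve_mixed_model(np.arange(4.0), X, [], {}, 1.0)


class TestDispersionResponse:
    @pytest.mark.parametrize(
        "e,h,s2,expected",
        [(1.0, 0.0, 1.0, 0.0), (0.0, 0.0, 1.0, -1.0), (2.0, 0.5, 1.0, 7.0)],
    )
    def test_unit_cases(self, e, h, s2, expected):
        psi = compute_dispersion_response(
            np.array([e]), np.array([h]), np.array([s2])
        )
        assert psi[0] == pytest.approx(expected)

    def test_degenerate_leverage_rejected(self):
        with pytest.raises(ValueError, match="leverage"):
            compute_dispersion_response(np.ones(1), np.ones(1), np.ones(1))


class TestEmReml:
    def test_balanced_sire_model_matches_anova_closed_form(self):
        s_count, per = 50, 20
        y, X, Z = _one_way(s_count, per, 0.2, 0.8, seed=2)
        v, s2e, sol, trace, conv = fit_univariate_reml(
            y, X, [RandomTerm("s", Z)], tol=1e-10, max_iter=500
        )
        gm = y.reshape(s_count, per)
        msb = per * np.sum((gm.mean(1) - y.mean()) ** 2) / (s_count - 1)
        msw = np.sum((gm - gm.mean(1, keepdims=True)) ** 2) / (s_count * (per - 1))
        assert conv
        assert v["s"] == pytest.approx((msb - msw) / per, abs=1e-4)
        assert s2e == pytest.approx(msw, abs=1e-4)

    def test_update_is_fixed_point_at_true_components(self):
        # large balanced design: one EM step from the REML optimum moves < 1e-3
        s_count, per = 60, 25
        y, X, Z = _one_way(s_count, per, 0.5, 1.0, seed=3)
        v, s2e, *_ = fit_univariate_reml(
            y, X, [RandomTerm("s", Z)], tol=1e-12, max_iter=800
        )
        state = MMEState(y=y, X=X, terms=[RandomTerm("s", Z)])
        new_v, new_s2e, _, _ = reml_update(state, v, s2e)
        assert abs(new_v["s"] - v["s"]) / v["s"] < 1e-3
        assert abs(new_s2e - s2e) / s2e < 1e-3

    def test_zero_variance_truth_hits_lower_bound(self):
        y, X, Z = _one_way(30, 10, 0.0, 1.0, seed=4)
        v, s2e, sol, trace, conv = fit_univariate_reml(
            y, X, [RandomTerm("s", Z)], tol=1e-9, max_iter=500
        )
        assert v["s"] < 1e-3

    def test_loglik_nondecreasing_along_em_path(self):
        y, X, Z = _one_way(25, 8, 0.3, 0.7, seed=5)
        state = MMEState(y=y, X=X, terms=[RandomTerm("s", Z)])
        variances, s2e = {"s": 0.05}, 1.5
        lls = []
        for _ in range(40):
            variances, s2e, ll, _ = reml_update(state, variances, s2e)
            lls.append(ll)
        diffs = np.diff(lls)
        assert (diffs > -1e-9).all()


class TestReliabilityMonotonicity:
    def test_adding_a_sibs_record_never_reduces_reliability(self):
        """Prediction-error variance of a candidate cannot grow when a
        full-sib gains a phenotype (information monotonicity)."""
        ped = ub.Pedigree.from_records(
            [("S", None, None), ("D", None, None)]
            + [(f"O{i}", "S", "D") for i in range(1, 6)]
        )
        A = ub.build_numerator_relationship(ped)
        A_inv = np.linalg.inv(A.values)
        s2a, s2e = 0.4, 0.6
        rng = np.random.default_rng(6)
        y_full = rng.standard_normal(4)
        pev = []
        for n_rec in (3, 4):  # candidate O5 never has a record
            rows = np.arange(n_rec)
            cols = [ped.index_of(f"O{i+1}") for i in range(n_rec)]
            Z = sp.csr_matrix(
                (np.ones(n_rec), (rows, cols)), shape=(n_rec, ped.n)
            )
            sol = solve_mixed_model(
                y_full[:n_rec], np.ones((n_rec, 1)),
                [RandomTerm("a", Z, A_inv)], {"a": s2a}, s2e, return_C_inv=True,
            )
            i_cand = 1 + ped.index_of("O5")  # offset: 1 fixed effect
            pev.append(sol.C_inv[i_cand, i_cand])
        assert pev[1] <= pev[0] + 1e-12
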