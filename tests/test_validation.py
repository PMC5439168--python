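"""Cross-validation machinery: folds, metrics, residual comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import uniblup as ub


def _pheno_with_families(sizes, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for f, size in enumerate(sizes):
        for j in range(size):
            rows.append(
                (
                    f"F{f}_{j}",
                    float(900 + 30 * rng.standard_normal()),
                    int(rng.integers(470, 500)),
                    "T1",
                    "y1",
                    f"F{f}",
                )
            )
    return ub.PhenotypeTable(
        pd.DataFrame(
            rows, columns=["animal", "weight", "age", "tank", "year_class", "family"]
        )
    )


class TestMakeFolds:
    def test_exact_divisibility_one_per_family(self):
        ph = _pheno_with_families([10] * 10)
        plan = ub.make_folds(ph, k=10, seed=1)
        for mask in plan.masks:
            assert len(mask) == 10
            fams = {a.split("_")[0] for a in mask}
            assert len(fams) == 10  # one animal from each family

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_property(self, seed):
        ph = _pheno_with_families([4, 7, 13, 2, 9], seed=seed)
        with pytest.warns(UserWarning, match="smaller than k"):
            plan = ub.make_folds(ph, k=10, seed=seed)
        union = set().union(*plan.masks)
        assert union == set(ph.animals)
        assert sum(len(m) for m in plan.masks) == len(ph)  # disjoint

    def test_seed_reproducibility(self):
        ph = _pheno_with_families([12, 15, 20])
        p1 = ub.make_folds(ph, k=5, seed=42)
        p2 = ub.make_folds(ph, k=5, seed=42)
        p3 = ub.make_folds(ph, k=5, seed=43)
        assert p1.masks == p2.masks
        assert p1.masks != p3.masks
        assert sorted(map(len, p1.masks)) == sorted(map(len, p3.masks))


class TestMsep:
    def test_identities(self):
        t = np.array([1.0, 2.0, 4.0, 7.0])
        assert ub.msep_scaled(t, t) == 0.0
        # constant prediction at the mean: MSE = population variance = (n-1)/n * sample var
        n = len(t)
        expected = (n - 1) / n
        assert ub.msep_scaled(np.full(n, t.mean()), t) == pytest.approx(expected)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        p, t = rng.standard_normal(50), rng.standard_normal(50)
        brute = np.mean([(a - b) ** 2 for a, b in zip(p, t)]) / np.var(t, ddof=1)
        assert ub.msep_scaled(p, t) == pytest.approx(brute)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ub.msep_scaled(np.arange(3.0), np.ones(3))


class TestRankCorrelations:
    def test_monotone_perfect(self):
        x = np.arange(10.0)
        tau, rho = ub.rank_correlations(x, np.exp(x))
        assert tau == pytest.approx(1.0) and rho == pytest.approx(1.0)
        tau, rho = ub.rank_correlations(x, -x**3)
        assert tau == pytest.approx(-1.0) and rho == pytest.approx(-1.0)

    def test_tau_b_matches_pair_count_with_ties(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 1.0, 3.0, 3.0, 2.0])
        tau, _ = ub.rank_correlations(x, y)
        # O(n^2) tau-b: concordant minus discordant over tie-corrected pairs
        conc = disc = tx = ty = 0
        n = len(x)
        for i in range(n):
            for j in range(i + 1, n):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    tx += 1
                    ty += 1
                elif dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        n0 = n * (n - 1) / 2
        brute = (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))
        assert tau == pytest.approx(brute)

    def test_constant_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            tau, rho = ub.rank_correlations(np.ones(5), np.arange(5.0))
        assert np.isnan(tau) and np.isnan(rho)


class TestDifferenceCi:
    def test_identical_models_not_significant(self):
        m = np.array([0.3, 0.35, 0.4])
        d, lo, hi, sig = ub.difference_ci(m, m)
        assert d == 0.0 and lo <= 0.0 <= hi and not sig

    def test_constant_offset_significant(self):
        m1 = np.full(5, 0.5)
        m2 = np.full(5, -0.5)
        d, lo, hi, sig = ub.difference_ci(m1, m2)
        assert d == pytest.approx(1.0) and lo == hi == pytest.approx(1.0) and sig

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(4)
        m1, m2 = rng.standard_normal(10), rng.standard_normal(10)
        d, lo, hi, sig = ub.difference_ci(m1, m2)
        se = np.sqrt((m1.std(ddof=1) ** 2 + m2.std(ddof=1) ** 2) / 10)
        assert d == pytest.approx(m1.mean() - m2.mean())
        assert hi - d == pytest.approx(1.96 * se)


class TestAdjustedPhenotypes:
    def test_reconstruction_identity(self, small_fit):
        """y* plus the fitted fixed effects reconstructs the response."""
        data, spec, kin, y, fit = small_fit
        y_star, psi_star = ub.adjusted_phenotypes(fit)
        X = fit._designs["X"]
        fixed_part = X @ fit.fixed_mean
        assert np.abs(y_star.to_numpy() + fixed_part - y).max() < 1e-8

    def test_assembly_matches_solution_vectors(self, small_fit):
        data, spec, kin, y, fit = small_fit
        y_star, psi_star = ub.adjusted_phenotypes(fit)
        d = fit._designs
        hand = d["T"] @ fit.ebv_mean + d["Q"] @ fit.common_mean + fit.residuals
        assert np.abs(y_star.to_numpy() - hand).max() < 1e-12


class TestCompareResiduals:
    def test_identical_fits_give_unit_slope(self, small_fit):
        data, spec, kin, y, fit = small_fit
        out = ub.compare_residual_estimates(fit, fit, data.genotyped_ids)
        for _, row in out.iterrows():
            assert row["slope"] == pytest.approx(1.0)
            assert row["pearson"] == pytest.approx(1.0)

    def test_record_mismatch_rejected(self, small_fit):
        data, spec, kin, y, fit = small_fit
        import copy

        other = copy.copy(fit)
        other.animals = list(fit.animals[::-1])
        with pytest.raises(ValueError, match="records"):
            ub.compare_residual_estimates(fit, other, [])


class TestRunCrossval:
    def test_perfect_and_null_predictions(self, small_fit):
        """Metric identities on synthetic predictions: correlations 1 and
        MSEP 0 for perfect predictors."""
        rng = np.random.default_rng(5)
        y_star = rng.standard_normal(30)
        assert ub.msep_scaled(y_star, y_star) == 0.0
        assert stats.pearsonr(y_star, y_star).statistic == pytest.approx(1.0)

    def test_report_structure(self, small_fit):
        data, spec, kin, y, fit = small_fit
        plan = ub.make_folds(data.phenotypes, k=5, seed=0)
        report = ub.run_crossval(
            data.phenotypes, spec, fit.varcomps, plan, data.genotyped_ids,
            kin, data.pedigree, fit, response=y,
        )
        s = report.summary()
        assert set(s["trait"]) == {"weight", "uniformity"}
        vals = report.fold_values("uniformity", "pearson")
        assert len(vals) == 5 - len(report.excluded_folds)
        assert np.all(np.abs(vals) <= 1.0)
        msep = report.fold_values("weight", "msep_scaled")
        assert (msep >= 0).all()


class TestResidualDivergencePattern:
    def test_animal_model_residuals_diverge_more_for_genotyped(self):
        """Genomic information reshapes residual estimates of genotyped
        animals far more under the animal model than under the sire-dam
        model: the A-vs-H residual correlation for genotyped animals drops
        under the animal model while the sire-dam model's stays near 1."""
        cfg = ub.SimConfig(
            n_sires=35, n_dams=60, family_size_mean=18.0,
            family_size_range=(14, 24), family_size_sigma=0.2, n_snps=300,
            genotyped_families=50, genotyped_sibs_range=(16, 20), seed=710,
        )
        data = ub.simulate_dataset(cfg)
        geno, _ = ub.qc_snps(data.genotypes)
        rels = ub.build_relationship_set(data.pedigree, ub.scale_genotypes(geno))
        sd_spec = ub.ModelSpec(genetic_param="sire_dam", relationship="A")
        kin_sd = ub.kinship_inverse_for(sd_spec, rels, data.pedigree)
        y, _ = ub.standardize(data.phenotypes.weight)
        est = ub.fit_dhglm(data.phenotypes, sd_spec, kin_sd, data.pedigree, response=y)

        corr = {}
        for param in ("sire_dam", "animal"):
            fits = {}
            for rel in ("A", "H"):
                spec = ub.ModelSpec(genetic_param=param, relationship=rel)
                kin = ub.kinship_inverse_for(spec, rels, data.pedigree)
                vc = est.varcomps.to_animal() if param == "animal" else est.varcomps
                fits[rel] = ub.blup_full_fit(
                    data.phenotypes, spec, vc, kin, data.pedigree, response=y
                )
            table = ub.compare_residual_estimates(
                fits["A"], fits["H"], data.genotyped_ids
            ).set_index("group")
            corr[param] = table.loc["genotyped", "pearson"]
        assert corr["animal"] < corr["sire_dam"]
        assert corr["sire_dam"] > 0.95


class TestResidualScatterExport:
    def test_scatter_frame_matches_fit_residuals(self, small_fit):
        data, spec, kin, y, fit = small_fit
        df = ub.residual_scatter(fit, fit, data.genotyped_ids)
        assert list(df.columns) == ["animal", "residual_A", "residual_H", "group"]
        assert len(df) == len(fit.animals)
        assert np.allclose(df["residual_A"], fit.residuals)
        assert set(df["group"]) <= {"genotyped", "non_genotyped"}
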