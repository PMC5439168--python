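"""Bivariate DHGLM fitting and BLUP-only prediction."""

import numpy as np
import pandas as pd
import pytest

import uniblup as ub
from uniblup.mme import RandomTerm, fit_univariate_reml
from uniblup.dhglm import (
    ModelSpec,
    VarianceComponents,
    common_env_design,
    fixed_effects_design,
    genetic_design,
    predict_breeding_values,
)


class TestVarianceComponents:
    def test_sire_dam_to_animal_conversion(self):
        vc = VarianceComponents(
            genetic=np.array([[0.05, 0.01], [0.01, 0.06]]),
            common=np.eye(2) * 0.1,
            sigma2_e=0.6,
            scaled_eps=(1.0, 1.0),
            genetic_param="sire_dam",
        )
        assert vc.sigma2_a == pytest.approx(0.2)
        assert vc.sigma2_av_exp == pytest.approx(0.24)
        animal = vc.to_animal()
        assert animal.sigma2_a == pytest.approx(0.2)
        assert animal.genetic[0, 0] == pytest.approx(0.2)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            VarianceComponents(
                genetic=np.array([[0.01, 0.5], [0.5, 0.01]]),
                common=np.eye(2),
                sigma2_e=1.0,
                scaled_eps=(1.0, 1.0),
            )


class TestFitProperties:
    def test_fit_invariants(self, small_fit):
        data, spec, kin, y, fit = small_fit
        assert fit.converged
        h = fit.hat_values
        assert (h >= 0).all() and (h < 1).all()
        assert (fit.fitted_resid_var > 0).all()
        eps, eps_v = fit.varcomps.scaled_eps
        assert 0.8 <= eps <= 1.2
        assert 0.8 <= eps_v <= 1.2

    def test_homoscedastic_reduction_matches_univariate_reml(self):
        """With the dispersion sub-model held at its intercept, the mean-model
        components agree with a plain homoscedastic REML fit within 1%."""
        cfg = ub.SimConfig(
            n_sires=25, n_dams=45, family_size_mean=14.0, family_size_range=(8, 22),
            family_size_sigma=0.3, n_snps=10, genotyped_families=0, seed=17,
            sigma2_a=0.25, sigma2_av_exp=0.0, sigma2_c=0.1, sigma2_cv_exp=0.0,
            sigma2_e=0.65, r_g_mean_disp=0.0,
        )
        data = ub.simulate_dataset(cfg)
        rels = ub.build_relationship_set(data.pedigree)
        spec = ModelSpec(genetic_param="sire_dam", relationship="A")
        kin = ub.kinship_inverse_for(spec, rels, data.pedigree)
        y, _ = ub.standardize(data.phenotypes.weight)
        fit = ub.fit_dhglm(
            data.phenotypes, spec, kin, data.pedigree, response=y,
            estimate_dispersion=False, max_outer=150, param_tol=1e-5,
        )
        X, _ = fixed_effects_design(data.phenotypes)
        T = genetic_design(data.phenotypes, data.pedigree, spec, kin.ids)
        Q, _ = common_env_design(data.phenotypes, data.pedigree)
        v, s2e, *_ = fit_univariate_reml(
            y, X, [RandomTerm("u", T, kin.values), RandomTerm("c", Q)],
            tol=1e-9, max_iter=400,
        )
        assert fit.varcomps.genetic[0, 0] == pytest.approx(v["u"], rel=0.01)
        assert fit.varcomps.common[0, 0] == pytest.approx(v["c"], rel=0.01)
        assert fit.varcomps.sigma2_e == pytest.approx(s2e, rel=0.01)


class TestBlupPrediction:
    @pytest.fixture(scope="class")
    def fixed_comps(self):
        return VarianceComponents(
            genetic=np.array([[0.25, 0.0], [0.0, 0.05]]),
            common=np.array([[0.08, 0.0], [0.0, 0.04]]),
            sigma2_e=0.6,
            scaled_eps=(1.0, 1.0),
            genetic_param="animal",
        )

    def _pheno(self, animals, weights, families):
        rng = np.random.default_rng(0)
        return ub.PhenotypeTable(
            pd.DataFrame(
                {
                    "animal": animals,
                    "weight": weights,
                    "age": rng.integers(470, 500, len(animals)),
                    "tank": ["T1"] * len(animals),
                    "year_class": ["y1"] * len(animals),
                    "family": families,
                }
            )
        )

    def test_unrelated_unphenotyped_animal_has_zero_ebv(self, fixed_comps):
        ped = ub.Pedigree.from_records(
            [("X", None, None), ("Y", None, None)]
            + [(f"O{i}", None, None) for i in range(1, 7)]
        )
        A_inv = ub.invert(ub.build_numerator_relationship(ped))
        rng = np.random.default_rng(1)
        ph = self._pheno(
            [f"O{i}" for i in range(1, 7)], 900 + 30 * rng.standard_normal(6),
            ["f1", "f1", "f1", "f2", "f2", "f2"],
        )
        spec = ModelSpec(genetic_param="animal", relationship="A")
        blup = predict_breeding_values(ph, spec, fixed_comps, A_inv, ped)
        i = blup.genetic_ids.index("X")
        assert abs(blup.ebv_mean[i]) < 1e-10
        assert abs(blup.ebv_disp[i]) < 1e-10

    def test_parent_average_for_unphenotyped_offspring(self, fixed_comps):
        """A non-phenotyped, non-inbred offspring with no descendants gets
        exactly the parent-average EBV under the animal model."""
        records = [("S", None, None), ("D", None, None), ("C", "S", "D")]
        records += [(f"P{i}", "S", "D") for i in range(1, 9)]  # phenotyped sibs
        ped = ub.Pedigree.from_records(records)
        A_inv = ub.invert(ub.build_numerator_relationship(ped))
        rng = np.random.default_rng(2)
        ph = self._pheno(
            [f"P{i}" for i in range(1, 9)], 900 + 40 * rng.standard_normal(8),
            ["f1"] * 8,
        )
        spec = ModelSpec(genetic_param="animal", relationship="A")
        blup = predict_breeding_values(ph, spec, fixed_comps, A_inv, ped)
        ebv = dict(zip(blup.genetic_ids, blup.ebv_mean))
        assert ebv["C"] == pytest.approx((ebv["S"] + ebv["D"]) / 2, abs=1e-8)

    def test_identical_genomic_rows_give_equal_gebv(self, fixed_comps):
        """Animals with duplicated genotype rows (identical twins) under H
        receive identical GEBV."""
        ped = ub.Pedigree.from_records(
            [("S", None, None), ("D", None, None)]
            + [(f"O{i}", "S", "D") for i in range(1, 7)]
        )
        A = ub.build_numerator_relationship(ped)
        rng = np.random.default_rng(3)
        geno = ub.gene_drop(ped, rng.uniform(0.2, 0.5, 300), seed=4)
        gen_ids = ["O1", "O2", "O3", "O4"]
        codes = geno.subset_animals(gen_ids).codes.copy()
        codes[1] = codes[0]  # O2 is O1's twin
        gm = ub.GenotypeMatrix(gen_ids, geno.snp_ids, codes)
        gm, _ = ub.qc_snps(gm, maf_min=0.01)
        H, H_inv = ub.single_step_pair(ped, ub.scale_genotypes(gm))
        ph = self._pheno(["O3", "O4", "O5", "O6"], [850.0, 950.0, 900.0, 920.0], ["f"] * 4)
        spec = ModelSpec(genetic_param="animal", relationship="H")
        blup = predict_breeding_values(ph, spec, fixed_comps, H_inv, ped)
        ebv = dict(zip(blup.genetic_ids, blup.ebv_mean))
        assert ebv["O1"] == pytest.approx(ebv["O2"], abs=1e-8)

    def test_mask_excludes_records(self, small_fit):
        data, spec, kin, y, fit = small_fit
        masked = set(data.phenotypes.animals[:10])
        blup = predict_breeding_values(
            data.phenotypes, spec, fit.varcomps, kin, data.pedigree,
            response=y, mask=masked,
            psi=fit.psi, resid_var=fit.fitted_resid_var, hat=fit.hat_values,
        )
        # masked animals still receive (relationship-propagated) EBVs
        ebv = blup.animal_ebv(data.pedigree, "mean")
        assert all(a in ebv for a in masked)

    def test_parameterization_mismatch_rejected(self, small_fit):
        data, spec, kin, y, fit = small_fit
        animal_spec = ModelSpec(genetic_param="animal", relationship="A")
        with pytest.raises(ValueError, match="to_animal"):
            predict_breeding_values(
                data.phenotypes, animal_spec, fit.varcomps, kin, data.pedigree
            )


class TestSireDamVsAnimalConsistency:
    def test_mean_trait_variance_estimates_agree(self):
        """On two-generation non-inbred data with large families, sigma2_a
        from the sire-dam model is close to the animal-model estimate
        (both are REML estimates of the same additive variance)."""
        cfg = ub.SimConfig(
            n_sires=30, n_dams=55, family_size_mean=18.0, family_size_range=(14, 24),
            family_size_sigma=0.2, n_snps=10, genotyped_families=0, seed=23,
            sigma2_a=0.3, sigma2_av_exp=0.0, sigma2_c=0.08, sigma2_cv_exp=0.0,
            sigma2_e=0.62, r_g_mean_disp=0.0,
        )
        data = ub.simulate_dataset(cfg)
        rels = ub.build_relationship_set(data.pedigree)
        y, _ = ub.standardize(data.phenotypes.weight)
        X, _ = fixed_effects_design(data.phenotypes)
        Q, _ = common_env_design(data.phenotypes, data.pedigree)
        out = {}
        for param in ("sire_dam", "animal"):
            spec = ModelSpec(genetic_param=param, relationship="A")
            kin = ub.kinship_inverse_for(spec, rels, data.pedigree)
            T = genetic_design(data.phenotypes, data.pedigree, spec, kin.ids)
            v, s2e, *_ = fit_univariate_reml(
                y, X, [RandomTerm("u", T, kin.values), RandomTerm("c", Q)],
                tol=1e-8, max_iter=500,
            )
            out[param] = 4 * v["u"] if param == "sire_dam" else v["u"]
        # ~2 SE band for this design (sampling SD of sigma2_a ~ 0.06)
        assert out["sire_dam"] == pytest.approx(out["animal"], abs=0.12)
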