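"""Synthetic-data generator: design, gene dropping, phenotype model."""

import numpy as np
import pytest

import uniblup as ub
from uniblup.pedigree import UNKNOWN


class TestSimulatePedigree:
    def test_exact_counts_small_design(self):
        cfg = ub.SimConfig(
            n_sires=2, n_dams=4, family_size_mean=3.0, family_size_range=(3, 3),
            family_size_sigma=0.0, seed=0,
        )
        ped, fams = ub.simulate_pedigree(cfg)
        assert len(fams) == 4
        assert fams["size"].sum() == 12
        assert ped.n == 2 + 4 + 12
        # every dam mated to exactly one sire; sires serve 1..max dams
        assert fams.groupby("dam").size().max() == 1
        assert fams.groupby("sire").size().between(1, cfg.max_dams_per_sire).all()

    def test_mean_family_size_near_target(self):
        sizes = []
        for seed in range(5):
            cfg = ub.SimConfig(seed=seed, n_snps=2)
            _, fams = ub.simulate_pedigree(cfg)
            sizes.append(fams["size"].mean())
        assert np.mean(sizes) == pytest.approx(15.4, rel=0.10)

    def test_same_seed_identical(self):
        cfg = ub.SimConfig(n_sires=5, n_dams=9, seed=3, n_snps=2)
        p1, f1 = ub.simulate_pedigree(cfg)
        p2, f2 = ub.simulate_pedigree(cfg)
        assert p1.ids == p2.ids
        assert f1.equals(f2)

    def test_infeasible_ratio_rejected(self):
        with pytest.raises(ValueError, match="dams"):
            ub.SimConfig(n_sires=2, n_dams=10, max_dams_per_sire=3)


class TestGeneDrop:
    def test_fixed_founders_propagate(self, trio_pedigree):
        g = ub.gene_drop(trio_pedigree, np.ones(5), seed=0)
        assert (g.codes == 2).all()

    def test_mendelian_consistency(self):
        cfg = ub.SimConfig(n_sires=5, n_dams=9, family_size_mean=6.0,
                           family_size_range=(4, 8), n_snps=200, seed=4)
        ped, _ = ub.simulate_pedigree(cfg)
        g = ub.gene_drop(ped, np.full(200, 0.4), seed=5)
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s == UNKNOWN:
                continue
            child, sire, dam = g.codes[i], g.codes[s], g.codes[d]
            # a homozygous parent always transmits that allele
            assert not np.any((sire == 0) & (dam == 0) & (child > 0))
            assert not np.any((sire == 2) & (dam == 2) & (child < 2))
            assert not np.any((sire == 0) & (child == 2))
            assert not np.any((sire == 2) & (child == 0))

    def test_expected_G_tracks_A22_for_full_sibs(self):
        ped = ub.Pedigree.from_records(
            [("S", None, None), ("D", None, None)]
            + [(f"O{i}", "S", "D") for i in range(1, 11)]
        )
        A = ub.build_numerator_relationship(ped)
        g = ub.gene_drop(ped, np.random.default_rng(6).uniform(0.2, 0.5, 5000), seed=7)
        sibs = [f"O{i}" for i in range(1, 11)]
        panel, _ = ub.qc_snps(g.subset_animals(sibs), maf_min=0.01)
        G = ub.build_genomic_relationship(ub.scale_genotypes(panel))
        A22 = A.submatrix(sibs)
        off = ~np.eye(10, dtype=bool)
        # centring shifts G by a constant; compare the full-sib contrast
        diff = (G.values - G.values[off].mean()) - (A22.values - A22.values[off].mean())
        assert np.abs(diff[off]).mean() < 0.05

    def test_same_seed_identical(self, trio_pedigree):
        g1 = ub.gene_drop(trio_pedigree, np.full(50, 0.3), seed=8)
        g2 = ub.gene_drop(trio_pedigree, np.full(50, 0.3), seed=8)
        assert (g1.codes == g2.codes).all()


class TestSimulatePhenotypes:
    def test_null_dispersion_gives_constant_residual_variance(self):
        cfg = ub.SimConfig(n_sires=4, n_dams=8, family_size_mean=5.0,
                           family_size_range=(3, 8), sigma2_av_exp=0.0,
                           sigma2_cv_exp=0.0, n_snps=2, seed=9)
        data = ub.simulate_dataset(cfg)
        rv = data.truth.animals["resid_var"]
        assert np.allclose(rv, cfg.sigma2_e)

    def test_founder_breeding_value_variance(self):
        cfg = ub.SimConfig(n_sires=300, n_dams=500, family_size_mean=4.0,
                           family_size_range=(1, 6), n_snps=2,
                           genotyped_families=0, seed=10)
        rng = np.random.default_rng(cfg.seed)
        ped, fams = ub.simulate_pedigree(cfg, rng)
        phen, truth = ub.simulate_phenotypes(ped, fams, cfg, rng)
        # founder-generation variance check via parents' offspring means is
        # indirect; check offspring a-variance against the additive expectation
        var_a = truth.animals["a"].var(ddof=1)
        se = cfg.sigma2_a * np.sqrt(2.0 / (len(truth.animals) - 1))
        # offspring variance is slightly below sigma2_a only through parent
        # sampling; allow 3 SE around the target
        assert abs(var_a - cfg.sigma2_a) < 5 * se

    def test_scale_effect_induces_mean_variance_coupling(self):
        cfg = ub.SimConfig.log_scale(n_sires=30, n_dams=50, family_size_mean=10.0,
                                     family_size_range=(8, 12), n_snps=2,
                                     genotyped_families=0, seed=11)
        data = ub.simulate_dataset(cfg)
        w = data.phenotypes.weight
        assert (w > 0).all()
        fam = data.phenotypes.df["family"]
        means = data.phenotypes.df.groupby("family")["weight"].mean()
        sds = data.phenotypes.df.groupby("family")["weight"].std()
        r_raw = np.corrcoef(means, sds)[0, 1]
        logw = data.phenotypes.df.assign(lw=np.log(w))
        lmeans = logw.groupby("family")["lw"].mean()
        lsds = logw.groupby("family")["lw"].std()
        r_log = np.corrcoef(lmeans, lsds)[0, 1]
        assert r_raw > r_log + 0.2  # coupling on the raw scale only


class TestFixtures:
    def test_round_trip_and_byte_stability(self, tmp_path):
        cfg = ub.SimConfig(n_sires=4, n_dams=7, family_size_mean=5.0,
                           family_size_range=(3, 8), n_snps=50,
                           genotyped_families=3, seed=12)
        data = ub.simulate_dataset(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        ub.write_fixture(data, d1)
        ub.write_fixture(ub.simulate_dataset(cfg), d2)
        for f in d1.iterdir():
            assert (d2 / f.name).read_bytes() == f.read_bytes()
        back = ub.simulate.read_fixture(d1) if hasattr(ub, "simulate") else None
        from uniblup.simulate import read_fixture

        back = read_fixture(d1)
        assert back.pedigree.ids == data.pedigree.ids
        assert np.allclose(back.phenotypes.weight, data.phenotypes.weight)
        assert (back.genotypes.codes == data.genotypes.codes).all()

    def test_seed_changes_data_not_schema(self, tmp_path):
        cfg1 = ub.SimConfig(n_sires=4, n_dams=7, family_size_mean=5.0,
                            family_size_range=(3, 8), n_snps=20,
                            genotyped_families=2, seed=13)
        cfg2 = ub.SimConfig(n_sires=4, n_dams=7, family_size_mean=5.0,
                            family_size_range=(3, 8), n_snps=20,
                            genotyped_families=2, seed=14)
        d1 = ub.simulate_dataset(cfg1)
        d2 = ub.simulate_dataset(cfg2)
        assert list(d1.phenotypes.df.columns) == list(d2.phenotypes.df.columns)
        assert not np.allclose(d1.phenotypes.weight[: 10], d2.phenotypes.weight[: 10])
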