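"""Masking cross-validation: pedigree BLUP vs single-step genomic BLUP.

Estimates variance components once with the sire-dam DHGLM, then predicts
breeding values for masked animals with the animal model under A (pedigree
only) and H (pedigree + genomic), and compares predictive ability for
uniformity over family-stratified folds.
"""

import uniblup as ub

cfg = ub.SimConfig(
    n_sires=35, n_dams=60, family_size_mean=18.0, family_size_range=(14, 24),
    n_snps=300, genotyped_families=50, genotyped_sibs_range=(16, 20), seed=704,
)
data = ub.simulate_dataset(cfg)
geno, _ = ub.qc_snps(data.genotypes)
rels = ub.build_relationship_set(data.pedigree, ub.scale_genotypes(geno))

sd_spec = ub.ModelSpec(genetic_param="sire_dam", relationship="A")
kin_sd = ub.kinship_inverse_for(sd_spec, rels, data.pedigree)
stdwt, _ = ub.standardize(data.phenotypes.weight)
fit = ub.fit_dhglm(data.phenotypes, sd_spec, kin_sd, data.pedigree, response=stdwt)

plan = ub.make_folds(data.phenotypes, k=10, seed=11)
for rel in ("A", "H"):
    spec = ub.ModelSpec(genetic_param="animal", relationship=rel)
    kin = ub.kinship_inverse_for(spec, rels, data.pedigree)
    full = ub.blup_full_fit(
        data.phenotypes, spec, fit.varcomps.to_animal(), kin, data.pedigree,
        response=stdwt,
    )
    report = ub.run_crossval(
        data.phenotypes, spec, fit.varcomps.to_animal(), plan,
        data.genotyped_ids, kin, data.pedigree, full, response=stdwt,
    )
    r_w = report.metric("weight", "pearson")
    r_u = report.metric("uniformity", "pearson")
    msep = report.metric("uniformity", "msep_scaled")
    print(f"{rel}: predictive ability weight {r_w:.3f}, uniformity {r_u:.3f}, "
          f"scaled MSEP (uniformity) {msep:.3f}")
    if rel == "A":
        folds_A = report.fold_values("uniformity", "pearson")
    else:
        folds_H = report.fold_values("uniformity", "pearson")

d, lo, hi, sig = ub.difference_ci(folds_H, folds_A)
print(f"H - A difference for uniformity: {d:+.3f} (95% CI {lo:+.3f}..{hi:+.3f}; "
      f"{'significant' if sig else 'not significant'} across folds)")
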