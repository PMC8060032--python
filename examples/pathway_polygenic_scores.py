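"""Pathway-specific polygenic scores in a genotyped validation cohort.

Simulates a cohort of 5000 individuals whose phenotype hides 1% of its
variance inside one druggable gene-set, builds the pathway score from an
independent discovery GWAS, scores every individual, and tests the score
against the covariate-residualised Blom-normalised phenotype — with and
without adjustment for a genome-wide polygenic score — plus the
decile-depletion odds ratio.
"""

import pharmagenic as pg
from pharmagenic.pes import (build_pes_definition, associate_profile,
                             decile_depletion, pes_pgs_overlap,
                             prepare_phenotype, score_profiles)
from pharmagenic.simulate import (CohortSimParams, make_gene_annotations,
                                  simulate_cohort, sumstats_from_true_effects)

panel = pg.make_ld_panel(n_blocks=12, block_size=25, ar1_rho=0.6, seed=8)
ann = make_gene_annotations(panel, snps_per_gene=5)
pathway = pg.GeneSet("SECRETIN_LIKE", [a.gene for a in ann[:5]], druggable=True)

# 1% of phenotypic variance in the pathway, 10% polygenic background elsewhere
geno, table, truth = simulate_cohort(
    CohortSimParams(n=5000, planted_fraction=0.01, background_fraction=0.10,
                    seed=9), panel, ann, pathway)
discovery = sumstats_from_true_effects(truth["beta_std"], panel, n=100_000, seed=10)

pes_def = build_pes_definition(discovery, pathway, ann, panel,
                               p_t=1.0, boundary="conservative")
pgs_def = build_pes_definition(discovery, None, ann, panel, p_t=1.0, boundary=None)
pes = score_profiles(pes_def, geno)
pgs = score_profiles(pgs_def, geno)
print(f"pathway score: {pes_def.m} SNPs; genome-wide score: {pgs_def.m} SNPs")

covars = ["sex", "age", "age2", "height", "height2", "smoking"]
pheno = prepare_phenotype(table, "phenotype", covars)
res = associate_profile(pes, pheno)
res_adj = associate_profile(pes, pheno, adjust_pgs=pgs)
print(f"PES association:           Z {res.z:+.2f}, p {res.p:.2e}, "
      f"delta R2 {res.delta_r2:.4f}")
print(f"PES adjusted for PGS:      Z {res_adj.z:+.2f}, p {res_adj.p:.2e}, "
      f"delta R2 {res_adj.delta_r2:.4f}")
overlap = pes_pgs_overlap(pes, pgs)
print(f"PES-PGS correlation r = {overlap['correlation']:.2f}; "
      f"{100 * overlap['top_pgs_bottom_pes_fraction']:.1f}% of top-decile-PGS "
      "individuals sit in the bottom PES decile")
dec = decile_depletion(pes, pheno)
lo, hi = dec["ci95"]
print(f"odds of bottom-PES-decile membership per phenotype SD: "
      f"OR {dec['odds_ratio']:.2f} [{lo:.2f}, {hi:.2f}]")
print("-> the pathway score recovers the planted 1% signal (delta R2 ~ 0.007)"
      " while correlating only modestly with the genome-wide score; PGS"
      " adjustment attenuates it because the genome-wide score at the same"
      " threshold contains the pathway SNPs themselves.")
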