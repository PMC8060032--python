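"""Causal inference on a genetically correlated trait pair.

Simulates a fully causal exposure -> outcome architecture (GCP = 1,
r_g = 0.5) and runs both causality frameworks: the latent-causal-variable
genetic causality proportion, and the two-sample Mendelian-randomisation
suite (IVW with multiplicative random effects, weighted median, MR-Egger,
Steiger directionality, leave-one-out, global pleiotropy test).
"""

import numpy as np

import pharmagenic as pg
from pharmagenic.mr import mr_leave_one_out

panel = pg.make_ld_panel(n_blocks=200, block_size=25, ar1_rho=(0.0, 0.8), seed=2)
params = pg.LcvSimParams(h2_1=0.4, h2_2=0.3, rg=0.5, gcp=1.0, frac_causal=0.01,
                         n1=200_000, n2=200_000, seed=7)
exposure, outcome = pg.simulate_sumstats_pair(params, panel)

gcp = pg.estimate_gcp(exposure, outcome)
print(f"GCP estimate: {gcp.gcp:.2f} (se {gcp.se:.2f}, p {gcp.p_gcp0:.2e}); "
      f"partial causality flag: {gcp.partial_causality}")

iv = pg.select_instruments(exposure, outcome, panel)
true_slope = abs(params.rg) * np.sqrt(params.h2_2 / params.h2_1)
print(f"{len(iv)} instruments selected (p < 5e-8, r2 < 0.001, no palindromes)")
print(f"true causal slope: {true_slope:.3f} outcome SD per exposure unit")
for est in (pg.mr_ivw(iv), pg.mr_weighted_median(iv, seed=1), pg.mr_egger(iv)):
    lo, hi = est.ci95
    print(f"  {est.method:16s} beta {est.beta:+.3f} [{lo:+.3f}, {hi:+.3f}] p {est.p:.2e}")
steiger = pg.mr_steiger(iv)
print(f"Steiger direction: {steiger['verdict']} (p {steiger['p']:.2e})")
presso = pg.presso_global(iv, seed=3)
print(f"global pleiotropy test p: {presso['p']:.3f} "
      "(heterogeneity is expected here: the outcome carries genetic "
      "variance of its own beyond the causal pathway)")
loo = mr_leave_one_out(iv)
print(f"leave-one-out: {int(loo['significance_changed'].sum())} of {len(loo)} "
      "instruments change significance when removed")
print("-> GCP > 0.6 and concordant MR estimates near the true slope indicate"
      " a robust exposure -> outcome causal effect.")
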