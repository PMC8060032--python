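"""Fine-map a TWAS locus to a credible set of putatively causal genes.

Simulates a 10-gene locus with one causal gene (causal-effect variance 40,
the fine-mapping default), computes per-gene posterior inclusion
probabilities by enumerating causal configurations, reports the 90%
credible set, and shows the effect of the more conservative causal prior.
"""

import numpy as np

import pharmagenic as pg
from pharmagenic.finemap import FinemapConfig, finemap_locus, finemap_pips

locus = pg.simulate_twas_locus(m=10, omega_rho=0.4, causal_genes=(3,), seed=4)
print(f"simulated locus: causal gene {locus.causal_genes[0]}, "
      f"z range [{locus.z.min():+.1f}, {locus.z.max():+.1f}]")

res = finemap_locus(locus, FinemapConfig(prior_prob=1e-3, prior_var=40.0, rho=0.9))
order = np.argsort(-res.pip)
print("gene PIPs (descending):")
for i in order[:5]:
    print(f"  {res.genes[i]}: {res.pip[i]:.3f}")
print(f"null-model posterior: {res.null_pip:.3f}")
print(f"90% credible set: {res.credible_set} "
      f"(null model in set: {res.locus_excluded})")

conservative = finemap_pips(locus, FinemapConfig(prior_prob=1e-5))
i_best = order[0]
print(f"with prior 1e-5, top gene PIP moves {res.pip[i_best]:.3f} -> "
      f"{conservative.pip[i_best]:.3f}")
print("-> a druggable gene with high PIP inside the credible set (and the"
      " null model outside it) is a prioritised repurposing target.")
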