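"""Population structure of a simulated panel: PCA, Fst and LD pruning.

The Weir-Cockerham estimate should sit near the simulated divergence
(F = 0.24), PC1 should separate the two subpopulations, and LD pruning
should remove redundant neighbouring markers.
"""

import numpy as np

from gwgp import popgen, simulate as sim, variants_io as vio

geno, labels = sim.simulate_genotypes(sim.oat195_genotype_config(n_snps=5000, seed=1))
geno = vio.impute_missing(vio.filter_snps(geno, vio.FilterSpec()))

res = popgen.fst(geno, labels, window_bp=30_000)
print(f"overall Weir-Cockerham Fst = {res.overall:.3f} (simulated F = 0.24)")
print(f"windowed estimates: {len(res.windowed)} windows, "
      f"median {res.windowed['fst'].median():.3f}")

scores, frac = popgen.pca(geno, n_components=4)
print(f"PC1/PC2 explain {frac[0]:.1%} / {frac[1]:.1%} of GRM variance")
pc1 = scores[:, 0]
cuts = np.quantile(pc1, np.linspace(0, 1, 201))
sep = max(
    max(((pc1 > t) == (labels == 1)).mean() for t in cuts),
    max(((pc1 < t) == (labels == 1)).mean() for t in cuts),
)
print(f"best 1-D split on PC1 classifies {sep:.0%} of accessions correctly")

keep = popgen.ld_prune(geno, r2_max=0.98, window_kb=100)
print(f"LD pruning at r2 <= 0.98 within 100 kb keeps {len(keep)}/{geno.n_snps} markers")
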