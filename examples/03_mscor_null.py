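"""Step C in isolation: mscor and its stratified empirical null.

Construct a pair of genes whose entire correlation flows through one
shared miRNA (population cor = 0.5, partial cor = 0, so mscor = 0.5), then
score it against null draws where the miRNAs are independent of the genes.
"""

import numpy as np

from cerna import NullModel, empirical_pvalue, mscor, partial_correlation, pearson_cor

rng = np.random.default_rng(0)
n = 200
m = rng.standard_normal(n)
gene_a = -m + rng.standard_normal(n)
gene_b = -m + rng.standard_normal(n)

cor = pearson_cor(gene_a, gene_b)
pcor = partial_correlation(gene_a, gene_b, m[:, None])
ms = mscor(gene_a, gene_b, m[:, None])
print(f"cor = {cor:.3f}   pcor|miRNA = {pcor:.3f}   mscor = {ms:.3f}")

null = NullModel(n_samples=n, n_draws=1000, seed=1)
null.ensure_stratum(m=1, cor=cor)  # strata are simulated lazily on demand
p = empirical_pvalue(null, ms, m=1, cor_ab=cor)
print(f"empirical p = {p:.4f}")
# mscor near cor with pcor near zero says the gene-gene correlation is
# miRNA-mediated; the tiny empirical p confirms that no null pair (same
# correlation, unrelated miRNA) reaches such an mscor.
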