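"""Genotype QC, expression normalization and the univariate cis screen.

QC removes SNPs with low call rate, low minor-allele frequency or exact-test
Hardy-Weinberg violations; expression is mapped to normal scores per gene;
the screen keeps genes with at least one BH-significant cis association.
"""

import numpy as np

from eqtel import SimulationConfig, normalize_expression, qc_filter, simulate_dataset, univariate_screen

cfg = SimulationConfig(
    n_samples=150, n_genes=4, snps_per_gene=60,
    regulator_fraction=0.1, r2_beta_a=8.0, r2_beta_b=8.0,  # strong signal
)
g, e, f, truth = simulate_dataset(cfg, seed=2)

# corrupt a few SNPs to exercise the filters
g.dosages[: int(0.2 * g.n_samples), :3] = np.nan
g.maf = np.minimum(np.nanmean(g.dosages, 0) / 2, 1 - np.nanmean(g.dosages, 0) / 2)

g_qc, report = qc_filter(g, call_rate_min=0.95, maf_min=0.15)
print("QC report:", report)

e_norm = normalize_expression(e)
print(f"normalized rows: mean {e_norm.values.mean(axis=1).round(10).max()}, "
      f"var {e_norm.values.var(axis=1).round(10).min()} (normal scores)")

genes = univariate_screen(g_qc, e_norm, window_bp=1_000_000, fdr=1e-3)
print(f"genes passing the univariate cis screen: {genes}")
# With mean R^2 = 0.5 every gene should carry a detectable cis association.
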