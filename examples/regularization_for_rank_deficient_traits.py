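"""Spectral regularization for linearly dependent trait panels.

Replacing 5 base traits with their 10 pairwise sums makes the trait
correlation matrix rank-5. Inverting it as-is amplifies noise in the
near-null eigendirections and the null p-values stop being uniform;
flooring the 5 smallest eigenvalues (r = K - rank) repairs the test.
"""

import warnings

import numpy as np
from scipy import stats

from mvgwas import MostestConfig, run_mostest
from mvgwas.simulation import SimulationConfig, simulate_study

warnings.filterwarnings("ignore", category=UserWarning)

study = simulate_study(SimulationConfig(
    n_samples=2000, n_variants=20_000, chrom_sizes=(1000, 19_000),
    n_causal=10, T=5, t=5, h2=0.05, rank_deficient=True, seed=3))
print(f"{study.Y.n_traits} derived traits from 5 base traits "
      f"(correlation rank {np.linalg.matrix_rank(np.corrcoef(study.Y.values.T), tol=1e-8)})")

for r_reg in (0, 5):
    res = run_mostest(study.G, study.Y, MostestConfig(seed=4, r_reg=r_reg))
    null_p = res.table[res.table["chrom"] != 1]["mostest_p"]
    ks = stats.kstest(null_p, "uniform")
    print(f"r = {r_reg}: null-chromosome KS uniformity p = {ks.pvalue:.3g}, "
          f"fraction < 1e-3 = {np.mean(null_p < 1e-3):.5f} (nominal 0.001)")

print("\nWithout regularization the null distribution is visibly distorted;"
      "\nwith r = 5 the empirical rate matches the nominal alpha again.")
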