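"""Run the multivariate omnibus test on a fully synthetic study.

Simulates 2,000 individuals, 5,000 variants (all genetic effects on
chromosome 1), and 10 correlated traits with distributed effects, then
runs the full pipeline: rank-based inverse-normal preparation, observed
and genotype-permutation GWAS, gamma-null calibration, and per-variant
omnibus + corrected min-P p-values.
"""

import warnings

from mvgwas import MostestConfig
from mvgwas.simulation import SimulationConfig, run_study, simulate_study

warnings.filterwarnings("ignore", category=UserWarning)

cfg = SimulationConfig(n_samples=2000, n_variants=5000,
                       chrom_sizes=(1000, 4000), n_causal=10, T=10, t=10,
                       h2=0.05, seed=42)
study = simulate_study(cfg)
result = run_study(study, MostestConfig(seed=42))

cal = result.calibration
print(f"traits K = {cal.K}, permuted statistics M = {cal.M_perm}")
print(f"fitted null: gamma(a = {cal.gamma_shape:.3f}, b = {cal.gamma_scale:.3f})"
      f"  [chi-square(K) would be gamma({cal.K / 2}, 2)]")
print(f"effective number of independent traits Meff = {cal.minp_meff:.2f}")

top = result.table.nsmallest(5, "mostest_p")
causal = {int(v) for ids in study.causal_ids.values() for v in ids}
print("\ntop 5 variants by omnibus p (is_causal = planted effect):")
for i, row in top.iterrows():
    print(f"  {row.variant_id:>12}  chr{row.chrom}  "
          f"omnibus p = {row.mostest_p:.2e}  min-P = {row.minp_corrected_p:.2e}"
          f"  causal = {i in causal}")

n_sig = int((result.table.mostest_p < 5e-8).sum())
print(f"\n{n_sig} variants reach genome-wide significance (5e-8); a variant is"
      "\na true positive if it is one of the 10 planted causal variants.")
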