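"""Type-I error and power of the omnibus test versus corrected min-P.

Uses the default reduced-scale scenario (2,000 samples, 20,000 variants,
effects confined to chromosome 1) so every variant on chromosome 2 is an
exact null: the fraction of those passing each alpha estimates the
type-I error, and the fraction of planted causal variants passing 5e-8
estimates power.
"""

import warnings

from mvgwas import evaluate_power, evaluate_type1
from mvgwas.simulation import SimulationConfig, run_study, simulate_study

warnings.filterwarnings("ignore", category=UserWarning)

study = simulate_study(SimulationConfig(seed=7))
result = run_study(study)

t1 = evaluate_type1(result, causal_chrom=1, alphas=(0.05, 1e-3))
print("type-I error on the null chromosome (99% binomial CI):")
print(t1.to_string(index=False, float_format=lambda x: f"{x:.5g}"))

power = evaluate_power(result, study.B, alpha=5e-8)
print("\npower at the planted causal variants (alpha = 5e-8):")
print(power.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print("\nA calibrated test keeps each type-I fraction inside its CI; with"
      "\ndistributed effects the omnibus power exceeds the min-P power.")
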