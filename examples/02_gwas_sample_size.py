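"""Lower bounds on GWAS sample size implied by the persistence threshold.

If every true risk allele has d < nu, a study powered to detect d = nu at
genome-wide significance gives the minimum case-control pairs needed to
see any of them at the worst-case allele frequency x = 0.5.
"""

from pcriterion import (
    MU_PRESETS,
    PopulationParams,
    PowerDesign,
    compute_nu,
    normal_quantile,
    required_pairs,
    round_sig,
)

ALPHA = 2.5e-7  # genome-wide two-sided level
params = PopulationParams()

z_sum = normal_quantile(ALPHA / 2) + normal_quantile(0.2)
print(f"z*_alpha + z_beta = {z_sum:.3f}  (alpha={ALPHA}, power=0.8)")
for name in ("highest", "average", "low"):
    d = compute_nu(params, MU_PRESETS[name]).nu
    n = required_pairs(PowerDesign(alpha=ALPHA, power=0.8, x=0.5, d=d))
    print(f"  mu {name:>7}: d = nu = {d:.3e}  ->  N = {round_sig(n, 2):,.0f} pairs "
          f"(raw {n:,.0f})")
print("Detecting average-mutation-rate risk alleles would need millions of pairs.")
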