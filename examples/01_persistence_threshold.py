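"""Compute the persistence threshold nu for the three mutation-rate presets.

nu = (1 - s*p) * mu / ((1 - p) * s * p) caps the case-control allele
frequency difference d that a nuclear susceptibility allele can show while
the disease persists under mutation-selection balance.
"""

from pcriterion import MU_PRESETS, PopulationParams, compute_nu

params = PopulationParams()  # p = 1.29e-2, s = 0.654
print(f"prevalence p = {params.prevalence}, selection s = {params.selection_coefficient}")
for name in ("low", "average", "highest"):
    thr = compute_nu(params, MU_PRESETS[name])
    print(f"  mu {name:>7} = {thr.mu_used:.3g}  ->  nu = {thr.display:.3g} "
          f"(full precision {thr.nu:.6e})")
print("A variant with d at or above nu cannot persist as a risk allele;")
print("under balance it must instead be protective.")
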