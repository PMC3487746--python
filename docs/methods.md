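# Methods

## Model and assumptions

The package analyses a multifactorial-threshold disease in a large,
random-mating population at equilibrium, with prevalence *p* stable
across generations and genetic drift negligible. Fitness of affected
individuals is summarised by a single selection coefficient *s* (1 minus
their mean relative fitness; the unaffected population has mean fitness
1). For any allele M the population frequency decomposes as
*m*G = *p·m*A + (1−*p*)·*m*U over affected and unaffected carriers; the
case-control difference is *d* = *m*A − *m*U.

One generation of selection moves the population frequency to
*m*G′ = (*m*G − *s*M·*p*·*m*A)/(1 − *s*M·*p*), where *s*M is the
selection coefficient within the M-carrying affected subpopulation, so
the per-generation loss is *p*(1−*p*)·*d*·*s*M/(1−*s*M·*p*). For a
susceptibility allele *s*M ≥ *s* (carrying the allele cannot make
affected carriers fitter), and balance requires the loss not to exceed
the per-locus mutation rate *μ*. Together these give the persistence
bound *d* < ν = (1−*sp*)·*μ*/((1−*p*)·*sp*). The contrapositive drives
the catalog analysis: an associated allele with *d* ≥ ν, if sustained by
balance, must have *s*M < *s* — it is protective, not causal.

Key default parameters:

| parameter | default | units | basis |
|---|---|---|---|
| prevalence *p* | 1.29×10⁻² | proportion | large-cohort epidemiology of schizophrenia |
| selection *s* | 6.54×10⁻¹ | dimensionless | same cohort (1 − relative fertility of patients) |
| *μ* "average" | 1.48×10⁻⁵ | /locus/generation | nuclear average (autosomes + X) |
| *μ* "highest" | 1.48×10⁻⁴ | /locus/generation | 1×10⁻⁴ ceiling scaled by mean parental age 29.6 y / 20 y generation |
| *μ* "low" | 1.48×10⁻⁶ | /locus/generation | lower end of the nuclear range |

*p* and *s* are accepted as user inputs with these packaged defaults;
re-estimating them from primary cohort data is out of scope. ν is always
carried unrounded: the catalog's most informative variant (rs2661319,
*d* = 0.0176) falls on the right side of the threshold only when ν ≈
0.0176219 is not pre-rounded to 3 significant figures. Display rounding
is applied at output boundaries only.

## Catalog classification

Catalogs are delimited text (CSV/TSV, header row) with risk-allele
oriented frequencies: `freq_cases`/`freq_controls` are the frequencies of
the asterisk-marked allele exactly as published, never re-oriented to the
minor allele. *d* is computed from these frequencies, never taken from a
published rounded *d* column (retained as `printed_d` for regression
checks only; two rows of the packaged catalog, rs1800857 and rs2461491,
have printed *d* inconsistent with their own printed frequencies — the
frequencies govern, and the class is the same either way).

Classes are strict and exhaustive: MEETS (0 < *d* < ν), EXCEEDS
(*d* ≥ ν; a tie classifies EXCEEDS), NONPOSITIVE (*d* ≤ 0). A gene meets
if any of its variants meets; a chromosome arm (chromosome + p/q — the
granularity at which regional co-location is judged) meets if any
resident gene meets. The "protective loci outside" count is the number of
genes with no MEETS variant, at least one EXCEEDS variant, and residence
on a non-meeting arm. Pseudo-loci from genome-wide scans (`GWA_*` rows)
count as genes; structural and multi-allelic variants (a gene deletion,
a haptoglobin type, an apolipoprotein isoform) are represented as the
biallelic rows their source tables print. Locations are taken verbatim
from the source even where unconventional (one variant is printed on
"13p14.13"); each gene must map to a single arm, and violations raise.

## Power arithmetic

`normal_quantile` wraps scipy's inverse normal CDF (`ndtri`), accurate to
well below 10⁻⁹ into the far tails, which matters at genome-wide
α/2 = 1.25×10⁻⁷. The sample-size formula is implemented in two forms: the
split form ½·(z\*α·√(2x(1−x)) + zβ·γ)²/d² with the exact per-group factor
γ = √(2x(1−x) − d²/2), and the collapsed form (z\*α+zβ)²·x(1−x)/d². For
threshold-scale d the dropped d²/2 term costs under 0.2%, and the
collapsed form — the one the headline bounds are quoted from — is the
default. Bounds are quoted at the worst-case frequency x = 0.5 and
rounded to two significant figures for presentation; raw values are
always returned.

## Forward dynamics

**Nuclear recurrence.** `iterate_to_equilibrium` tracks the
case-attributable excess allele mass *p*(1−*p*)·*d*: each generation it
loses the selection amount above and gains *μ* (new pathogenic alleles
accrue to the case-enriched pool — where replenishment enters is not
fixed by the balance argument itself, and this choice makes the fixed
point exactly the closed-form ν, which the property tests verify to
10⁻⁶ relative error for all three presets). The control frequency is the
fixed anchor, so the trajectory's (mA, mU, mG) triple satisfies the
decomposition identity to 10⁻¹² at every generation by construction. The
recurrence contracts whenever *s*/(1−*sp*) < 2 — monotonically for
*s*(1+*p*) ≤ 1, with damped oscillation above — which covers every
disease-plausible parameter set; the divergent regime (prevalence near or
above one half with *s* near 1) is reported via a `converged=False` flag
rather than raised. Convergence tolerance 10⁻¹⁰ on |Δd| per generation,
cap 10⁶ generations.

**Maternal carrier model.** Because mitochondrial DNA passes only through
females, carrier dynamics depend on female fitnesses alone. A two-class
model tracks the fraction of females carrying pathogenic mtDNA: with
penetrance π a carrier is affected (relative fitness w_A) or unaffected
(w_U), non-carrier fitness 1. The next carrier frequency is the
fitness-weighted carrier mass normalised by mean female fitness, plus de
novo conversion of non-carriers. This functional form is this package's
own construction — the qualitative claim it operationalises is that
w_U > 1 (a slight advantage of unaffected carrier females) plus
mitochondrial-scale de novo mutation can hold carriers stable under
selection that would eliminate a nuclear allele. Defaults: w_A = 0.45
(observed female-patient fitness 0.4–0.5), w_U = 1.05 (observed
unaffected-sister advantage 1.02–1.08), de novo rate 4.3×10⁻³ (the
8.8×10⁻⁴–1.3×10⁻² mitochondrial range's average); carrier frequency
0.014 with penetrance 0.5 are the package's choice so that their product
matches a ~0.7% prevalence. The deterministic recurrence is the default;
a binomial stochastic mode requires an explicit seed. No claim is made
about any particular published value of the cross-generational carrier
loss; the model is parameterised, not fitted.

**Transmission arithmetic.** `sporadic_fraction` is the de novo rate over
the prevalence (capped at 1); `maternal_excess_test` is the exact
binomial upper tail, delegated to scipy's `binom.sf` and cross-checked in
tests against exhaustive enumeration up to n = 16.

## Synthetic data

The generator emulates the statistical skeleton of a published
case-control catalog: genes scattered round-robin over a configurable arm
pool, each with 1–3 variants whose *d* values are drawn either inside
(0, ν) or at/above ν according to a per-gene meeting assignment, and
control frequencies uniform on (0.05, 0.85). Emitted truth labels are
consistent with the generated frequencies by construction, which is what
makes the "classifier recovers ground truth exactly" guard meaningful.
Seeding uses one root seed with per-(gene, variant) `SeedSequence` spawn
keys, so existing rows are unchanged when a catalog grows. The generator
does **not** model linkage disequilibrium, population stratification,
genotyping error, or realistic minor-allele-frequency spectra — passing
tests show the pipeline's internal consistency, not robustness to those
features of real data.

`empirical_power` samples allele counts binomially (two alleles per
subject, cases and controls independent) and applies the pooled
two-proportion z-test — the test implicit in the d-based sample-size
formula. Monte-Carlo checks use 2000 replicates, which puts one binomial
standard error at ≈0.009 around a true power of 0.8; designs in tests are
kept at a few hundred to a few thousand pairs so the whole suite runs in
seconds.

## Numerical choices and limitations

- Strict-inequality tie-break: *d* = ν classifies EXCEEDS.
- All thresholds and differences compared at full double precision;
  3-significant-figure (ν) and 2-significant-figure (N) rounding happens
  only in display fields and presentation helpers.
- The classifier is arm-granular by design; physical distance and LD
  adjacency are out of scope.
- Published odds-ratio columns are meta-analytic summaries and are not
  reproducible from pooled frequencies; `odds_ratio_from_freqs` exists as
  a diagnostic, and one catalog row is kept in the tests precisely to
  document the mismatch.
- The per-gene "meets" rollup counts genes, not variants; a source that
  quotes a variant-level headline count for the same data may differ
  where a gene carries several qualifying variants.
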