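"""Generate twin synthetic cohorts with a shared planted gene signature.

The two cohorts mirror the structure of pediatric AHRF microarray studies:
a 26-control / 70-case ARDS-style cohort and a 65-control / 96-case
sepsis-style cohort, probe-level log2 intensities, and 30 informative genes
planted in both.
"""

from ahrfsig import CohortSpec, generate_paired_cohorts

spec_a = CohortSpec(n_cases=70, n_controls=26, n_genes=2000, n_informative=40,
                    effect_size=0.5, noise_sd=0.5, seed=1)
spec_b = CohortSpec(n_cases=96, n_controls=65, n_genes=2000, n_informative=40,
                    effect_size=0.5, noise_sd=0.5, seed=2)
(ma, ta), (mb, tb) = generate_paired_cohorts(spec_a, spec_b,
                                             shared_informative=30)

shared = set(ta.informative_genes) & set(tb.informative_genes)
print(f"cohort A: {ma.n_features} probes x {ma.n_samples} samples, "
      f"{100 * (ma.classes == 'control').mean():.1f}% mild")
print(f"cohort B: {mb.n_features} probes x {mb.n_samples} samples, "
      f"{100 * (mb.classes == 'control').mean():.1f}% mild")
print(f"planted: {len(ta.informative_genes)} informative per cohort, "
      f"{len(shared)} shared")
# The probe counts exceed the 2,000 genes because ~30% of genes carry
# multiple probes, as on expression arrays.
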