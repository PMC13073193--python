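"""Hardy-Weinberg imputation of missing genotypes and entropy features.

Masks 14 whole panel SNPs (the situation when an external cohort's
genotyping platform lacks part of the panel), imputes them from reference
allele frequencies under HWE, and computes the per-subject genotype-entropy
descriptor before and after.
"""

import numpy as np

import t1dprs as t

panel = t.load_panel()
cohort = t.simulate_cohort(t.SimulationConfig(n_subjects=2_000, seed=4), panel)

ref = t.build_reference(cohort.genotypes, cohort.subjects, target_prevalence=0.10, seed=4)
masked = t.inject_missingness(cohort.genotypes, pattern="whole_snps", k_snps=14, seed=4)
print(f"columns fully missing after masking: {masked.n_missing_columns}")

imputed = t.impute(masked, ref, mode="expected")
print(f"missing entries after HWE imputation: {int(imputed.missing_mask.sum())}")
complete = t.impute(cohort.genotypes, ref)  # no-op on fully observed data

# expected-dosage imputation fills each missing cell with 2q
j = 0
q = ref.q[j]
print(f"example SNP {ref.rsids[j]}: q = {q:.3f}, imputed dosage = {2*q:.3f}")

# per-subject genotype entropy (bits): higher = rarer genotype profile
h_complete = t.subject_entropy(complete.dosages, ref, panel.rsids)
h_imputed = t.subject_entropy(imputed.dosages, ref, panel.rsids)
print(f"mean entropy, complete data: {np.mean(h_complete):.2f} bits")
print(f"mean entropy, 14 SNPs imputed: {np.mean(h_imputed):.2f} bits")
# imputed subjects drift toward the most common genotype classes, so their
# entropy moves toward the population-typical value
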