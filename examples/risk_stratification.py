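"""Five-category risk stratification and prevalence-aware predictive values.

Shows the two halves of the stratification module: (1) the closed-form Bayes
arithmetic that turns a sensitivity/specificity pair and an assumed
prevalence into PPV/NPV, and (2) the category-distribution table for a
cohort of predicted probabilities.
"""

import numpy as np

import t1dprs as t

# (1) predictive values at a screening prevalence of 10%: a test with
# sensitivity 94.5% and specificity 54.5% at the very-low cut-off
ppv, npv = t.predictive_values(0.9450, 0.5454, prevalence=0.10)
print(f"threshold 0.1:  PPV {100*ppv:.2f}%  NPV {100*npv:.2f}%")
# the high NPV (98.9%) is what makes the lowest category useful for
# rule-out screening, despite the modest PPV

# the same pair at a 70.6% prevalence cohort (antibody-positive cases vs
# controls) gives a very different picture
ppv, npv = t.predictive_values(0.9450, 0.5454, prevalence=295 / 418)
print(f"same test, 70.6% prevalence:  PPV {100*ppv:.2f}%  NPV {100*npv:.2f}%")

# (2) category distribution of a synthetic test cohort
rng = np.random.default_rng(3)
p = np.concatenate([rng.beta(6, 2, 300), rng.beta(2, 6, 2_700)])  # cases, controls
groups = np.array(["case"] * 300 + ["control"] * 2_700)
dist = t.category_distribution(p, groups)
print("\npercentage of each group per risk category:")
print(dist.round(2))
# each column sums to 100; well-separated cohorts put most controls in
# very_low/low and most cases in high/very_high
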