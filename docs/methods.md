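# Methods

## Panel and encodings

The packaged panel holds 67 GRCh37 variants, each with a dbSNP identifier,
a risk allele (A/C/G/T, or I/D for indels), a signed log-odds weight β, and
coordinates. Panel order is canonical: every downstream matrix aligns its
columns to it regardless of the order variants appear in a source file.

Genotypes are ingested as risk-allele dosages. For VCF sources, variants
are matched by ID first, then by (chromosome, position); if the risk allele
is the ALT, dosage is the ALT count, and if it is the REF, dosage is
2 − ALT count. Indel codes are resolved by length: I matches the longer of
REF/ALT, D the shorter. A variant whose alleles cannot represent the risk
allele raises an error naming the rsid — silent strand guessing is worse
than failing. Malformed or missing genotype calls become masked entries;
panel variants absent from a source become all-missing columns. The
delimited interchange format is a matrix with an rsid header row, a
subject-id first column and cells in {0,1,2,NA}.

The `count` encoding is the identity on dosages; `beta_weighted` multiplies
each column by its β. Both require fully imputed input, so encoding can
never silently absorb missingness.

## Reference frequencies and Hardy–Weinberg imputation

Allele frequencies are estimated on a prevalence-controlled subsample: all
minority-class subjects are kept and the majority class is randomly
undersampled (seeded) until the case fraction equals the target (default
0.10, the enrichment typical of high-risk screening populations), up to
one-subject rounding. Per SNP, q is the mean observed dosage divided by 2
and the empirical genotype-class frequencies are recorded; classes never
observed receive a floor of 1e−6 (renormalised) so that downstream log₂
terms stay finite without materially changing any frequency.

Missing dosages are imputed under HWE. The default `expected` mode fills
2q — deterministic, and standard practice for dosage-based scores; the
`sampled` mode draws an integer genotype from ((1−q)², 2q(1−q), q²) with an
explicit seed, for sensitivity analyses. Imputation takes no labels as
input, so it is label-blind by construction. Whole-cohort missing columns
(e.g. 14 panel SNPs absent from an external genotyping platform) are filled
the same way as any other missing entry.

## Entropy features

For subject s, `H(s) = −Σ_i p_i log₂ p_i` (bits), where p_i is the
empirical reference-population frequency of the subject's genotype class at
SNP i — the genotype frequency, not the allele frequency. Expected-dosage
values are rounded to the nearest class for the lookup. Three
configurations exist: one global column, one column per panel chromosome,
or both; by additivity of the sum, per-chromosome values add up exactly to
the global value. Entropy columns (names prefixed `H_`) are z-scored inside
`fit` using training-set statistics, because their scale (tens of bits)
would otherwise dwarf the bounded dosage features; dosage and β-weighted
columns are fed raw. Entropy is an exploratory descriptor — nothing in this
package claims it improves discrimination.

## Linear GRS

`S = Σ_j β_j d_j`, linear and panel-order invariant. Min-max normalisation
to [0, 1] is computed over a stated cohort; out-of-cohort subjects are
mapped with the cohort's min/max and clipped. Min-max was chosen because it
is the convention under which fixed probability-style thresholds
(0.1–0.9) are meaningful on a score scale; AUC is unaffected by any strictly
increasing transform, which the tests assert. The benchmark is deliberately
the additive 67-SNP score only — no HLA haplotype interaction terms.

## Classifier and training protocol

Architecture: input → 256 → 128 → 64 → 1; ReLU hidden activations; dropout
after each hidden layer at 0.40/0.30/0.20 (the published schedule runs
"from 40% to 20%"; the middle rate is linearly interpolated); sigmoid
output; Glorot-uniform initialisation. Training: binary cross-entropy,
mini-batches of 32, SGD or Adam, learning rates {0.1, 0.01, 0.001} in the
grid, maximum 1000 epochs. Early stopping monitors validation loss on a 10%
stratified split of the training data with patience 20 and restores the
best-epoch weights; the split size and patience are implementation choices
sized so that full training runs finish in minutes on one CPU. The default
configuration outside grid search is SGD at 0.001 — the most stable grid
point. A class-weighted loss is available but off by default; undersampling
is the primary imbalance strategy.

The network is implemented directly on NumPy arrays (forward, backprop,
inverted dropout, both optimizers) with every stochastic step — weight
init, dropout masks, batch shuffling, validation split — drawn from
explicit seeds, so identical seeds give bitwise-identical models. Training
raises on a non-finite loss, reporting epoch and learning rate.

Resampling: undersampling keeps all cases and takes a prefix of one seeded
control permutation, which makes the 1:1/1:2/1:3 control sets nested by
construction. The train/test split reserves 20% of case/control subjects at
a fixed 1:9 test ratio (up to one-subject rounding); auxiliary controls
(e.g. a type 2 diabetes negative-control group) are never trained on and
are routed to the test side for descriptive stratification. Grid search is
stratified five-fold CV by mean AUC with a deterministic tie-break (lower
learning rate, then SGD before Adam).

AUC is the midrank Mann–Whitney statistic (ties count half). The DeLong
variance uses per-positive and per-negative placement values,
`var = var(V10)/m + var(V01)/n`, with a normal-approximation 95% CI clipped
to [0, 1].

## Risk stratification

Categories partition [0, 1] at cuts 0.10/0.35/0.65/0.90 with left-closed
upper intervals: p = 0.10 falls in "low", and a positive call at threshold
t means p ≥ t. This makes the category and threshold views coherent:
sensitivity at the first cut equals one minus the case fraction in
very-low, and specificity equals the control fraction there. PPV/NPV come
from the Bayes identities at a stated prevalence: 0.10 for screening-style
cohorts, and the observed case fraction (e.g. 295/418 when comparing
antibody-positive cases against controls) for external cohorts, since
predictive values are prevalence-dependent by nature. In tabulated output a
threshold at which one side has no calls yields NaN predictive values
rather than an exception; the scalar function keeps the strict error. The
density summary is a Gaussian KDE (Scott bandwidth) on a 512-point grid
over [0, 1], renormalised after truncation to the unit interval — purely
descriptive.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes and
nothing more: dosages are independent Binomial(2, q_j) draws (HWE at every
SNP), labels follow a logistic liability `P(case) = σ(α + γ_s Σ_j β_j d_sj)`
with the packaged β values as true effects, and α calibrated by bisection
(Brent, tolerance 1e−6 on the mean) so expected prevalence hits the target
(default 0.10). Allele frequencies default to one seeded Uniform(0.05,
0.95) draw per SNP — the source panel's frequencies are not published — and
explicit vectors are accepted for reproducibility.

An attenuated subgroup (fraction of subjects with effect scale γ < 1)
emulates an antibody-negative-like stratum with weaker genetic signal. The
intercept is calibrated separately within each stratum so both strata hit
the target prevalence: subgroup membership weakens the genotype–disease
coupling, not the disease rate. (A single shared intercept would, at this
panel's effect scale, drive the attenuated stratum's case probability to
zero — a degenerate cohort no study design resembles.) With γ = 0 the
stratum's labels are independent of the score; with intermediate γ the
stratum's AUC sits strictly between 0.5 and the full-effect AUC, which is
the qualitative ordering observed between antibody-negative and
antibody-positive strata.

Missingness is MCAR only: independent entry masking at a given rate, or
whole-column masking of k SNPs (emulating platform gaps). Labels are never
consulted.

What the generator does **not** emulate: linkage disequilibrium, population
structure and relatedness, HLA haplotype effects and epistasis,
genotyping-batch artefacts, and informative missingness. Passing tests
therefore demonstrate that the pipeline recovers the signal it assumes
(additive logistic liability under HWE), not that it would achieve any
particular performance on real cohorts.

## Problem sizes and numerical choices

The test and acceptance runs use cohorts of 20,000 subjects (parameter
recovery; five seeds) and 8,000 subjects (subgroup ordering), with training
capped at 400 epochs — early stopping ends runs far earlier, and the cap
changes nothing at these sizes. Goodness-of-fit checks use 10,000 draws and
α = 0.01; the bootstrap comparison for the DeLong variance uses n = 200
subjects and 2,000 replicates. Probabilities are clipped to
[1e−7, 1 − 1e−7] inside the loss and [1e−12, 1 − 1e−12] at prediction;
genotype-frequency floors are 1e−6. All tolerances asserted in tests are
stated next to the assertion.

## Known limitations

- The classifier runs on CPU via NumPy; it is sized for this panel (tens of
  features, tens of thousands of subjects), not for genome-wide input.
- Probability calibration is not assessed; outputs are used for ranking and
  threshold stratification only.
- HWE imputation is biased exactly where HWE fails — notably under
  selection near immune loci; LD-aware imputation is out of scope.
- The linear benchmark omits haplotype interaction terms, so it is an
  additive approximation to the published score it stands in for.
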