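"""Per-subject genotype-entropy features.

For subject *s* with genotype class g_i (0/1/2 risk-allele copies) at SNP i,
and p_i the reference-population frequency of that genotype class,

    H(s) = - sum_i p_i * log2(p_i)      [bits]

Rare genotypes contribute large terms, so H measures how far a subject's
genotype profile deviates from population expectations.  Three feature
configurations are supported: one global value over the whole panel, one
value per panel chromosome, or both concatenated.  The sum over SNPs is
additive, so per-chromosome entropies sum exactly to the global value.
"""

from __future__ import annotations

import numpy as np

from .hwe import ReferenceFrequencies
from .panel import FeatureMatrix, GenotypeMatrix

CONFIGURATIONS = ("global", "per_chromosome", "combined")


def _entropy_terms(
    dosage_rows: np.ndarray, ref: ReferenceFrequencies, rsids: list[str]
) -> np.ndarray:
    """Per-entry contributions -p*log2(p) for each (subject, SNP)."""
    if np.isnan(dosage_rows).any():
        raise ValueError("dosages must be fully imputed before entropy computation")
    ref_idx = np.array([ref.index_of(r) for r in rsids])
    freqs = ref.genotype_freqs[ref_idx]  # (n_snps, 3)
    classes = np.clip(np.rint(dosage_rows), 0, 2).astype(int)  # (n, n_snps)
    p = freqs[np.arange(len(rsids))[np.newaxis, :], classes]
    return -p * np.log2(p)


def subject_entropy(
    dosages: np.ndarray,
    ref: ReferenceFrequencies,
    rsids: list[str],
    snp_subset: list[str] | None = None,
) -> float | np.ndarray:
    """Genotype entropy in bits for one subject (1-D dosages) or many (2-D).

    ``rsids`` names the columns of ``dosages``; ``snp_subset`` restricts the
    sum to those SNPs (e.g. one chromosome).  Real-valued expected dosages are
    mapped to the nearest genotype class for the frequency lookup.
    """
    arr = np.atleast_2d(np.asarray(dosages, dtype=float))
    if snp_subset is not None:
        cols = [rsids.index(r) for r in snp_subset]
        arr = arr[:, cols]
        rsids = list(snp_subset)
    terms = _entropy_terms(arr, ref, rsids)
    h = terms.sum(axis=1)
    return float(h[0]) if np.asarray(dosages).ndim == 1 else h


def augment_features(
    features: FeatureMatrix,
    genotypes: GenotypeMatrix,
    ref: ReferenceFrequencies,
    configuration: str = "global",
) -> FeatureMatrix:
    """Append entropy columns to a feature matrix.

    Added columns are named ``H_global`` and/or ``H_chr<label>``; the
    classifier z-scores columns with this prefix using training-set statistics
    (their scale, tens of bits, would otherwise dwarf dosage features).
    """
    if configuration not in CONFIGURATIONS:
        raise ValueError(
            f"unknown entropy configuration {configuration!r}; choose from {CONFIGURATIONS}"
        )
    if features.subject_ids != genotypes.subject_ids:
        raise ValueError("features and genotypes must be aligned on subjects")
    if genotypes.has_missing:
        raise ValueError("impute genotypes before computing entropy features")
    rsids = genotypes.panel.rsids
    terms = _entropy_terms(genotypes.dosages, ref, rsids)

    cols: list[np.ndarray] = []
    names: list[str] = []
    if configuration in ("global", "combined"):
        cols.append(terms.sum(axis=1))
        names.append("H_global")
    if configuration in ("per_chromosome", "combined"):
        chroms = genotypes.panel.chromosomes
        for c in sorted(set(chroms), key=lambda x: (len(x), x)):
            idx = [j for j, cj in enumerate(chroms) if cj == c]
            cols.append(terms[:, idx].sum(axis=1))
            names.append(f"H_chr{c}")
    values = np.column_stack([features.values] + [c[:, np.newaxis] for c in cols])
    return FeatureMatrix(
        values=values,
        feature_names=list(features.feature_names) + names,
        encoding=features.encoding,
        subject_ids=list(features.subject_ids),
    )
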