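"""Reference allele frequencies and Hardy-Weinberg imputation of missing genotypes.

Missing dosages are filled from allele frequencies estimated on a
prevalence-controlled reference subsample of the cohort, under the
Hardy-Weinberg equilibrium genotype law ((1-q)^2, 2q(1-q), q^2).  Imputation
never consults case/control labels: the reference subsample fixes the case
fraction once, and every missing entry is filled from the same per-SNP
frequencies regardless of the subject's label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, SubjectTable

#: floor applied to unobserved genotype classes so downstream log2 is finite
FREQUENCY_FLOOR = 1e-6


@dataclass
class ReferenceFrequencies:
    """Per-SNP risk-allele frequency q and empirical genotype frequencies."""

    rsids: list[str]
    q: np.ndarray                  # risk-allele frequency per SNP
    genotype_freqs: np.ndarray     # (n_snps, 3) frequencies of dosage 0/1/2
    n_reference: int
    target_prevalence: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.genotype_freqs = np.asarray(self.genotype_freqs, dtype=float)
        if self.q.shape != (len(self.rsids),):
            raise ValueError("q length mismatch")
        if self.genotype_freqs.shape != (len(self.rsids), 3):
            raise ValueError("genotype_freqs must be (n_snps, 3)")
        if np.any(self.q < 0) or np.any(self.q > 1):
            raise ValueError("q must lie in [0, 1]")
        sums = self.genotype_freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("genotype frequencies must sum to 1 per SNP")

    def index_of(self, rsid: str) -> int:
        try:
            return self.rsids.index(rsid)
        except ValueError as exc:
            raise KeyError(f"SNP {rsid} absent from reference frequencies") from exc

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "rsid": self.rsids,
                "q": self.q,
                "f0": self.genotype_freqs[:, 0],
                "f1": self.genotype_freqs[:, 1],
                "f2": self.genotype_freqs[:, 2],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, n_reference: int = 0, target_prevalence: float = float("nan")
    ) -> "ReferenceFrequencies":
        df = pd.read_csv(path, sep="\t")
        return cls(
            rsids=list(df["rsid"]),
            q=df["q"].to_numpy(),
            genotype_freqs=df[["f0", "f1", "f2"]].to_numpy(),
            n_reference=n_reference,
            target_prevalence=target_prevalence,
        )


def _reference_subsample(
    subjects: SubjectTable, target_prevalence: float, rng: np.random.Generator
) -> list[str]:
    """Undersample the majority class so cases/(cases+controls) hits the target."""
    cases = [s for s, l in zip(subjects.subject_ids, subjects.labels) if l == "case"]
    controls = [s for s, l in zip(subjects.subject_ids, subjects.labels) if l == "control"]
    n_cases, n_controls = len(cases), len(controls)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("reference subsample needs both cases and controls")
    t = target_prevalence
    if not 0 < t < 1:
        raise ValueError("target_prevalence must lie in (0, 1)")
    # controls needed to pair with all cases at prevalence t
    want_controls = int(np.floor(n_cases * (1 - t) / t))
    if want_controls <= n_controls:
        keep_controls = list(rng.permutation(controls)[:want_controls])
        return cases + keep_controls
    # controls are the minority: undersample cases instead
    want_cases = int(np.floor(n_controls * t / (1 - t)))
    if want_cases < 1:
        achievable = n_cases / (n_cases + n_controls)
        raise ValueError(
            f"target prevalence {t} unreachable; cohort supports at most ~{achievable:.4f}"
        )
    keep_cases = list(rng.permutation(cases)[:want_cases])
    return keep_cases + controls


def build_reference(
    genotypes: GenotypeMatrix,
    subjects: SubjectTable,
    target_prevalence: float = 0.10,
    seed: int = 0,
) -> ReferenceFrequencies:
    """Estimate per-SNP allele and genotype frequencies from a prevalence-controlled subsample.

    All cases are retained and controls are randomly undersampled (or vice
    versa if controls are the minority) so that the case fraction of the
    subsample equals ``target_prevalence`` up to one-subject rounding.
    Frequencies ignore masked entries; unobserved genotype classes receive a
    small floor so entropy terms stay finite.
    """
    rng = np.random.default_rng(seed)
    chosen = _reference_subsample(subjects, target_prevalence, rng)
    sub = genotypes.subset(chosen)
    m = len(sub.panel)
    q = np.zeros(m)
    gf = np.zeros((m, 3))
    for j in range(m):
        obs = sub.dosages[~sub.missing_mask[:, j], j]
        if obs.size == 0:
            # SNP unobserved everywhere: fall back to maximal uncertainty
            q[j] = 0.5
            gf[j] = hwe_genotype_probs(0.5)
            continue
        classes = np.clip(np.rint(obs), 0, 2).astype(int)
        q[j] = classes.mean() / 2.0
        counts = np.bincount(classes, minlength=3).astype(float)
        gf[j] = counts / counts.sum()
    gf = _floor_and_renormalize(gf)
    return ReferenceFrequencies(
        rsids=list(sub.panel.rsids),
        q=q,
        genotype_freqs=gf,
        n_reference=len(chosen),
        target_prevalence=target_prevalence,
    )


def _floor_and_renormalize(gf: np.ndarray) -> np.ndarray:
    gf = np.maximum(gf, FREQUENCY_FLOOR)
    return gf / gf.sum(axis=1, keepdims=True)


def hwe_genotype_probs(q: float | np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2) for dosages 0/1/2."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("allele frequency q must lie in [0, 1]")
    probs = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)
    return probs


IMPUTE_MODES = ("expected", "sampled")


def impute(
    genotypes: GenotypeMatrix,
    ref: ReferenceFrequencies,
    mode: str = "expected",
    seed: int = 0,
) -> GenotypeMatrix:
    """Fill missing dosages under Hardy-Weinberg equilibrium.

    ``expected`` fills each missing entry with the expected dosage 2q (a real
    value, carried through encoding as-is); ``sampled`` draws an integer
    genotype from the HWE law with the given seed.  Observed entries are never
    modified and labels are never consulted.
    """
    if mode not in IMPUTE_MODES:
        raise ValueError(f"unknown impute mode {mode!r}; choose from {IMPUTE_MODES}")
    for rsid in genotypes.panel.rsids:
        ref.index_of(rsid)  # raises KeyError if absent
    if not genotypes.has_missing:
        return GenotypeMatrix(
            list(genotypes.subject_ids),
            genotypes.dosages.copy(),
            genotypes.missing_mask.copy(),
            genotypes.panel,
        )
    dosages = genotypes.dosages.copy()
    rng = np.random.default_rng(seed)
    ref_idx = [ref.index_of(r) for r in genotypes.panel.rsids]
    q = ref.q[ref_idx]
    for j in range(len(genotypes.panel)):
        miss = genotypes.missing_mask[:, j]
        k = int(miss.sum())
        if k == 0:
            continue
        if mode == "expected":
            dosages[miss, j] = 2.0 * q[j]
        else:
            probs = hwe_genotype_probs(q[j])
            dosages[miss, j] = rng.choice(3, size=k, p=probs)
    mask = np.zeros_like(genotypes.missing_mask)
    return GenotypeMatrix(list(genotypes.subject_ids), dosages, mask, genotypes.panel)
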