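"""Synthetic genotype cohorts with the statistical structure the pipeline assumes.

Genotypes are independent Hardy-Weinberg draws (dosage ~ Binomial(2, q_j));
disease labels follow a logistic liability on the additive beta-weighted
score, with the intercept calibrated by bisection so the expected prevalence
hits the target exactly.  An attenuated-effect case subgroup (per-subject
effect scaling gamma < 1) emulates an antibody-negative stratum whose genetic
signal is weaker, and MCAR missingness (random entries or whole SNP columns)
emulates array drop-out and panel gaps in external cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .panel import GenotypeMatrix, SNPPanel, SubjectTable


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the cohort structure the pipeline targets: ~10% disease
    prevalence, panel betas as true additive effects, allele frequencies
    drawn once per run from Uniform(0.05, 0.95) (panel frequencies are not
    published), and no attenuated subgroup unless requested.
    """

    n_subjects: int = 10_000
    panel: SNPPanel | None = None
    allele_freqs: np.ndarray | None = None   # explicit per-SNP q; else drawn
    target_prevalence: float = 0.10
    missing_rate: float = 0.0
    subgroup_fraction: float = 0.0           # fraction of subjects with attenuated effects
    attenuation: float = 1.0                 # gamma, scales beta for the subgroup
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.subgroup_fraction <= 1:
            raise ValueError("subgroup_fraction must lie in [0, 1]")
        if not 0 <= self.attenuation <= 1:
            raise ValueError("attenuation gamma must lie in [0, 1]")
        if self.allele_freqs is not None:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if np.any(self.allele_freqs <= 0) or np.any(self.allele_freqs >= 1):
                raise ValueError("explicit allele frequencies must lie in (0, 1)")


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    subjects: SubjectTable
    true_linear_score: np.ndarray   # sum_j beta_j * dosage_sj (unattenuated)
    intercept: float                # alpha of the full-effect liability stratum
    allele_freqs: np.ndarray
    attenuation_mask: np.ndarray    # True where gamma was applied
    intercept_attenuated: float | None = None  # alpha of the attenuated stratum


def _resolve_freqs(config: SimulationConfig, rng: np.random.Generator, m: int) -> np.ndarray:
    if config.allele_freqs is not None:
        if len(config.allele_freqs) != m:
            raise ValueError("allele_freqs length must equal panel size")
        return config.allele_freqs
    return rng.uniform(0.05, 0.95, size=m)


def sample_genotypes(
    config: SimulationConfig, panel: SNPPanel, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Independent HWE genotypes: dosage_sj ~ Binomial(2, q_j)."""
    rng = rng or np.random.default_rng(config.seed)
    m = len(panel)
    q = _resolve_freqs(config, rng, m)
    dosages = rng.binomial(2, q, size=(config.n_subjects, m)).astype(float)
    ids = [f"S{i:06d}" for i in range(config.n_subjects)]
    mask = np.zeros_like(dosages, dtype=bool)
    return GenotypeMatrix(ids, dosages, mask, panel), q


def calibrate_intercept(
    scores: np.ndarray, target_prevalence: float, gamma: np.ndarray | float = 1.0
) -> float:
    """Intercept alpha with mean_s sigmoid(alpha + gamma_s * score_s) = target.

    The mean sigmoid is strictly increasing in alpha, so bisection on a
    bracket spanning the score range always converges; solved to 1e-6.
    """
    scores = np.asarray(scores, dtype=float)
    g = np.broadcast_to(np.asarray(gamma, dtype=float), scores.shape)
    eff = g * scores
    logit_t = float(np.log(target_prevalence / (1 - target_prevalence)))

    def mean_prev(alpha: float) -> float:
        return float(_sigmoid(alpha + eff).mean()) - target_prevalence

    lo = logit_t - float(eff.max()) - 1.0
    hi = logit_t - float(eff.min()) + 1.0
    return float(brentq(mean_prev, lo, hi, xtol=1e-8))


def assign_labels(
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SubjectTable, np.ndarray, float, np.ndarray]:
    """Draw case/control labels from the logistic liability model.

    A seeded ``subgroup_fraction`` of subjects carries the attenuation gamma
    in its generative probability; attenuated cases are tagged
    ``attenuated`` and the rest ``full_effect`` (emulating antibody-negative
    vs antibody-positive strata).  The intercept is calibrated separately
    within each stratum so that both hit the target prevalence — subgroup
    membership weakens the genetic signal, not the disease rate.  Returns
    (subjects, true_linear_score, intercepts, attenuation_mask) where
    ``intercepts`` is (alpha_full, alpha_attenuated_or_None).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    score = genotypes.dosages @ panel.betas
    n = len(score)
    atten = rng.random(n) < config.subgroup_fraction
    gamma = np.where(atten, config.attenuation, 1.0)
    p_case = np.empty(n)
    alpha_att = None
    if atten.all():
        alpha = calibrate_intercept(
            score[atten], config.target_prevalence, config.attenuation
        )
        alpha_att = alpha
        p_case[:] = _sigmoid(alpha + gamma * score)
    else:
        alpha = calibrate_intercept(score[~atten], config.target_prevalence, 1.0)
        p_case[~atten] = _sigmoid(alpha + score[~atten])
        if atten.any():
            alpha_att = calibrate_intercept(
                score[atten], config.target_prevalence, config.attenuation
            )
            p_case[atten] = _sigmoid(alpha_att + config.attenuation * score[atten])
    is_case = rng.random(n) < p_case
    labels = ["case" if c else "control" for c in is_case]
    subgroups: list[str | None] = [
        ("attenuated" if a else "full_effect") if c else None
        for c, a in zip(is_case, atten)
    ]
    subjects = SubjectTable(list(genotypes.subject_ids), labels, subgroups)
    return subjects, score, (alpha, alpha_att), atten


MISSINGNESS_PATTERNS = ("random_entries", "whole_snps")


def inject_missingness(
    genotypes: GenotypeMatrix,
    missing_rate: float = 0.0,
    pattern: str = "random_entries",
    k_snps: int | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Mask dosages missing-completely-at-random; labels are never consulted.

    ``random_entries`` masks each entry independently at ``missing_rate``;
    ``whole_snps`` masks ``k_snps`` entire columns (emulating panel variants
    absent from an external genotyping platform).
    """
    if pattern not in MISSINGNESS_PATTERNS:
        raise ValueError(f"pattern must be one of {MISSINGNESS_PATTERNS}")
    rng = np.random.default_rng(seed)
    mask = genotypes.missing_mask.copy()
    if pattern == "random_entries":
        if not 0 <= missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        mask |= rng.random(genotypes.dosages.shape) < missing_rate
    else:
        if k_snps is None or not 0 <= k_snps <= len(genotypes.panel):
            raise ValueError("whole_snps pattern needs k_snps <= panel size")
        cols = rng.choice(len(genotypes.panel), size=k_snps, replace=False)
        mask[:, cols] = True
    return GenotypeMatrix(
        list(genotypes.subject_ids), genotypes.dosages.copy(), mask, genotypes.panel
    )


def simulate_cohort(config: SimulationConfig, panel: SNPPanel) -> SyntheticCohort:
    """Full generative run: genotypes, labels, optional missingness."""
    rng = np.random.default_rng(config.seed)
    genotypes, q = sample_genotypes(config, panel, rng)
    subjects, score, (alpha, alpha_att), atten = assign_labels(genotypes, panel, config, rng)
    if config.missing_rate > 0:
        genotypes = inject_missingness(
            genotypes, config.missing_rate, "random_entries", seed=config.seed + 2
        )
    return SyntheticCohort(
        genotypes=genotypes,
        subjects=subjects,
        true_linear_score=score,
        intercept=alpha,
        allele_freqs=q,
        attenuation_mask=atten,
        intercept_attenuated=alpha_att,
    )
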