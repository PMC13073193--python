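"""Linear beta-weighted genetic risk score (the GRS2-style additive benchmark).

The score for subject s is the additive log-odds sum over the panel,
raw_s = sum_j beta_j * dosage_sj, optionally min-max normalised to [0, 1]
over a stated cohort.  Normalisation is strictly monotone, so rank-based
metrics (AUC) are identical on raw and normalised scores; only
threshold-level metrics depend on the normalisation cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, SNPPanel


@dataclass
class GRSResult:
    subject_ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.subject_ids),):
            raise ValueError("raw score length mismatch")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"subject_id": self.subject_ids, "raw": self.raw})
        if self.normalized is not None:
            df["normalized"] = self.normalized
        df.to_csv(path, index=False)


def compute_grs(genotypes: GenotypeMatrix, panel: SNPPanel | None = None) -> GRSResult:
    """Raw beta-weighted score per subject; genotypes must be fully imputed."""
    panel = panel or genotypes.panel
    if panel.rsids != genotypes.panel.rsids:
        raise ValueError("panel does not match genotype columns")
    if genotypes.has_missing:
        raise ValueError("genotypes contain missing dosages; impute first")
    raw = genotypes.dosages @ panel.betas
    return GRSResult(list(genotypes.subject_ids), raw)


def normalize_scores(result: GRSResult, cohort: list[str] | None = None) -> GRSResult:
    """Min-max rescale raw scores to [0, 1] over the stated cohort.

    Subjects outside the cohort are mapped with the cohort's min/max and
    clipped to [0, 1].
    """
    if cohort is None:
        cohort_scores = result.raw
    else:
        idx = {s: i for i, s in enumerate(result.subject_ids)}
        cohort_scores = result.raw[[idx[s] for s in cohort]]
    lo, hi = float(np.min(cohort_scores)), float(np.max(cohort_scores))
    if hi <= lo:
        raise ValueError("degenerate normalization: cohort scores are constant")
    normalized = np.clip((result.raw - lo) / (hi - lo), 0.0, 1.0)
    return GRSResult(list(result.subject_ids), result.raw.copy(), normalized)
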