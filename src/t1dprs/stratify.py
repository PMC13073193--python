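"""Five-category risk stratification and prevalence-aware predictive values.

Predicted probabilities are mapped to five categories (very low, low,
average, high, very high) by the cut points 0.10 / 0.35 / 0.65 / 0.90.
Threshold metrics use the convention "positive call iff p >= threshold", so
sensitivity at a cut point equals one minus the case fraction falling below
it.  PPV and NPV follow the Bayes identities

    PPV = se*pi / (se*pi + (1-sp)*(1-pi))
    NPV = sp*(1-pi) / (sp*(1-pi) + (1-se)*pi)

and therefore depend on the assumed prevalence pi (0.10 for a high-risk
screening population; an external cohort's observed case fraction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

CATEGORY_NAMES = ("very_low", "low", "average", "high", "very_high")


@dataclass(frozen=True)
class RiskThresholds:
    cuts: tuple[float, float, float, float] = (0.10, 0.35, 0.65, 0.90)
    names: tuple[str, ...] = CATEGORY_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != len(self.cuts) + 1:
            raise ValueError("need one more category name than cut points")
        if not all(0 < a < 1 for a in self.cuts) or list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError("cuts must be strictly increasing within (0, 1)")


DEFAULT_THRESHOLDS = RiskThresholds()


@dataclass(frozen=True)
class ConfusionMetrics:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float


def categorize(
    p: float | np.ndarray, thresholds: RiskThresholds = DEFAULT_THRESHOLDS
) -> str | np.ndarray:
    """Risk category for probability p; intervals are left-closed above (p = cut
    falls in the higher category)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    idx = np.searchsorted(np.asarray(thresholds.cuts), arr, side="right")
    cats = np.asarray(thresholds.names, dtype=object)[idx]
    return str(cats) if np.isscalar(p) or arr.ndim == 0 else cats


def threshold_metrics(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    """(sensitivity, specificity) with positive call iff p >= threshold."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("threshold metrics need both classes present")
    called = p >= threshold
    sens = float(called[y == 1].mean())
    spec = float((~called[y == 0]).mean())
    return sens, spec


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV from sensitivity/specificity at an assumed prevalence."""
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    ppv_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    npv_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    if ppv_den == 0:
        raise ZeroDivisionError("PPV undefined: no positive calls at this prevalence")
    if npv_den == 0:
        raise ZeroDivisionError("NPV undefined: no negative calls at this prevalence")
    ppv = sensitivity * prevalence / ppv_den
    npv = specificity * (1 - prevalence) / npv_den
    return ppv, npv


def metrics_table(
    probabilities: np.ndarray,
    labels: np.ndarray,
    prevalence: float,
    thresholds: Sequence[float] = (0.10, 0.35, 0.50, 0.65, 0.90),
) -> pd.DataFrame:
    """Sensitivity/specificity/PPV/NPV at each threshold (the printed-table layout)."""
    rows = []
    for t in thresholds:
        sens, spec = threshold_metrics(probabilities, labels, t)
        try:
            ppv, npv = predictive_values(sens, spec, prevalence)
        except ZeroDivisionError:
            # degenerate cell (no positive or no negative calls): undefined, not fatal
            ppv = npv = float("nan")
        rows.append(
            ConfusionMetrics(
                threshold=t, sensitivity=sens, specificity=spec,
                ppv=ppv, npv=npv, prevalence=prevalence,
            )
        )
    return pd.DataFrame(
        {
            "threshold": [r.threshold for r in rows],
            "sensitivity": [r.sensitivity for r in rows],
            "specificity": [r.specificity for r in rows],
            "ppv": [r.ppv for r in rows],
            "npv": [r.npv for r in rows],
        }
    )


def category_distribution(
    probabilities: np.ndarray,
    groups: Sequence[str],
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percentage of each group falling in each risk category.

    Rows are the five categories, columns the groups; each column sums to 100.
    ``group_order`` fixes the column order; groups named there but empty in
    the data are omitted with a warning.
    """
    import warnings

    p = np.asarray(probabilities, float)
    groups = np.asarray(groups, dtype=object)
    cats = categorize(p, thresholds)
    out = {}
    for g in group_order if group_order is not None else pd.unique(groups):
        mask = groups == g
        if not mask.any():
            warnings.warn(f"group {g!r} is empty; omitted")
            continue
        col = [100.0 * float((cats[mask] == name).mean()) for name in thresholds.names]
        out[str(g)] = col
    return pd.DataFrame(out, index=list(thresholds.names))


def distribution_summary(
    probabilities: np.ndarray,
    groups: Sequence[str],
    grid_size: int = 512,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> dict[str, dict]:
    """Numeric density summary per group: Gaussian KDE (Scott bandwidth) on a
    fixed grid over [0, 1] plus quantiles.  Groups with n < 2 get quantiles
    only."""
    p = np.asarray(probabilities, float)
    groups = np.asarray(groups, dtype=object)
    grid = np.linspace(0.0, 1.0, grid_size)
    summary: dict[str, dict] = {}
    for g in pd.unique(groups):
        vals = p[groups == g]
        entry: dict = {
            "n": int(len(vals)),
            "quantiles": {q: float(np.quantile(vals, q)) for q in quantiles},
            "median": float(np.median(vals)),
        }
        if len(vals) >= 2 and np.std(vals) > 0:
            kde = gaussian_kde(vals)  # Scott's rule by default
            dens = kde(grid)
            mass = np.trapezoid(dens, grid)
            dens = dens / mass  # renormalize the truncation to [0, 1]
            entry["grid"] = grid
            entry["density"] = dens
            entry["integral"] = float(np.trapezoid(dens, grid))
        summary[str(g)] = entry
    return summary
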