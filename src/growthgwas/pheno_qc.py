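"""Phenotype quality control for longitudinal body-weight records.

Three screening rules are applied, in a fixed order:

1. at each time point, records deviating by more than three standard
   deviations from that time point's mean are set missing (mean/SD computed
   once, before any masking);
2. body weight may decrease only slightly (<5%) between consecutive time
   points; a larger decrease sets the *later* record missing (comparison is
   against the nearest earlier surviving record when gaps exist);
3. individuals with more than two missing values over the schedule are
   removed entirely.

QC only masks or drops; it never alters a surviving weight value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import LongitudinalCohort

__all__ = [
    "QCReport",
    "PhenotypeQC",
    "mask_outliers_3sd",
    "enforce_decrease_rule",
    "drop_high_missing_individuals",
    "descriptive_stats",
]


def descriptive_stats(cohort: LongitudinalCohort) -> pd.DataFrame:
    """Per-time-point n, min, max, mean and SD of surviving records."""
    W = cohort.weights
    return pd.DataFrame(
        {
            "day": cohort.schedule,
            "n": W.notna().sum(axis=0).to_numpy(),
            "min": W.min(axis=0).to_numpy(),
            "max": W.max(axis=0).to_numpy(),
            "mean": W.mean(axis=0).to_numpy(),
            "sd": W.std(axis=0, ddof=1).to_numpy(),
        }
    )


@dataclass
class QCReport:
    """What a QC rule did: counts plus post-rule descriptive statistics."""

    rule: str
    n_masked: int = 0
    n_dropped_individuals: int = 0
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.n_masked < 0 or self.n_dropped_individuals < 0:
            raise ValueError("QC counts must be non-negative")


def mask_outliers_3sd(
    cohort: LongitudinalCohort, n_sd: float = 3.0
) -> tuple[LongitudinalCohort, QCReport]:
    """Mask records deviating more than ``n_sd`` SDs from their time-point mean.

    Mean and SD are those of the time point *before* masking (single pass,
    not iterative); sample SD (ddof=1).  Time points with fewer than two
    records are skipped with a warning.
    """
    W = cohort.weights.astype(float)
    n_masked = 0
    for day in W.columns:
        col = W[day]
        obs = col.dropna()
        if len(obs) < 2:
            warnings.warn(
                f"day {day}: fewer than 2 records, 3-SD rule skipped", stacklevel=2
            )
            continue
        mean, sd = obs.mean(), obs.std(ddof=1)
        if sd == 0:
            continue
        bad = (col - mean).abs() > n_sd * sd
        n_masked += int(bad.sum())
        W.loc[bad, day] = np.nan
    out = LongitudinalCohort(cohort.individuals, W)
    return out, QCReport("outliers_3sd", n_masked=n_masked, stats=descriptive_stats(out))


def enforce_decrease_rule(
    cohort: LongitudinalCohort, max_drop: float = 0.05
) -> tuple[LongitudinalCohort, QCReport]:
    """Mask records that drop by ``max_drop`` (5%) or more from the previous one.

    Scanning each individual's records in time order, a record with
    ``w < (1 - max_drop) * w_ref`` is set missing, where ``w_ref`` is the
    nearest earlier record that itself survived (masked records never serve
    as reference).
    """
    W = cohort.weights.astype(float)
    vals = W.to_numpy()
    n_masked = 0
    for i in range(vals.shape[0]):
        ref = np.nan
        for j in range(vals.shape[1]):
            w = vals[i, j]
            if np.isnan(w):
                continue
            if not np.isnan(ref) and w < (1.0 - max_drop) * ref:
                vals[i, j] = np.nan
                n_masked += 1
            else:
                ref = w
    W.iloc[:, :] = vals
    out = LongitudinalCohort(cohort.individuals, W)
    return out, QCReport("decrease_rule", n_masked=n_masked, stats=descriptive_stats(out))


def drop_high_missing_individuals(
    cohort: LongitudinalCohort, max_missing: int = 2
) -> tuple[LongitudinalCohort, QCReport]:
    """Remove individuals with strictly more than ``max_missing`` missing records."""
    n_missing = cohort.n_missing_per_individual
    keep = n_missing <= max_missing
    out = cohort.subset(cohort.individuals.index[keep])
    return out, QCReport(
        "drop_high_missing",
        n_dropped_individuals=int((~keep).sum()),
        stats=descriptive_stats(out),
    )


class PhenotypeQC(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer running the full three-rule phenotype QC.

    Parameters
    ----------
    n_sd : float, default 3.0
        Outlier threshold in time-point standard deviations.
    max_drop : float, default 0.05
        Largest tolerated fractional decrease between consecutive records.
    max_missing : int, default 2
        Individuals with more missing records than this are removed.

    Attributes
    ----------
    reports_ : list of QCReport
        One report per rule, in application order.
    """

    def __init__(self, n_sd: float = 3.0, max_drop: float = 0.05, max_missing: int = 2):
        self.n_sd = n_sd
        self.max_drop = max_drop
        self.max_missing = max_missing

    def fit(self, cohort: LongitudinalCohort, y=None):
        return self

    def transform(self, cohort: LongitudinalCohort) -> LongitudinalCohort:
        cohort, rep1 = mask_outliers_3sd(cohort, self.n_sd)
        cohort, rep2 = enforce_decrease_rule(cohort, self.max_drop)
        cohort, rep3 = drop_high_missing_individuals(cohort, self.max_missing)
        self.reports_ = [rep1, rep2, rep3]
        return cohort
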