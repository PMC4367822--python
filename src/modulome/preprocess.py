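"""Metabolomics preprocessing: run-day normalization, outlier masking,
missingness filters, and cohort-level sample exclusions.

The fixed pipeline order is normalize -> mask_outliers -> filter_missing
(any reordering must be configured explicitly); every drop is reported with
a machine-readable reason so the sample accounting is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "run_day_normalize",
    "day_median_cv",
    "mask_outliers",
    "filter_missing",
    "exclude_samples",
    "preprocess_metabolites",
]


@dataclass
class PreprocessReport:
    """Accounting of a preprocessing run."""

    day_median_cv: pd.Series = None
    n_outliers_masked: int = 0
    dropped_features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature_id", "reason"])
    )
    dropped_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"])
    )

    def add_features(self, ids, reason: str) -> None:
        if len(ids):
            self.dropped_features = pd.concat(
                [self.dropped_features,
                 pd.DataFrame({"feature_id": list(ids), "reason": reason})],
                ignore_index=True,
            )

    def add_samples(self, ids, reason: str) -> None:
        if len(ids):
            self.dropped_samples = pd.concat(
                [self.dropped_samples,
                 pd.DataFrame({"sample_id": list(ids), "reason": reason})],
                ignore_index=True,
            )


def _day_groups(matrix: OmicsMatrix, day_of: pd.Series) -> pd.Series:
    day_of = pd.Series(day_of)
    missing = matrix.sample_ids.difference(day_of.index)
    if len(missing):
        raise ValueError(f"samples without a run day: {list(missing[:5])}")
    return day_of.loc[matrix.sample_ids]


def run_day_normalize(matrix: OmicsMatrix, day_of: pd.Series) -> OmicsMatrix:
    """Divide each observed cell by the same-day median of its feature.

    Technical run-day effects are removed by dividing each metabolite's
    concentration by the median over samples measured on the same day.  A
    (day, feature) group with no observed value is left missing and the
    feature is flagged in the log.  Idempotent: per-day medians are 1 after
    one application.
    """
    days = _day_groups(matrix, day_of)
    values = matrix.values.copy()
    for _, idx in values.groupby(days.to_numpy()).groups.items():
        block = values.loc[idx]
        med = block.median(axis=0, skipna=True)
        empty = med.isna() & block.notna().any(axis=0)
        if empty.any():  # cannot happen with skipna medians; defensive
            logger.warning("empty (day, feature) groups: %s", list(empty[empty].index))
        all_missing = block.isna().all(axis=0)
        if all_missing.any():
            logger.warning(
                "feature(s) entirely missing on a run day, left unnormalized there: %s",
                list(all_missing[all_missing].index[:5]),
            )
        values.loc[idx] = block / med
    return OmicsMatrix(values, matrix.annotation.copy())


def day_median_cv(matrix: OmicsMatrix, day_of: pd.Series) -> pd.Series:
    """Per-feature coefficient of variation of the per-day medians.

    CV = sample SD (ddof=1) / mean of the day medians, computed on the
    pre-normalization scale.  With a single run day the CV is undefined and
    NaN is returned with a warning.
    """
    days = _day_groups(matrix, day_of)
    medians = matrix.values.groupby(days.to_numpy()).median()
    if medians.shape[0] < 2:
        logger.warning("day_median_cv undefined with a single run day")
        return pd.Series(np.nan, index=matrix.feature_ids, name="day_median_cv")
    cv = medians.std(axis=0, ddof=1) / medians.mean(axis=0)
    cv.name = "day_median_cv"
    return cv


def mask_outliers(matrix: OmicsMatrix, k: float = 4.0):
    """Set cells more than ``k`` SDs from the feature mean on log10 to missing.

    Single pass: means and SDs are computed once per feature over the
    observed cells; features with zero SD mask nothing.  Observed values
    must be strictly positive (log10 undefined otherwise).

    Returns ``(matrix, n_masked)``.
    """
    arr = matrix.values.to_numpy(copy=True)
    bad = (arr <= 0) & ~np.isnan(arr)
    if bad.any():
        i, j = map(int, next(zip(*np.nonzero(bad))))
        raise ValueError(
            "nonpositive observed value at "
            f"({matrix.sample_ids[i]}, {matrix.feature_ids[j]}); log10 undefined"
        )
    with np.errstate(invalid="ignore"):
        logv = np.log10(arr)
    mean = np.nanmean(logv, axis=0)
    sd = np.nanstd(logv, axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        z = np.abs(logv - mean)
        outlier = (sd > 0) & (z > k * sd)
    outlier &= ~np.isnan(arr)
    n_masked = int(outlier.sum())
    arr[outlier] = np.nan
    values = pd.DataFrame(arr, index=matrix.sample_ids, columns=matrix.feature_ids)
    return OmicsMatrix(values, matrix.annotation.copy()), n_masked


def filter_missing(matrix: OmicsMatrix, feature_max: float = 0.5,
                   sample_max: float = 0.2, report: PreprocessReport | None = None):
    """Drop features then samples that exceed the missingness thresholds.

    Features with missing fraction > ``feature_max`` are dropped first;
    sample missing fractions are then recomputed on the surviving features
    and samples above ``sample_max`` are dropped.  Both lists are recorded
    in the report.
    """
    for name, frac in (("feature_max", feature_max), ("sample_max", sample_max)):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    report = report if report is not None else PreprocessReport()
    frac_feat = matrix.values.isna().mean(axis=0)
    drop_feat = frac_feat.index[frac_feat > feature_max]
    values = matrix.values.drop(columns=drop_feat)
    if values.shape[1] == 0:
        raise ValueError("all features dropped by missingness filter")
    frac_samp = values.isna().mean(axis=1)
    drop_samp = frac_samp.index[frac_samp > sample_max]
    values = values.drop(index=drop_samp)
    if values.shape[0] == 0:
        raise ValueError("all samples dropped by missingness filter")
    report.add_features(drop_feat, f"missing_fraction>{feature_max}")
    report.add_samples(drop_samp, f"missing_fraction>{sample_max}")
    out = OmicsMatrix(values, matrix.annotation.loc[values.columns].copy())
    return out, report


def exclude_samples(pheno: pd.DataFrame, min_fasting_h: float = 8.0,
                    dbw_sd_limit: float = 5.0):
    """Cohort exclusions: short fasting, then extreme weight change.

    Samples fasting fewer than ``min_fasting_h`` hours are dropped first;
    the weight-change mean and SD are then computed on the remaining samples
    and values outside mean +/- ``dbw_sd_limit`` SDs are dropped.

    Returns ``(pheno, dropped)`` where ``dropped`` is a frame of
    (sample_id, reason).
    """
    dropped = []
    fast = pheno.index[pheno["fasting_h"] < min_fasting_h]
    dropped += [(s, f"fasting<{min_fasting_h}h") for s in fast]
    kept = pheno.drop(index=fast)
    if kept.shape[0] == 0:
        raise ValueError("all samples excluded by fasting criterion")
    dbw = kept["dbw"]
    mean, sd = dbw.mean(), dbw.std(ddof=1)
    if sd > 0:
        out = kept.index[(dbw - mean).abs() > dbw_sd_limit * sd]
        dropped += [(s, f"dbw outside mean±{dbw_sd_limit}SD") for s in out]
        kept = kept.drop(index=out)
    if kept.shape[0] == 0:
        raise ValueError("all samples excluded")
    return kept, pd.DataFrame(dropped, columns=["sample_id", "reason"])


def preprocess_metabolites(matrix: OmicsMatrix, pheno: pd.DataFrame,
                           outlier_k: float = 4.0, feature_max: float = 0.5,
                           sample_max: float = 0.2, log10_output: bool = True):
    """Full metabolite preprocessing: normalize -> mask outliers -> filter.

    Returns ``(matrix, report)``.  The day-median CVs are computed before
    normalization.  When ``log10_output`` is set (the default) the surviving
    values are returned on the log10 scale, the scale on which all
    downstream modelling operates.
    """
    day_of = pheno.loc[matrix.sample_ids, "run_day"]
    report = PreprocessReport()
    if day_of.nunique() >= 2:
        report.day_median_cv = day_median_cv(matrix, day_of)
    matrix = run_day_normalize(matrix, day_of)
    matrix, n_masked = mask_outliers(matrix, k=outlier_k)
    report.n_outliers_masked = n_masked
    matrix, report = filter_missing(matrix, feature_max, sample_max, report)
    if log10_output:
        matrix = OmicsMatrix(np.log10(matrix.values), matrix.annotation.copy())
    logger.info(
        "preprocess: %d features and %d samples kept; %d outlier cells masked",
        matrix.n_features, matrix.n_samples, n_masked,
    )
    return matrix, report
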