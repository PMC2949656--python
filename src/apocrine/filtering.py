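"""Probe-set filtering for unsupervised analysis.

Three sequential criteria select informative probe sets from a log2
expression matrix:

1. *Intensity*: control probes and probes whose 90th-percentile log2
   intensity falls below 10 are removed.
2. *Variance test*: each probe's unbiased sample variance Var(P) is
   compared to the median variance of all probes (Varmed) with the
   statistic (n-1) * Var(P) / Varmed, referred to the chi-square
   distribution with n-1 degrees of freedom (upper tail by default).
3. *Robust coefficient of variation* (rCV): the CV after discarding one
   minimum and one maximum observation; kept probes must lie strictly
   between the 95th percentile of all rCVs and an absolute cap of 10.

Percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, ExpressionMatrix, ProbeAnnotation

__all__ = [
    "FilterReport",
    "intensity_filter",
    "variance_test",
    "robust_cv",
    "select_clustering_probes",
]


@dataclass
class FilterReport:
    """Per-probe filter statistics plus the monotone count chain."""

    n_input: int
    n_after_intensity: int
    n_after_variance: int
    n_after_rcv: int
    varmed: float
    rcv_threshold_low: float  # 95th percentile of rCV across tested probes
    rcv_threshold_high: float
    table: pd.DataFrame  # index probe_id: variance, statistic, p_value, rcv, kept, reason

    def __post_init__(self) -> None:
        chain = (self.n_input, self.n_after_intensity, self.n_after_variance, self.n_after_rcv)
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise DataError(f"filter counts must be non-increasing, got {chain}")

    @property
    def kept_probes(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def intensity_filter(
    X: ExpressionMatrix,
    ann: ProbeAnnotation,
    percentile: float = 90.0,
    min_log2: float = 10.0,
) -> list[str]:
    """Probes that are non-control and reach ``min_log2`` at the given
    per-probe intensity percentile."""
    if X.n_probes == 0 or X.n_samples == 0:
        raise DataError("cannot intensity-filter an empty expression matrix")
    q = np.nanpercentile(X.values, percentile, axis=1)
    control = np.array(
        [ann.table.at[p, "is_control"] if p in ann.table.index else False for p in X.probe_ids]
    )
    keep = (~control) & (q >= min_log2)
    return [p for p, k in zip(X.probe_ids, keep) if k]


def variance_test(
    values: np.ndarray, varmed: float, two_sided: bool = False
) -> tuple[float, float]:
    """Chi-square test of a probe's variance against the cohort median.

    statistic = (n-1) * Var(values) / varmed, with Var the unbiased sample
    variance; under Var = varmed the statistic is chi-square with n-1 df.
    Returns (statistic, p). One-sided (upper tail) by default, selecting
    high-variability probes.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise DataError("variance test needs at least 2 observations")
    if varmed <= 0:
        raise DataError(f"varmed must be positive, got {varmed}")
    statistic = (n - 1) * values.var(ddof=1) / varmed
    upper = stats.chi2.sf(statistic, df=n - 1)
    if two_sided:
        lower = stats.chi2.cdf(statistic, df=n - 1)
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        p = upper
    return float(statistic), float(p)


def robust_cv(values: np.ndarray) -> float:
    """Coefficient of variation after trimming one minimum and one maximum.

    Exactly one instance of the smallest and one of the largest value are
    removed, even under ties. Returns NaN (probe flagged undefined) when
    the trimmed mean is zero.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise DataError(f"robust CV needs >= 4 observations, got {values.size}")
    trimmed = np.sort(values)[1:-1]
    mean = trimmed.mean()
    if mean == 0:
        return float("nan")
    return float(trimmed.std(ddof=1) / mean)


def _rcv_rows(values: np.ndarray) -> np.ndarray:
    """Vectorized row-wise rCV (one min and one max trimmed per row)."""
    srt = np.sort(values, axis=1)[:, 1:-1]
    mean = srt.mean(axis=1)
    sd = srt.std(ddof=1, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rcv = np.where(mean == 0, np.nan, sd / mean)
    return rcv


def select_clustering_probes(
    X: ExpressionMatrix,
    ann: ProbeAnnotation,
    p_thresh: float = 0.01,
    rcv_cap: float = 10.0,
    rcv_percentile: float = 95.0,
    intensity_percentile: float = 90.0,
    min_log2: float = 10.0,
    apply_intensity: bool = True,
    two_sided: bool = False,
) -> tuple[list[str], FilterReport]:
    """Run the full probe-selection chain and report every intermediate.

    Varmed and the rCV percentile threshold are computed over all probes
    surviving the intensity step, before any selection.
    """
    n_input = X.n_probes
    if apply_intensity:
        stage1 = intensity_filter(X, ann, percentile=intensity_percentile, min_log2=min_log2)
    else:
        stage1 = list(X.probe_ids)
    Xs = X.subset_probes(stage1)
    n = Xs.n_samples
    if n < 4:
        raise DataError("probe selection needs >= 4 samples (rCV trimming)")

    variances = Xs.values.var(ddof=1, axis=1)
    varmed = float(np.median(variances))
    if varmed <= 0:
        raise DataError("median probe variance is zero; matrix degenerate")
    statistic = (n - 1) * variances / varmed
    upper = stats.chi2.sf(statistic, df=n - 1)
    if two_sided:
        lower = stats.chi2.cdf(statistic, df=n - 1)
        p_values = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
    else:
        p_values = upper

    rcv = _rcv_rows(Xs.values)
    finite = rcv[np.isfinite(rcv)]
    rcv_low = float(np.percentile(finite, rcv_percentile))
    pass_var = p_values < p_thresh
    pass_rcv = np.isfinite(rcv) & (rcv > rcv_low) & (rcv < rcv_cap)
    kept = pass_var & pass_rcv

    reason = np.where(
        kept, "", np.where(~pass_var, np.where(~pass_rcv, "variance+rcv", "variance"), "rcv")
    )
    table = pd.DataFrame(
        {
            "variance": variances,
            "statistic": statistic,
            "p_value": p_values,
            "rcv": rcv,
            "kept": kept,
            "reason": reason,
        },
        index=pd.Index(stage1, name="probe_id"),
    )
    report = FilterReport(
        n_input=n_input,
        n_after_intensity=len(stage1),
        n_after_variance=int(pass_var.sum()),
        n_after_rcv=int(kept.sum()),
        varmed=varmed,
        rcv_threshold_low=rcv_low,
        rcv_threshold_high=rcv_cap,
        table=table,
    )
    return report.kept_probes, report
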