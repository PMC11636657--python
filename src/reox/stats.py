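"""Gas-challenge contrasts and test-retest reproducibility statistics.

Implements the study's statistical surface: per-subject percent changes
(cohort summaries are the mean and SD of per-subject values), paired
baseline-vs-gas contrasts with a day-by-time interaction test,
variance-component intraclass correlation with the Koo & Li reliability
bands, within-subject coefficient of variation for duplicate
measurements, and Bland-Altman limits of agreement. Tests are two-sided
throughout, alpha = 0.05; Shapiro-Wilk normality is reported as a
diagnostic only and never switches the analysis branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import StatisticsError
from .model import IccModel

__all__ = [
    "percent_change",
    "summarize_percent_changes",
    "gas_contrast",
    "day_interaction",
    "icc",
    "koo_li_band",
    "cov_within_subject",
    "bland_altman",
    "shapiro_diagnostic",
    "reproducibility_report",
    "ContrastResult",
    "BlandAltman",
    "ReproducibilityReport",
]


def percent_change(baseline, follow):
    """Per-subject percent change 100 * (follow - baseline) / baseline.

    Accepts scalars or aligned arrays; a zero baseline is undefined."""
    baseline = np.asarray(baseline, dtype=float)
    follow = np.asarray(follow, dtype=float)
    if np.any(baseline == 0.0):
        raise StatisticsError("percent change undefined for zero baseline")
    out = 100.0 * (follow - baseline) / baseline
    return float(out) if out.ndim == 0 else out


def summarize_percent_changes(changes: Sequence[float]) -> tuple[float, float]:
    """Cohort convention: mean and SD (ddof=1) of per-subject changes."""
    arr = np.asarray(changes, dtype=float)
    if arr.size < 2:
        raise StatisticsError("need >= 2 per-subject changes to summarize")
    return float(arr.mean()), float(arr.std(ddof=1))


@dataclass(frozen=True)
class ContrastResult:
    """Paired baseline-vs-gas contrast for one variable on one study day."""

    mean_baseline: float
    mean_gas: float
    mean_pct_change: float
    sd_pct_change: float
    p_value: float
    n: int


def _paired_p(differences: np.ndarray) -> float:
    """Two-sided paired t-test p-value with degenerate-spread guards:
    identically-zero differences give p = 1, a constant non-zero shift
    with no spread gives p = 0."""
    d = np.asarray(differences, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 1.0 if np.all(d == 0.0) else 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(2.0 * sps.t.sf(abs(t), df=d.size - 1))


def gas_contrast(baseline_values, gas_values) -> ContrastResult:
    """Within-subject contrast between (same-day) baseline and gas
    breathing. Inputs are aligned per-subject vectors; the test is a
    two-sided paired t-test on the within-subject differences, and the
    percent-change summary is the mean +/- SD of per-subject changes."""
    b = np.asarray(baseline_values, dtype=float)
    g = np.asarray(gas_values, dtype=float)
    if b.shape != g.shape:
        raise StatisticsError("baseline and gas vectors must be paired (same length)")
    if b.size < 2:
        raise StatisticsError("need >= 2 paired subjects for a contrast")
    changes = percent_change(b, g)
    mean_pc, sd_pc = summarize_percent_changes(changes)
    return ContrastResult(
        mean_baseline=float(b.mean()),
        mean_gas=float(g.mean()),
        mean_pct_change=mean_pc,
        sd_pct_change=sd_pc,
        p_value=_paired_p(g - b),
        n=int(b.size),
    )


def day_interaction(diff_day1, diff_day2) -> tuple[float, float]:
    """Day-by-time interaction: paired two-sided test on the
    difference-of-differences across the two study days for subjects
    measured on both. Returns (mean difference-of-differences, p)."""
    d1 = np.asarray(diff_day1, dtype=float)
    d2 = np.asarray(diff_day2, dtype=float)
    if d1.shape != d2.shape:
        raise StatisticsError("day differences must be paired per subject")
    if d1.size < 2:
        raise StatisticsError("need >= 2 subjects with both study days")
    dd = d1 - d2
    return float(dd.mean()), _paired_p(dd)


def _pairs_array(pairs, min_subjects: int) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise StatisticsError("expected an (n, 2) array of duplicate measurements")
    if arr.shape[0] < min_subjects:
        raise StatisticsError(f"need >= {min_subjects} subjects, got {arr.shape[0]}")
    if np.any(~np.isfinite(arr)):
        raise StatisticsError("non-finite measurement in pairs")
    return arr


def icc(pairs, model: IccModel | str = IccModel.TWO_WAY_MIXED_ABSOLUTE) -> float:
    """Intraclass correlation for a duplicate-measurement design.

    ``pairs`` is (n_subjects, 2). The default is the single-measurement,
    absolute-agreement form of the two-way mixed-effects model
    (the standard test-retest choice):

        ICC = (MSB - MSE) / (MSB + MSE + 2 (MSC - MSE) / n)

    with MSB/MSC/MSE the between-subject, between-session and residual
    mean squares. ``one_way_random`` gives the one-way random-effects
    form (MSB - MSW) / (MSB + MSW), which doubles as a brute-force
    cross-check."""
    model = IccModel(model)
    x = _pairs_array(pairs, min_subjects=3)
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise StatisticsError("ICC undefined: zero total variance")
    subj_means = x.mean(axis=1)
    sess_means = x.mean(axis=0)
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - subj_means[:, None]) ** 2) / (n * (k - 1))
    if model is IccModel.ONE_WAY_RANDOM:
        return float((msb - msw) / (msb + (k - 1) * msw))
    ssc = n * np.sum((sess_means - grand) ** 2)
    sse = np.sum((x - subj_means[:, None] - sess_means[None, :] + grand) ** 2)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msb + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        raise StatisticsError("ICC undefined: degenerate mean squares")
    return float((msb - mse) / denom)


def koo_li_band(icc_value: float) -> str:
    """Reliability interpretation bands: below 0.5 poor, 0.5 to 0.75
    moderate, 0.75 to 0.90 good (inclusive upper bound), above 0.90
    excellent."""
    if not np.isfinite(icc_value):
        raise StatisticsError("ICC value must be finite")
    if icc_value < 0.5:
        return "poor"
    if icc_value < 0.75:
        return "moderate"
    if icc_value <= 0.90:
        return "good"
    return "excellent"


def cov_within_subject(pairs) -> tuple[float, float, np.ndarray]:
    """Within-subject coefficient of variation for duplicate measurements.

    Per subject, CoV = SD(pair) / mean(pair) * 100 with
    SD(pair) = |x1 - x2| / sqrt(2). Returns (mean CoV, SD of CoVs across
    subjects, per-subject CoVs)."""
    x = _pairs_array(pairs, min_subjects=2)
    means = x.mean(axis=1)
    if np.any(means <= 0):
        raise StatisticsError("pair means must be > 0 for a coefficient of variation")
    covs = np.abs(x[:, 0] - x[:, 1]) / np.sqrt(2.0) / means * 100.0
    return float(covs.mean()), float(covs.std(ddof=1)), covs


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray  # x-axis: average of the two measurements
    differences: np.ndarray  # y-axis: first minus second


def bland_altman(pairs) -> BlandAltman:
    """Bland-Altman agreement statistics: bias = mean difference, 95%
    limits of agreement = bias +/- 1.96 SD of the differences, plus the
    (average, difference) plotting coordinates."""
    x = _pairs_array(pairs, min_subjects=2)
    diffs = x[:, 0] - x[:, 1]
    means = x.mean(axis=1)
    bias = float(diffs.mean())
    spread = 1.96 * float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - spread,
        loa_high=bias + spread,
        means=means,
        differences=diffs,
    )


def shapiro_diagnostic(values) -> tuple[float, float]:
    """Shapiro-Wilk normality check, reported as a diagnostic (W, p)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise StatisticsError("Shapiro-Wilk needs >= 3 values")
    w, p = sps.shapiro(arr)
    return float(w), float(p)


@dataclass(frozen=True)
class ReproducibilityReport:
    """ICC, within-subject CoV and Bland-Altman limits for one set of
    duplicate measurements."""

    icc: float
    icc_model: IccModel
    icc_band: str
    cov_mean: float
    cov_sd: float
    bland_altman_bias: float
    bland_altman_loa_low: float
    bland_altman_loa_high: float
    n_pairs: int


def reproducibility_report(
    pairs, icc_model: IccModel | str = IccModel.TWO_WAY_MIXED_ABSOLUTE
) -> ReproducibilityReport:
    """Bundle the three reproducibility statistics for one pair table."""
    x = _pairs_array(pairs, min_subjects=3)
    icc_value = icc(x, icc_model)
    cov_mean, cov_sd, _ = cov_within_subject(x)
    ba = bland_altman(x)
    return ReproducibilityReport(
        icc=icc_value,
        icc_model=IccModel(icc_model),
        icc_band=koo_li_band(icc_value),
        cov_mean=cov_mean,
        cov_sd=cov_sd,
        bland_altman_bias=ba.bias,
        bland_altman_loa_low=ba.loa_low,
        bland_altman_loa_high=ba.loa_high,
        n_pairs=int(x.shape[0]),
    )
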