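"""Statistics for replicate assay readouts (LDH release, ELISA, qRT-PCR).

Covers the study-style confirmation analyses: fold change as the ratio of
condition means, the two-sided single-outlier Grubbs screen applied before
group comparison, Welch's unequal-variance t-test, 2^−ΔΔCt relative
quantification of qPCR cycle thresholds, and the Pearson correlation between
platform-level abundance measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expression_io import AssaySeries
from .marker_selection import signed_fold_change


@dataclass(frozen=True)
class GrubbsResult:
    flagged_index: int | None
    G: float
    critical: float
    alpha: float


@dataclass(frozen=True)
class TwoSampleResult:
    fold_change: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def _values(series) -> np.ndarray:
    if isinstance(series, AssaySeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def assay_fold_change(treated, control) -> float:
    """mean(treated) / mean(control)."""
    t, c = _values(treated), _values(control)
    if t.size == 0 or c.size == 0:
        raise ValueError("both series must be non-empty")
    if c.mean() <= 0:
        raise ValueError(f"control mean must be positive, got {c.mean()}")
    return float(t.mean() / c.mean())


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided single-outlier Grubbs critical value at level ``alpha``.

    G_crit = ((n−1)/√n) · sqrt(t² / (n−2+t²)) with t the upper α/(2n)
    quantile of the t-distribution on n−2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs' test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    Flags at most the one most deviant point per call (G = max|x − mean|/sd
    compared against the t-based critical value); iterate after removal to
    screen for further outliers.  Zero-spread data yields G = 0, no outlier.
    """
    x = _values(values)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs' test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return GrubbsResult(None, 0.0, grubbs_critical(n, alpha), alpha)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    G = float(dev[idx] / sd)
    crit = grubbs_critical(n, alpha)
    return GrubbsResult(idx if G > crit else None, G, crit, alpha)


def remove_outliers(values, alpha: float = 0.05, max_iter: int | None = None
                    ) -> tuple[np.ndarray, list[int]]:
    """Iterated Grubbs screen; returns cleaned values and flagged original indices."""
    x = _values(values)
    original = np.arange(x.size)
    flagged: list[int] = []
    while x.size >= 3 and (max_iter is None or len(flagged) < max_iter):
        res = grubbs_test(x, alpha)
        if res.flagged_index is None:
            break
        flagged.append(int(original[res.flagged_index]))
        keep = np.arange(x.size) != res.flagged_index
        x, original = x[keep], original[keep]
    return x, flagged


def welch_t_test(treated, control) -> TwoSampleResult:
    """Welch's unequal-variance t-test (two-sided) plus the mean-ratio FC.

    Degrees of freedom follow Welch–Satterthwaite.  When both groups have
    zero variance and equal means, t = 0 and p = 1 by convention.
    """
    t_vals, c_vals = _values(treated), _values(control)
    if t_vals.size < 2 or c_vals.size < 2:
        raise ValueError("need >= 2 replicates per group")
    v1, v2 = t_vals.var(ddof=1), c_vals.var(ddof=1)
    n1, n2 = t_vals.size, c_vals.size
    if v1 == 0 and v2 == 0:
        if t_vals.mean() == c_vals.mean():
            return TwoSampleResult(assay_fold_change(t_vals, c_vals), 0.0,
                                   float(n1 + n2 - 2), 1.0)
        raise ValueError("zero variance in both groups with unequal means")
    se2 = v1 / n1 + v2 / n2
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    res = stats.ttest_ind(t_vals, c_vals, equal_var=False)
    return TwoSampleResult(
        fold_change=assay_fold_change(t_vals, c_vals),
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(df),
        p_value=float(res.pvalue),
    )


def relative_quantification(
    ct_target_treated,
    ct_target_control,
    ct_ref_treated,
    ct_ref_control,
) -> float:
    """2^−ΔΔCt relative abundance as a signed fold change.

    ΔΔCt = (mean Ct_target − mean Ct_ref) in treated minus the same
    difference in control; the resulting ratio is reported with the signed
    convention (ratio when >= 1, negative reciprocal otherwise).  The
    reference (normalizer) assay is a required input.
    """
    arrays = [_values(a) for a in (ct_target_treated, ct_target_control,
                                   ct_ref_treated, ct_ref_control)]
    if any(a.size == 0 or not np.all(np.isfinite(a)) for a in arrays):
        raise ValueError("Ct inputs must be non-empty and finite")
    tt, tc, rt, rc = arrays
    ddct = (tt.mean() - rt.mean()) - (tc.mean() - rc.mean())
    ratio = 2.0 ** (-ddct)
    return signed_fold_change(ratio, 1.0)


def platform_correlation(series_a, series_b) -> float:
    """Pearson correlation of paired per-item abundances.

    Returns NaN (undefined) when either series has zero variance.
    """
    a, b = _values(series_a), _values(series_b)
    if a.size != b.size:
        raise ValueError("paired series must have equal length")
    if a.size < 3:
        raise ValueError("need >= 3 paired items")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)
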