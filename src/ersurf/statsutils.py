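"""Distribution summaries, two-sample KS tests and the 2^−ΔΔCt formula."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats


@dataclass
class QuartileSummary:
    """Box/violin-plot summary: quartiles, 1.5·IQR whiskers, outliers."""

    n: int
    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.array([]))


def quartile_summary(values) -> QuartileSummary:
    """Summarize a sample by quartiles and Tukey whiskers.

    Quartiles use linear interpolation between order statistics (the
    common "type 7" convention: position 1 + (n−1)p); whiskers are
    Q1 − 1.5·IQR and Q3 + 1.5·IQR, and every point outside them is
    reported as a potential outlier.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # numpy default = type 7
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return QuartileSummary(
        n=x.size,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(lo),
        whisker_high=float(hi),
        outliers=np.sort(x[(x < lo) | (x > hi)]),
    )


@dataclass
class KsResult:
    D: float
    p: float
    n1: int
    n2: int


def ks_two_sample(x, y, method: str = "asymp") -> KsResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the exact supremum of |ECDF_x − ECDF_y| over the pooled sample
    points. The two-sided p-value uses the asymptotic Kolmogorov
    distribution with effective size n1·n2/(n1+n2), which is adequate for
    the group sizes (hundreds) this package compares; ``method="exact"``
    switches to the exact small-sample distribution and is only allowed
    for n1·n2 <= 10_000.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n1
    cdf_y = np.searchsorted(y, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    if method == "asymp":
        ne = n1 * n2 / (n1 + n2)
        p = float(special.kolmogorov(math.sqrt(ne) * d))
    elif method == "exact":
        if n1 * n2 > 10_000:
            raise ValueError("exact mode limited to n1*n2 <= 10000")
        p = float(stats.ks_2samp(x, y, method="exact").pvalue)
    else:
        raise ValueError("method must be 'asymp' or 'exact'")
    return KsResult(D=d, p=min(p, 1.0), n1=n1, n2=n2)


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target,treated − Ct_ref,treated) −
           (Ct_target,control − Ct_ref,control); the returned fold change
    is 2^−ΔΔCt (1 = no change, <1 = lower expression in treated).
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct_val = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct_val))


def two_sample_t(x, y, equal_var: bool = True):
    """Plain two-sample Student t-test (utility; returns (t, p))."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
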