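"""Method-agreement statistics for paired diameter measurements.

The validation toolkit for comparing two measurement methods (e.g. manual
caliper readings at discrete stations vs the continuous profile at the same
stations): ordinary least-squares correlation, Bland-Altman bias and limits
of agreement, Passing-Bablok distribution-free regression, and an F test on
the variances of visit-to-visit change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasures",
    "AgreementReport",
    "least_squares",
    "bland_altman",
    "passing_bablok",
    "f_concordance",
    "agreement_report",
    "read_paired_csv",
    "bland_altman_plot",
    "passing_bablok_plot",
    "regression_plot",
]


@dataclass
class PairedMeasures:
    """Same quantity measured twice (method A and method B), in mm."""

    method_a: np.ndarray
    method_b: np.ndarray
    labels: Optional[Sequence] = None

    def __post_init__(self):
        self.method_a = np.asarray(self.method_a, dtype=float).ravel()
        self.method_b = np.asarray(self.method_b, dtype=float).ravel()
        if len(self.method_a) != len(self.method_b):
            raise ValueError("methods must have equal length")
        if len(self.method_a) < 3:
            raise ValueError("need at least 3 pairs")
        if not (
            np.isfinite(self.method_a).all() and np.isfinite(self.method_b).all()
        ):
            raise ValueError("measurements must be finite")

    def __len__(self):
        return len(self.method_a)


@dataclass
class AgreementReport:
    slope: float
    intercept: float
    r_value: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    reproducibility_coefficient: float
    pb_slope: float
    pb_slope_ci: tuple
    pb_intercept: float
    pb_intercept_ci: tuple

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_value": self.r_value,
            "p_value": self.p_value,
            "bias_mm": self.bias,
            "loa_low_mm": self.loa_low,
            "loa_high_mm": self.loa_high,
            "reproducibility_coefficient_mm": self.reproducibility_coefficient,
            "pb_slope": self.pb_slope,
            "pb_slope_ci": list(self.pb_slope_ci),
            "pb_intercept": self.pb_intercept,
            "pb_intercept_ci": list(self.pb_intercept_ci),
        }


def least_squares(pm: PairedMeasures):
    """OLS regression of method B on method A.

    Returns (slope, intercept, r, p) with r the Pearson correlation and p
    from the t distribution with n - 2 degrees of freedom.
    """
    a, b = pm.method_a, pm.method_b
    if np.ptp(a) == 0:
        raise ValueError("method A is constant; regression undefined")
    res = stats.linregress(a, b)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
    )


def bland_altman(pm: PairedMeasures):
    """Bland-Altman agreement: bias and +/- 1.96 SD limits of agreement.

    Differences are method A minus method B; the reproducibility
    coefficient is 1.96 x SD of the differences (sample SD, n - 1).
    Returns (bias, loa_low, loa_high, reproducibility_coefficient).
    """
    d = pm.method_a - pm.method_b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    coeff = 1.96 * sd
    return bias, bias - coeff, bias + coeff, coeff


def passing_bablok(pm: PairedMeasures, alpha: float = 0.05):
    """Passing-Bablok distribution-free regression of B on A.

    The slope is the shifted median of all pairwise slopes S_ij (i < j):
    slopes equal to -1 are discarded and the median index is offset by K,
    the number of slopes below -1, per the original rank procedure; the
    intercept is median(b - slope * a).  Confidence bounds use the
    rank-based normal approximation.

    Returns (slope, intercept, (slope_lo, slope_hi), (int_lo, int_hi)).
    """
    a, b = pm.method_a, pm.method_b
    if np.ptp(a) == 0:
        raise ValueError("method A is constant; slope undefined")
    n = len(a)
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    iu = np.triu_indices(n, k=1)
    da, db = da[iu], db[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = db / da
    # da == 0 with db != 0 contributes +/- inf (ranked at the extremes);
    # da == db == 0 (exact ties) carries no information
    keep = ~((da == 0) & (db == 0))
    slopes = slopes[keep]
    slopes = slopes[slopes != -1.0]
    slopes = np.sort(slopes)
    n_slopes = len(slopes)
    if n_slopes == 0:
        raise ValueError("no valid pairwise slopes")
    k_offset = int(np.sum(slopes < -1.0))

    def shifted_median(sorted_s, offset):
        m = len(sorted_s)
        if m % 2 == 1:
            return float(sorted_s[(m + 1) // 2 + offset - 1])
        lo = sorted_s[m // 2 + offset - 1]
        hi = sorted_s[m // 2 + offset]
        return float(0.5 * (lo + hi))

    slope = shifted_median(slopes, k_offset)

    z = stats.norm.ppf(1 - alpha / 2)
    w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((n_slopes - w) / 2.0))
    m2 = n_slopes - m1 + 1
    lo_i = np.clip(m1 + k_offset - 1, 0, n_slopes - 1)
    hi_i = np.clip(m2 + k_offset - 1, 0, n_slopes - 1)
    slope_ci = (float(slopes[lo_i]), float(slopes[hi_i]))

    intercept = float(np.median(b - slope * a))
    intercept_ci = (
        float(np.median(b - slope_ci[1] * a)),
        float(np.median(b - slope_ci[0] * a)),
    )
    return slope, intercept, slope_ci, intercept_ci


def f_concordance(changes_a, changes_b, alpha: float = 0.05):
    """Variance-equality F test between two sets of change values.

    The larger sample variance goes in the numerator and F is compared with
    an upper-tail critical value; concordance holds when F < F_crit.
    Because the larger variance is always placed on top, the critical value
    is taken at the 1 - alpha/2 quantile so the overall false-alarm rate of
    the procedure is ``alpha`` (a plain 1 - alpha quantile would double it).
    Returns (f_value, f_crit, concordant).
    """
    a = np.asarray(changes_a, dtype=float).ravel()
    b = np.asarray(changes_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 change values per method")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0, float(stats.f.ppf(1 - alpha / 2, len(a) - 1, len(b) - 1)), True
    if va >= vb:
        num, den, dfn, dfd = va, vb, len(a) - 1, len(b) - 1
    else:
        num, den, dfn, dfd = vb, va, len(b) - 1, len(a) - 1
    f_value = float(num / den) if den > 0 else np.inf
    f_crit = float(stats.f.ppf(1 - alpha / 2, dfn, dfd))
    return f_value, f_crit, bool(f_value < f_crit)


def agreement_report(pm: PairedMeasures) -> AgreementReport:
    """All agreement statistics for one set of paired measurements."""
    slope, intercept, r, p = least_squares(pm)
    bias, lo, hi, coeff = bland_altman(pm)
    pb_slope, pb_int, pb_slope_ci, pb_int_ci = passing_bablok(pm)
    return AgreementReport(
        slope=slope,
        intercept=intercept,
        r_value=r,
        p_value=p,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        reproducibility_coefficient=coeff,
        pb_slope=pb_slope,
        pb_slope_ci=pb_slope_ci,
        pb_intercept=pb_int,
        pb_intercept_ci=pb_int_ci,
    )


def read_paired_csv(path) -> PairedMeasures:
    """Load paired measurements from CSV columns method_a_mm, method_b_mm
    (optional station/visit columns become labels)."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("method_a_mm", "method_b_mm"):
        if col not in df.columns:
            raise ValueError(f"CSV must contain column {col!r}")
    labels = None
    if "station" in df.columns:
        labels = df["station"].tolist()
    return PairedMeasures(
        df["method_a_mm"].to_numpy(), df["method_b_mm"].to_numpy(), labels
    )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def regression_plot(pm: PairedMeasures, ax=None):
    """Scatter of B vs A with OLS line and identity reference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    slope, intercept, r, _ = least_squares(pm)
    ax.plot(pm.method_a, pm.method_b, "d", ms=4)
    xs = np.linspace(pm.method_a.min(), pm.method_a.max(), 2)
    ax.plot(xs, slope * xs + intercept, "-", label=f"OLS (R = {r:.2f})")
    ax.plot(xs, xs, "--", color="green", label="identity")
    ax.set_xlabel("method A (mm)")
    ax.set_ylabel("method B (mm)")
    ax.legend()
    return ax


def bland_altman_plot(pm: PairedMeasures, ax=None):
    """Difference vs mean with bias and +/- 1.96 SD limit lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bias, lo, hi, _ = bland_altman(pm)
    mean = (pm.method_a + pm.method_b) / 2
    diff = pm.method_a - pm.method_b
    ax.plot(mean, diff, "d", ms=4)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, ls=style, color="0.4")
    ax.set_xlabel("mean of methods (mm)")
    ax.set_ylabel("difference A - B (mm)")
    return ax


def passing_bablok_plot(pm: PairedMeasures, ax=None):
    """Scatter with the Passing-Bablok line and its confidence bounds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    slope, intercept, slope_ci, int_ci = passing_bablok(pm)
    ax.plot(pm.method_a, pm.method_b, "d", ms=4)
    xs = np.linspace(pm.method_a.min(), pm.method_a.max(), 2)
    ax.plot(xs, slope * xs + intercept, "-", label=f"PB {slope:.2f}x + {intercept:.2f}")
    ax.plot(xs, slope_ci[0] * xs + int_ci[1], "--", color="0.5")
    ax.plot(xs, slope_ci[1] * xs + int_ci[0], "--", color="0.5")
    ax.set_xlabel("method A (mm)")
    ax.set_ylabel("method B (mm)")
    ax.legend()
    return ax
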