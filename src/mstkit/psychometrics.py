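"""Analysis layer for comparing MST task variants.

Covers the statistics used when validating a task variant against the
full-length baseline:

* outlier-robust linear regression between paired scores in the style
  of the ROUT procedure (robust fit + false-discovery-rate outlier
  identification at rate Q), with a final ordinary Pearson r on the
  retained points;
* Fisher r-to-z comparison of two independent correlations;
* sample-size computation for detecting a correlation;
* Cohen's d (independent-groups pooled-SD and paired variants);
* the extra-sum-of-squares F-test asking whether two groups' score
  relationships need separate regression lines or share a common one;
* the linear conversion between baseline-MST and oMST scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedScores",
    "RobustFitResult",
    "robust_fit_with_outliers",
    "fisher_compare",
    "sample_size_for_r",
    "cohens_d",
    "CommonVsSeparateResult",
    "common_vs_separate_fit",
    "convert_scores",
    "DEFAULT_CONVERSION_SLOPE",
    "DEFAULT_CONVERSION_INTERCEPT",
]

#: Default linear map from baseline-MST LDI to oMST LDI
#: (``omst = intercept + slope * baseline``), the pooled two-cohort fit.
DEFAULT_CONVERSION_SLOPE = 0.65
DEFAULT_CONVERSION_INTERCEPT = 0.33


@dataclass
class PairedScores:
    """Per-participant (baseline, variant) score pairs."""

    baseline: np.ndarray
    variant: np.ndarray
    baseline_label: str = "baseline"
    variant_label: str = "variant"

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.variant = np.asarray(self.variant, dtype=float)
        if self.baseline.shape != self.variant.shape or self.baseline.ndim != 1:
            raise ValueError("baseline and variant must be 1-D and same length")
        if not (np.isfinite(self.baseline).all() and np.isfinite(self.variant).all()):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return len(self.baseline)


@dataclass
class RobustFitResult:
    """Result of a robust fit with FDR outlier identification."""

    slope: float
    intercept: float
    residual_scale: float  # robust SD of residuals (RSDR)
    outlier_flags: np.ndarray  # bool per point
    r_clean: float  # Pearson r on retained points
    n_removed: int
    n: int

    @property
    def n_clean(self) -> int:
        return self.n - self.n_removed


def _rsdr(residuals: np.ndarray, n_params: int = 2) -> float:
    """Robust standard deviation of residuals.

    The 68.27th percentile of the absolute residuals estimates sigma for
    a normal error distribution; the n/(n - K) factor corrects the
    downward bias from fitting K parameters.
    """
    n = len(residuals)
    p68 = float(np.percentile(np.abs(residuals), 68.27))
    return p68 * n / max(n - n_params, 1)


def _lorentzian_irls(
    x: np.ndarray, y: np.ndarray, n_iter: int = 60, tol: float = 1e-10
) -> tuple[float, float, float]:
    """Robust line fit by iteratively reweighted least squares with
    Lorentzian weights ``w = 1 / (1 + (res / RSDR)^2)``.

    The Lorentzian merit function gives distant points vanishing
    influence, so the fitted line tracks the bulk of the data even with
    gross outliers present.  Returns (slope, intercept, rsdr).
    """
    # ordinary least squares start
    slope, intercept = np.polyfit(x, y, 1)
    rsdr = _rsdr(y - (intercept + slope * x))
    if rsdr == 0:
        return float(slope), float(intercept), 0.0
    for _ in range(n_iter):
        res = y - (intercept + slope * x)
        rsdr = _rsdr(res)
        if rsdr == 0:
            break
        w = 1.0 / (1.0 + (res / rsdr) ** 2)
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx == 0:
            raise ValueError("x has zero (weighted) variance")
        new_slope = (w * (x - xm) * (y - ym)).sum() / sxx
        new_intercept = ym - new_slope * xm
        if (
            abs(new_slope - slope) < tol
            and abs(new_intercept - intercept) < tol
        ):
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept
    return float(slope), float(intercept), float(rsdr)


def robust_fit_with_outliers(
    scores: PairedScores, q: float = 0.01
) -> RobustFitResult:
    """Robust linear fit with automatic outlier detection at FDR ``q``.

    Follows the published outline of the ROUT procedure: fit the line
    robustly (IRLS, Lorentzian weights), standardize residuals by the
    robust scale (68.27th-percentile based RSDR with an n/(n-K)
    correction), convert each residual to a two-tailed t probability
    (df = n - K), and flag the largest residuals by a
    Benjamini-Hochberg-style step-up test at rate ``q``.  The final
    correlation ``r_clean`` is the ordinary Pearson r over the
    unflagged points.

    The commercial implementation of ROUT is not published in full
    detail, so agreement is behavioural (false-flag rate at or below
    ``q`` on clean data; gross outliers flagged), not bit-exact.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    x, y = scores.baseline, scores.variant
    n = scores.n
    if n < 5:
        raise ValueError("robust outlier detection needs n >= 5")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")

    slope, intercept, rsdr = _lorentzian_irls(x, y)
    res = y - (intercept + slope * x)
    flags = np.zeros(n, dtype=bool)
    if rsdr > 0:
        t_stat = np.abs(res) / rsdr
        pvals = 2.0 * stats.t.sf(t_stat, df=max(n - 2, 1))
        order = np.argsort(pvals)  # most extreme residuals first
        thresh = q * (np.arange(1, n + 1)) / n
        passed = pvals[order] <= thresh
        if passed.any():
            k = int(np.max(np.nonzero(passed)[0])) + 1
            flags[order[:k]] = True
    # never flag everything; an all-flagged fit is a degenerate outcome
    if flags.all():
        flags[:] = False

    keep = ~flags
    if keep.sum() >= 3 and np.ptp(x[keep]) > 0 and np.ptp(y[keep]) > 0:
        r_clean = float(stats.pearsonr(x[keep], y[keep]).statistic)
    elif np.allclose(res[keep], 0):
        r_clean = 1.0 if slope > 0 else -1.0
    else:
        r_clean = float("nan")
    return RobustFitResult(
        slope=slope,
        intercept=intercept,
        residual_scale=rsdr,
        outlier_flags=flags,
        r_clean=r_clean,
        n_removed=int(flags.sum()),
        n=n,
    )


def fisher_compare(
    r1: float, n1: int, r2: float, n2: int, tail: str = "one"
) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's r-to-z.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))``.

    ``tail="one"`` tests the directional alternative ``r1 < r2`` (the
    usual question when asking whether a variant's correlation falls
    short of a reference value): p = Phi(z).  ``tail="two"`` gives the
    symmetric two-sided p.
    """
    for r, name in ((r1, "r1"), (r2, "r2")):
        if not -1 < r < 1:
            raise ValueError(f"{name} must be strictly inside (-1, 1)")
    if min(n1, n2) <= 3:
        raise ValueError("both samples must have n > 3")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(r1) - math.atanh(r2)) / se
    if tail == "one":
        p = float(stats.norm.cdf(z))  # alternative: r1 < r2
    elif tail == "two":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("tail must be 'one' or 'two'")
    return float(z), p


def sample_size_for_r(
    r: float, alpha: float = 0.05, power: float = 0.8
) -> int:
    """Smallest n detecting correlation ``r`` at two-sided ``alpha``
    with the given power, from the Fisher-z normal approximation::

        n = ceil( ((z_{1-alpha/2} + z_{power}) / atanh(r))^2 + 3 )

    e.g. resolving r = 0.48 at alpha 0.05 with power 0.8 needs n = 32.
    """
    if not 0 < abs(r) < 1:
        raise ValueError("r must be in (0, 1) excluding 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n = ((z_a + z_b) / math.atanh(abs(r))) ** 2 + 3
    return max(int(math.ceil(n)), 4)


def cohens_d(
    group_a, group_b, paired: bool = False
) -> float:
    """Cohen's d effect size.

    Independent groups (default): mean difference over the pooled SD.
    ``paired=True``: mean within-participant change over the SD of the
    change scores (the groups must then be equal-length and aligned).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired groups must align")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            return 0.0 if diff.mean() == 0 else math.inf
        return float(diff.mean() / sd)
    na, nb = len(a), len(b)
    if min(na, nb) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else math.inf
    return float((a.mean() - b.mean()) / pooled)


@dataclass
class CommonVsSeparateResult:
    F: float
    df1: int
    df2: int
    p: float
    common_slope: float
    common_intercept: float
    common_r: float
    separate_better: bool


def _sse_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    sse = float(np.sum((y - (intercept + slope * x)) ** 2))
    return sse, float(slope), float(intercept)


def common_vs_separate_fit(
    scores_group1: PairedScores, scores_group2: PairedScores, alpha: float = 0.05
) -> CommonVsSeparateResult:
    """Extra-sum-of-squares F-test: one regression line or two?

    Fits a common line to the pooled data and separate lines per group;
    ``F = ((SSE_common - SSE_sep) / 2) / (SSE_sep / (n1 + n2 - 4))``
    with df (2, n1 + n2 - 4).  When the common model is retained
    (p >= alpha) its pooled slope/intercept/r are the ones to report.
    """
    x1, y1 = scores_group1.baseline, scores_group1.variant
    x2, y2 = scores_group2.baseline, scores_group2.variant
    n1, n2 = len(x1), len(x2)
    if min(n1, n2) < 3:
        raise ValueError("each group needs n >= 3")
    sse1, *_ = _sse_line(x1, y1)
    sse2, *_ = _sse_line(x2, y2)
    sse_sep = sse1 + sse2
    xc, yc = np.concatenate([x1, x2]), np.concatenate([y1, y2])
    sse_common, slope_c, int_c = _sse_line(xc, yc)
    df1, df2 = 2, n1 + n2 - 4
    if sse_sep == 0:
        F = 0.0 if sse_common == sse_sep else math.inf
    else:
        F = ((sse_common - sse_sep) / df1) / (sse_sep / df2)
    p = float(stats.f.sf(F, df1, df2))
    r_c = float(stats.pearsonr(xc, yc).statistic)
    return CommonVsSeparateResult(
        F=float(F), df1=df1, df2=df2, p=p,
        common_slope=slope_c, common_intercept=int_c, common_r=r_c,
        separate_better=p < alpha,
    )


def convert_scores(
    x,
    direction: str = "baseline_to_omst",
    slope: float = DEFAULT_CONVERSION_SLOPE,
    intercept: float = DEFAULT_CONVERSION_INTERCEPT,
):
    """Convert between baseline-MST and oMST LDI scores.

    ``baseline_to_omst`` applies ``y = intercept + slope * x``;
    ``omst_to_baseline`` applies the algebraic inverse.  The shipped
    defaults (slope 0.65, intercept 0.33) come from the pooled
    young+older regression between the two variants.
    """
    arr = np.asarray(x, dtype=float)
    if direction == "baseline_to_omst":
        out = intercept + slope * arr
    elif direction == "omst_to_baseline":
        if slope == 0:
            raise ValueError("cannot invert a zero slope")
        out = (arr - intercept) / slope
    else:
        raise ValueError(
            "direction must be 'baseline_to_omst' or 'omst_to_baseline'"
        )
    return out.item() if np.isscalar(x) or np.ndim(x) == 0 else out
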