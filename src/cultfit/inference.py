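"""Statistical layer: group comparisons, reliability, correlations, power.

Conventions throughout: two-sided p values, 95% intervals, pooled-variance
Student t for independent groups (Welch behind a flag), listwise deletion of
missing values inside each analysis cell.  The dependent-correlation
comparison implements the non-overlapping case — two correlations computed on
the same participants that share no variable — via the Fisher-z confidence
intervals combined with the asymptotic covariance of the two correlations
(Zou's procedure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InsufficientDataError, ParameterError, ValidationError


@dataclass(frozen=True)
class ComparisonResult:
    """A paired or independent two-sample mean comparison."""

    design: str           # 'paired' | 'independent'
    estimate: float       # mean difference (A - B, or own - other)
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    n: Tuple[int, ...]
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    df: int
    p: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass(frozen=True)
class DependentCorrelationComparison:
    """Zou-style CI for the difference of two non-overlapping correlations."""

    r_ab: float
    r_cd: float
    difference: float
    ci_low: float
    ci_high: float
    n: int
    corr_between: float          # asymptotic corr of the two sample correlations
    pairwise: Mapping[Tuple[str, str], float]

    @property
    def significant(self) -> bool:
        """True when the 95% CI for r_ab - r_cd excludes zero."""
        return bool(self.ci_low > 0 or self.ci_high < 0)


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def feature_compare(group_a, group_b, pooled: bool = True) -> ComparisonResult:
    """Independent two-sample t comparison of one feature across groups.

    Student (pooled-variance) t by default — the convention matching the
    reported df of n1+n2-2 — with Welch available via ``pooled=False``.
    """
    a, b = _clean(group_a), _clean(group_b)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("feature_compare needs >= 2 values per group")
    estimate = float(a.mean() - b.mean())
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        warnings.warn("zero pooled variance: p undefined", stacklevel=2)
        df = len(a) + len(b) - 2
        t = 0.0 if estimate == 0 else np.nan
        return ComparisonResult("independent", estimate, t, df, np.nan,
                                np.nan, np.nan, (len(a), len(b)), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=pooled)
    ci = res.confidence_interval(0.95)
    return ComparisonResult("independent", estimate, float(res.statistic),
                            int(round(res.df)), float(res.pvalue),
                            float(ci.low), float(ci.high), (len(a), len(b)))


def fit_within_compare(fit_table: pd.DataFrame, culture: str,
                       situation: str, measure: str | None = None) -> ComparisonResult:
    """Paired t of fit-to-own vs fit-to-other for one culture and situation."""
    sub = fit_table[(fit_table["culture"] == culture)
                    & (fit_table["situation"] == situation)]
    if measure is not None:
        sub = sub[sub["measure"] == measure]
    targets = sorted(sub["target_culture"].unique())
    others = [t for t in targets if t != culture]
    if culture not in targets or len(others) != 1:
        raise ValidationError(
            f"need scores toward {culture!r} and exactly one other culture; "
            f"found targets {targets}"
        )
    own = sub[sub["target_culture"] == culture].set_index("participant")["z"]
    other = sub[sub["target_culture"] == others[0]].set_index("participant")["z"]
    paired = pd.concat({"own": own, "other": other}, axis=1).dropna()
    if len(paired) < 2:
        raise InsufficientDataError("fewer than 2 complete fit pairs")
    diffs = paired["own"] - paired["other"]
    estimate = float(diffs.mean())
    if np.allclose(diffs, diffs.iloc[0]):
        if diffs.iloc[0] == 0:
            return ComparisonResult("paired", 0.0, 0.0, len(paired) - 1, 1.0,
                                    0.0, 0.0, (len(paired),), degenerate=True)
        warnings.warn("constant nonzero paired differences: p undefined",
                      stacklevel=2)
        return ComparisonResult("paired", estimate, np.nan, len(paired) - 1,
                                np.nan, estimate, estimate, (len(paired),),
                                degenerate=True)
    res = stats.ttest_rel(paired["own"], paired["other"])
    ci = res.confidence_interval(0.95)
    return ComparisonResult("paired", estimate, float(res.statistic),
                            len(paired) - 1, float(res.pvalue),
                            float(ci.low), float(ci.high), (len(paired),))


def fit_between_compare(fit_table: pd.DataFrame, target: str,
                        situation: str, measure: str | None = None,
                        pooled: bool = True) -> ComparisonResult:
    """Members vs non-members of the target culture on fit toward that target."""
    sub = fit_table[(fit_table["target_culture"] == target)
                    & (fit_table["situation"] == situation)]
    if measure is not None:
        sub = sub[sub["measure"] == measure]
    members = sub.loc[sub["culture"] == target, "z"]
    others = sub.loc[sub["culture"] != target, "z"]
    if members.empty or others.empty:
        raise InsufficientDataError(
            f"both cultures need scores toward {target!r} in {situation!r}"
        )
    return feature_compare(members, others, pooled=pooled)


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha of a participants x items (situations) matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row totals),
    sample variances (n-1 denominator), listwise deletion of incomplete rows.
    """
    arr = pd.DataFrame(matrix).dropna().to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise InsufficientDataError("cronbach_alpha needs >= 2 columns")
    if arr.shape[0] < 3:
        raise InsufficientDataError("cronbach_alpha needs >= 3 complete rows")
    k = arr.shape[1]
    total_var = np.var(arr.sum(axis=1), ddof=1)
    if total_var == 0:
        warnings.warn("zero total variance: alpha undefined", stacklevel=2)
        return np.nan
    item_vars = np.var(arr, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_vars / total_var))


def correlate_fits(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with exact-t p value and Fisher-z CI."""
    frame = pd.DataFrame({"x": np.asarray(x, dtype=float),
                          "y": np.asarray(y, dtype=float)}).dropna()
    n = len(frame)
    if n < 4:
        raise InsufficientDataError("correlate_fits needs >= 4 complete pairs")
    if frame["x"].std(ddof=1) == 0 or frame["y"].std(ddof=1) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return CorrelationResult(np.nan, n, n - 2, np.nan, np.nan, np.nan,
                                 degenerate=True)
    res = stats.pearsonr(frame["x"], frame["y"])
    r = float(res.statistic)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    if abs(r) < 1:
        half = zcrit / np.sqrt(n - 3)
        lo, hi = np.tanh(np.arctanh(r) - half), np.tanh(np.arctanh(r) + half)
    else:
        lo = hi = r
    return CorrelationResult(r, n, n - 2, float(res.pvalue), float(lo), float(hi))


def _pairwise_correlations(arr: np.ndarray, names: Sequence[str]):
    corr = np.corrcoef(arr, rowvar=False)
    out = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out[(names[i], names[j])] = float(corr[i, j])
            out[(names[j], names[i])] = float(corr[i, j])
    return out, corr


def compare_dependent_correlations(
    data: pd.DataFrame,
    pairing: Tuple[Tuple[str, str], Tuple[str, str]],
    alpha: float = 0.05,
) -> DependentCorrelationComparison:
    """CI for r(a,b) - r(c,d) on the same participants, a,b,c,d all distinct.

    The two correlations are dependent because they come from the same sample;
    the CI combines each correlation's Fisher-z interval with their asymptotic
    correlation, computed from the six pairwise correlations among the four
    variables (Zou's non-overlapping procedure).  Overlapping pairings (a
    shared variable) are a different procedure and are rejected.
    """
    (a, b), (c, d) = pairing
    names = [a, b, c, d]
    if len(set(names)) != 4:
        raise ParameterError(
            "overlapping pairing: the non-overlapping comparison requires four "
            "distinct variables (the overlapping variant is not implemented)"
        )
    missing = sorted(set(names) - set(data.columns))
    if missing:
        raise ValidationError(f"data lacks column(s) {missing}")
    frame = data[names].dropna()
    n = len(frame)
    if n < 10:
        raise InsufficientDataError("needs >= 10 complete rows")
    arr = frame.to_numpy(dtype=float)
    pairwise, _ = _pairwise_correlations(arr, names)

    r12, r34 = pairwise[(a, b)], pairwise[(c, d)]
    r13, r14 = pairwise[(a, c)], pairwise[(a, d)]
    r23, r24 = pairwise[(b, c)], pairwise[(b, d)]

    # asymptotic correlation between the two sample correlations
    num = (0.5 * r12 * r34 * (r13**2 + r14**2 + r23**2 + r24**2)
           + r13 * r24 + r14 * r23
           - (r12 * r13 * r14 + r12 * r23 * r24
              + r13 * r23 * r34 + r14 * r24 * r34))
    den = (1 - r12**2) * (1 - r34**2)
    corr_between = float(num / den) if den > 0 else 0.0
    corr_between = float(np.clip(corr_between, -1.0, 1.0))

    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit / np.sqrt(n - 3)
    l1, u1 = np.tanh(np.arctanh(r12) - half), np.tanh(np.arctanh(r12) + half)
    l2, u2 = np.tanh(np.arctanh(r34) - half), np.tanh(np.arctanh(r34) + half)

    diff = r12 - r34
    low = diff - np.sqrt((r12 - l1)**2 + (u2 - r34)**2
                         - 2 * corr_between * (r12 - l1) * (u2 - r34))
    high = diff + np.sqrt((u1 - r12)**2 + (r34 - l2)**2
                          - 2 * corr_between * (u1 - r12) * (r34 - l2))
    return DependentCorrelationComparison(
        r_ab=r12, r_cd=r34, difference=float(diff),
        ci_low=float(low), ci_high=float(high), n=n,
        corr_between=corr_between,
        pairwise={k: v for k, v in pairwise.items()},
    )


@dataclass(frozen=True)
class DetectableCorrelation:
    r: float              # unrounded root of the power equation
    r_rounded: float      # reported at 2 decimals
    n: int
    alpha: float
    power: float


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided level-alpha test of zero correlation.

    Uses the noncentral-t representation of the correlation t statistic,
    t = r*sqrt(n-2)/sqrt(1-r^2) with noncentrality r*sqrt(n)/sqrt(1-r^2) —
    the classic fixed-score power model behind standard power software.
    """
    if not (0 <= r < 1):
        raise ParameterError("r must lie in [0, 1)")
    if n < 4:
        raise ParameterError("n must be >= 4")
    df = n - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ncp = r * np.sqrt(n) / np.sqrt(1 - r**2)
    p = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    if np.isnan(p):          # extreme noncentrality: power is 1 to machine precision
        p = 1.0
    return float(p)


def detectable_r(n: int, alpha: float = 0.05,
                 power: float = 0.80) -> DetectableCorrelation:
    """Smallest population correlation detectable with the target power.

    Root-finds ``correlation_power(r, n, alpha) = power`` in r.  The unrounded
    root is returned alongside its conventional 2-decimal report.
    """
    if n < 4:
        raise ParameterError("n must be >= 4")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ParameterError("alpha and power must lie in (0, 1)")
    if power <= correlation_power(0.0, n, alpha):
        raise ParameterError(
            f"target power {power} not above the level alpha={alpha}: "
            f"unattainable by any r > 0"
        )
    root = optimize.brentq(
        lambda r: correlation_power(r, n, alpha) - power, 1e-9, 1 - 1e-9,
        xtol=1e-12,
    )
    return DetectableCorrelation(r=float(root), r_rounded=round(float(root), 2),
                                 n=n, alpha=alpha, power=power)
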