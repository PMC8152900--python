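"""Cognitive test scoring and group comparison of gain scores.

Scoring covers the three paper-and-pencil instruments of the study design:
the d2-R letter-cancellation test (concentration performance, CP), the
number-connection test ZVT (mean completion time over 4 forms) and the
WAIS-style digit span (count of correctly recalled trials).

Pre-to-post percentage gain scores are compared between groups with
unpaired Welch t tests (robust to unequal sizes and variances).  When a
baseline score confounds the gain, group regression lines are compared at
design points spanning the baseline distribution with a Johnson-Neyman
ANCOVA: bootstrap standard errors at each design point and a simultaneous
critical value from the K-variate Studentized maximum modulus distribution
with infinite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "D2RLine",
    "score_d2r",
    "score_zvt",
    "score_digit_span",
    "percent_gain",
    "WelchResult",
    "welch_test",
    "welch_ci_from_summary",
    "JNResult",
    "jn_ancova",
    "jn_point_stat",
    "smm_critical_value",
    "cohen_d_from_t",
]


@dataclass
class D2RLine:
    """Per-line d2-R counts.

    processed: symbols the subject reached on the line;
    processed_targets: targets among the processed symbols;
    commission_errors: distractors marked; overlooked_targets: targets
    among the processed symbols left unmarked (errors of overlooking).
    """

    processed: int
    processed_targets: int
    commission_errors: int
    overlooked_targets: int

    def validate(self) -> None:
        c = (self.processed, self.processed_targets, self.commission_errors,
             self.overlooked_targets)
        if any(v < 0 for v in c):
            raise ValueError(f"negative count in d2-R line {c}")
        if self.processed_targets > self.processed:
            raise ValueError("more processed targets than processed symbols")
        if self.overlooked_targets > self.processed_targets:
            raise ValueError("more overlooked targets than processed targets")
        if self.commission_errors > self.processed - self.processed_targets:
            raise ValueError("more commission errors than processed distractors")


def score_d2r(lines: Sequence[D2RLine], convention: str = "literal") -> int:
    """d2-R concentration performance (CP).

    convention="literal" (default): CP = total processed targets minus the
    sum of commission and overlooking errors.  convention="manual": CP =
    correctly marked targets minus commission errors, i.e. overlooked
    targets are first removed from the processed-target count (the scoring
    found in the test manual tradition).  The two differ by counting
    overlooked targets once or twice.
    """
    for ln in lines:
        ln.validate()
    targets = sum(ln.processed_targets for ln in lines)
    commission = sum(ln.commission_errors for ln in lines)
    overlooked = sum(ln.overlooked_targets for ln in lines)
    if convention == "literal":
        return targets - (commission + overlooked)
    if convention == "manual":
        return (targets - overlooked) - commission
    raise ValueError(f"unknown convention {convention!r}")


def score_zvt(form_times_seconds: Sequence[float]) -> float:
    """ZVT total score: total completion time over all forms divided by 4."""
    t = np.asarray(form_times_seconds, dtype=np.float64)
    if t.size != 4:
        raise ValueError(f"ZVT uses 4 forms, got {t.size}")
    if np.any(t < 0):
        raise ValueError("negative completion time")
    return float(t.sum() / 4.0)


def score_digit_span(trial_outcomes: Sequence[bool]) -> int:
    """Digit span: total number of correctly remembered trials."""
    return int(np.count_nonzero(np.asarray(trial_outcomes, dtype=bool)))


def percent_gain(pre, post):
    """Pre-to-post gain in percent, 100 * (post - pre) / pre."""
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if np.any(pre == 0):
        raise ValueError("pre score of 0 admits no percentage gain")
    out = 100.0 * (post - pre) / pre
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Welch comparisons
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_diff: float
    ci95: tuple
    d: float


def welch_test(x, y) -> WelchResult:
    """Unpaired Welch t test of two groups, with effect size.

    t = (mean(x) - mean(y)) / sqrt(s1^2/n1 + s2^2/n2); fractional df by
    Welch-Satterthwaite; two-sided p from the central t distribution; 95% CI
    of the mean difference; Cohen's d defined as t * sqrt(1/n1 + 1/n2).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x.mean() == y.mean():
            raise ValueError("zero variance in both groups with equal means: t undefined")
        raise ValueError("zero variance in both groups")
    se2 = v1 / n1 + v2 / n2
    diff = x.mean() - y.mean()
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    ci = (diff - tcrit * np.sqrt(se2), diff + tcrit * np.sqrt(se2))
    d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    return WelchResult(t=float(t), df=float(df), p=float(p), mean_diff=float(diff),
                       ci95=(float(ci[0]), float(ci[1])), d=float(d))


def welch_ci_from_summary(mean_diff: float, t: float, df: float) -> tuple:
    """95% CI of a mean difference reconstructed from printed t and df.

    SE = |mean_diff / t|; bounds = mean_diff +/- t_{0.975, df} * SE.
    """
    if t == 0:
        raise ValueError("t = 0: standard error cannot be reconstructed")
    if df <= 0:
        raise ValueError("df must be positive")
    se = abs(mean_diff / t)
    tcrit = stats.t.ppf(0.975, df)
    return (mean_diff - tcrit * se, mean_diff + tcrit * se)


# ---------------------------------------------------------------------------
# Johnson-Neyman ANCOVA
# ---------------------------------------------------------------------------

def smm_critical_value(k: int, alpha: float = 0.05) -> float:
    """Simultaneous critical value for K standardized comparisons.

    Infinite-df Studentized maximum modulus under independence:
    c = Phi^{-1}((1 + (1 - alpha)^{1/K}) / 2), so that
    P(max_k |Z_k| <= c) = 1 - alpha.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(stats.norm.ppf((1.0 + (1.0 - alpha) ** (1.0 / k)) / 2.0))


def jn_point_stat(est_control: float, est_exercise: float, se: float) -> tuple:
    """Design-point statistic and two-sided normal p from group estimates.

    stat = (control - exercise) / SE; p = 2 (1 - Phi(|stat|)).  Useful for
    reconstructing published design-point tables from their estimates.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    stat = (est_control - est_exercise) / se
    return float(stat), float(2.0 * stats.norm.sf(abs(stat)))


def cohen_d_from_t(t: float, n1: int, n2: int = None) -> float:
    """Cohen's d from a t statistic: t * sqrt(1/n1 + 1/n2) for two samples,
    t / sqrt(n) for a one-sample test."""
    if n2 is None:
        return float(t / np.sqrt(n1))
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


@dataclass
class JNResult:
    design_points: np.ndarray
    est_control: np.ndarray
    est_exercise: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    crit: float
    p: np.ndarray
    significant: np.ndarray


def _group_line(x, y):
    X = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def jn_ancova(y, x_covariate, group, n_points: int = 10, B: int = 5000,
              alpha: float = 0.05, seed: int = 0) -> JNResult:
    """Johnson-Neyman comparison of group regression lines at design points.

    Fits a least-squares line of ``y`` on the covariate within each group
    (group coded 0 = control, 1 = exercise) and compares predicted values at
    ``n_points`` design points: the 25th and 75th percentile of the pooled
    covariate (linear-interpolation percentiles) and ``n_points - 2`` points
    evenly spaced between.  The SE of the predicted difference at each point
    comes from a case bootstrap within each group (B resamples); the
    statistic is (control - exercise) / SE with a two-sided normal p value,
    and simultaneous significance uses the K-variate Studentized maximum
    modulus critical value (infinite df).
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x_covariate, dtype=np.float64)
    g = np.asarray(group)
    if n_points < 2:
        raise ValueError("need at least 2 design points")
    idx0, idx1 = np.flatnonzero(g == 0), np.flatnonzero(g != 0)
    if len(idx0) < 5 or len(idx1) < 5:
        raise ValueError("each group needs n >= 5")
    for name, idx in (("control", idx0), ("exercise", idx1)):
        if np.ptp(x[idx]) == 0:
            raise ValueError(f"covariate is constant within the {name} group")
    q25, q75 = np.percentile(x, [25, 75])  # type-7 linear interpolation
    points = np.linspace(q25, q75, n_points)

    b0 = _group_line(x[idx0], y[idx0])
    b1 = _group_line(x[idx1], y[idx1])
    est0 = b0[0] + b0[1] * points
    est1 = b1[0] + b1[1] * points

    rng = np.random.default_rng(seed)
    boot_diff = np.empty((B, n_points))
    for b in range(B):
        r0 = idx0[rng.integers(0, len(idx0), len(idx0))]
        r1 = idx1[rng.integers(0, len(idx1), len(idx1))]
        while np.ptp(x[r0]) == 0:
            r0 = idx0[rng.integers(0, len(idx0), len(idx0))]
        while np.ptp(x[r1]) == 0:
            r1 = idx1[rng.integers(0, len(idx1), len(idx1))]
        c0 = _group_line(x[r0], y[r0])
        c1 = _group_line(x[r1], y[r1])
        boot_diff[b] = (c0[0] + c0[1] * points) - (c1[0] + c1[1] * points)
    se = boot_diff.std(axis=0, ddof=1)

    stat = (est0 - est1) / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    crit = smm_critical_value(n_points, alpha)
    return JNResult(design_points=points, est_control=est0, est_exercise=est1,
                    se=se, stat=stat, crit=crit, p=p,
                    significant=np.abs(stat) >= crit)
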