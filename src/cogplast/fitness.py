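"""Graded-exercise-test (GXT) analytics.

A GXT on a cycle ergometer yields workload/heart-rate pairs and capillary
blood lactate per stage.  From these we compute the standard fitness indices:

* PWC120 / PWC170 — physical working capacity, the linearly interpolated
  workload at heart rate 120 / 170 bpm, divided by body mass (W/kg);
* the lactate curve — a least-squares cubic of lactate on workload;
* P3 — workload at a fixed 3 mmol/L lactate concentration;
* IAT — individual anaerobic threshold by the "1.5 mmol" method: the workload
  at which the fitted curve exceeds its minimum (the lactate equivalent) by
  1.5 mmol/L.

Thresholds are located by bisection on the fitted cubic restricted to the
observed workload range, which avoids spurious out-of-range cubic roots.
A training-intensity check normalizes training-session lactate to each
subject's absolute IAT lactate and tests the cohort mean against 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GXTRecord",
    "FitnessIndices",
    "pwc",
    "fit_lactate_curve",
    "threshold_workload",
    "iat_1p5",
    "compute_fitness_indices",
    "training_lactate_index",
]

ROOT_TOL_W = 0.005  # bisection xtol in watts; |dW| < 0.01 W guaranteed


@dataclass
class GXTRecord:
    """One subject's graded exercise test.

    stages: workloads in W, strictly increasing; hr: beats/min per stage;
    lactate: mmol/L per stage (NaN where no sample); body_mass: kg.
    """

    stages: np.ndarray
    hr: np.ndarray
    lactate: np.ndarray
    body_mass: float

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.float64)
        self.hr = np.asarray(self.hr, dtype=np.float64)
        self.lactate = np.asarray(self.lactate, dtype=np.float64)
        if np.any(np.diff(self.stages) <= 0):
            raise ValueError("workloads must be strictly increasing")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if len(self.hr) != len(self.stages) or len(self.lactate) != len(self.stages):
            raise ValueError("stages, hr and lactate must have equal length")
        if len(self.hr) < 2:
            raise ValueError("need at least 2 workload-HR pairs")

    @property
    def lactate_points(self) -> tuple:
        ok = np.isfinite(self.lactate)
        return self.stages[ok], self.lactate[ok]


@dataclass
class FitnessIndices:
    """Body-weight-adjusted fitness indices (W/kg); NaN where undefined."""

    pwc120: float
    pwc170: float
    iat: float
    iat_lactate: float
    p3: float


def pwc(record: GXTRecord, target_hr: float) -> float:
    """Workload at ``target_hr`` by linear interpolation, per kg body mass."""
    hr, w = record.hr, record.stages
    if not (np.min(hr) <= target_hr <= np.max(hr)):
        raise ValueError(
            f"target HR {target_hr} outside observed range [{np.min(hr)}, {np.max(hr)}]"
        )
    # exact match wins; otherwise interpolate inside the bracketing segment
    exact = np.flatnonzero(hr == target_hr)
    if exact.size:
        return float(w[exact[0]] / record.body_mass)
    above = np.flatnonzero(hr >= target_hr)
    below = np.flatnonzero(hr <= target_hr)
    j = above[above > 0][0] if (above > 0).any() else above[0]
    i = below[below < j].max()
    frac = (target_hr - hr[i]) / (hr[j] - hr[i])
    return float((w[i] + frac * (w[j] - w[i])) / record.body_mass)


def fit_lactate_curve(record: GXTRecord) -> np.ndarray:
    """Least-squares cubic of lactate on workload.

    Returns coefficients ``c`` with lactate(W) = c[0] + c[1]*W + c[2]*W^2 +
    c[3]*W^3 (ascending powers).  With exactly 4 points the cubic
    interpolates them.
    """
    w, lac = record.lactate_points
    if len(w) < 4:
        raise ValueError(f"cubic fit needs >= 4 lactate points, got {len(w)}")
    return np.polynomial.polynomial.polyfit(w, lac, deg=3)


def _curve_val(coeffs: np.ndarray, w) -> np.ndarray:
    return np.polynomial.polynomial.polyval(w, coeffs)


def _first_upcrossing(coeffs, target, lo, hi, start=None) -> float:
    """Smallest W in [lo, hi] (or [start, hi]) with curve(W) = target,
    approached from below; bisection on a dense bracket grid."""
    a = lo if start is None else start
    grid = np.linspace(a, hi, 512)
    vals = _curve_val(coeffs, grid) - target
    if np.any(np.abs(vals) < 1e-12):
        return float(grid[np.argmax(np.abs(vals) < 1e-12)])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if sign_change.size == 0:
        raise ValueError(
            f"fitted curve does not cross {target} mmol/L within [{a:.1f}, {hi:.1f}] W"
        )
    k = sign_change[0]
    root = optimize.bisect(lambda x: _curve_val(coeffs, x) - target,
                           grid[k], grid[k + 1], xtol=ROOT_TOL_W)
    return float(root)


def threshold_workload(coeffs: np.ndarray, target_lactate: float,
                       w_range: Sequence[float]) -> float:
    """Workload where the fitted curve first reaches ``target_lactate``.

    Restricted to the observed workload range so out-of-range cubic roots
    never leak out; |dW| < 0.01 W.
    """
    lo, hi = float(w_range[0]), float(w_range[1])
    return _first_upcrossing(coeffs, target_lactate, lo, hi)


def iat_1p5(coeffs: np.ndarray, w_range: Sequence[float],
            delta: float = 1.5) -> tuple:
    """Individual anaerobic threshold by the 1.5 mmol method.

    The anchor is the minimum fitted lactate over the observed range (the
    "lactate equivalent"); the IAT is the workload where the curve exceeds
    that anchor by ``delta`` mmol/L.  Returns ``(workload_W, absolute
    lactate at the IAT)``.  If the curve is decreasing over the whole range
    the anchor sits at the right edge and no crossing exists (raises).
    """
    lo, hi = float(w_range[0]), float(w_range[1])
    grid = np.linspace(lo, hi, 512)
    vals = _curve_val(coeffs, grid)
    k = int(np.argmin(vals))
    # polish the minimum unless it is at a boundary
    if 0 < k < len(grid) - 1:
        res = optimize.minimize_scalar(lambda x: _curve_val(coeffs, x),
                                       bounds=(grid[k - 1], grid[k + 1]), method="bounded")
        w_min, anchor = float(res.x), float(res.fun)
    else:
        w_min, anchor = float(grid[k]), float(vals[k])
    target = anchor + delta
    w_iat = _first_upcrossing(coeffs, target, lo, hi, start=w_min)
    return w_iat, float(_curve_val(coeffs, w_iat))


def compute_fitness_indices(record: GXTRecord, p3_lactate: float = 3.0) -> FitnessIndices:
    """All fitness indices for one GXT record (W/kg; NaN where undefined)."""

    def _safe(f):
        try:
            return f()
        except ValueError:
            return np.nan

    pwc120 = _safe(lambda: pwc(record, 120.0))
    pwc170 = _safe(lambda: pwc(record, 170.0))
    w, _ = record.lactate_points
    iat = iat_lac = p3 = np.nan
    if len(w) >= 4:
        coeffs = fit_lactate_curve(record)
        rng = (w.min(), w.max())
        p3_w = _safe(lambda: threshold_workload(coeffs, p3_lactate, rng))
        p3 = p3_w / record.body_mass if np.isfinite(p3_w) else np.nan
        res = _safe(lambda: iat_1p5(coeffs, rng))
        if res is not np.nan:
            iat = res[0] / record.body_mass
            iat_lac = res[1]
    return FitnessIndices(pwc120=pwc120, pwc170=pwc170, iat=iat,
                          iat_lactate=iat_lac, p3=p3)


@dataclass
class TrainingLactateResult:
    percent: np.ndarray          # per-subject training lactate, % of IAT lactate
    mean_percent: float
    mean_difference: float       # mean_percent - 100
    ci95: tuple                  # CI of the mean difference
    t: float
    df: int
    p: float
    d: float                     # Cohen's d = t / sqrt(n)


def training_lactate_index(session_samples, iat_lactate) -> TrainingLactateResult:
    """Training-intensity check against the anaerobic threshold.

    ``session_samples[i]`` holds, for subject i, one list of lactate samples
    per training session.  Samples are averaged within each session, the
    session means averaged, and the result expressed as a percentage of the
    subject's absolute IAT lactate.  The cohort of percentages is compared
    against mu0 = 100 with a one-sample t test; Cohen's d = t / sqrt(n).
    """
    iat_lactate = np.atleast_1d(np.asarray(iat_lactate, dtype=np.float64))
    if np.any(iat_lactate <= 0):
        raise ValueError("iat_lactate must be positive")
    if len(iat_lactate) == 1:
        iat_lactate = np.repeat(iat_lactate, len(session_samples))
    percents = []
    for subj, iat in zip(session_samples, iat_lactate):
        if len(subj) < 1 or any(len(s) < 1 for s in subj):
            raise ValueError("each subject needs >= 1 session with >= 1 sample")
        session_means = [float(np.mean(s)) for s in subj]
        percents.append(100.0 * float(np.mean(session_means)) / float(iat))
    percents = np.asarray(percents)
    n = len(percents)
    diff = float(percents.mean() - 100.0)
    se = percents.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
    if se == 0:  # all subjects at the same percentage
        t = 0.0 if diff == 0 else np.sign(diff) * np.inf
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = 2.0 * stats.t.sf(abs(t), n - 1)
    tcrit = stats.t.ppf(0.975, n - 1) if n > 1 else np.nan
    ci = (diff - tcrit * se, diff + tcrit * se)
    d = float(t / np.sqrt(n))
    return TrainingLactateResult(percent=percents, mean_percent=float(percents.mean()),
                                 mean_difference=diff, ci95=ci, t=float(t),
                                 df=n - 1, p=float(p), d=d)
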