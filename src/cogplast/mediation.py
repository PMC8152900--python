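"""Regression-based mediation analysis with percentile-bootstrap CIs.

The parallel-mediator model regresses each mediator on the binary treatment
(path a), and the outcome on treatment plus mediators (paths b and the
direct effect c'), optionally with covariates in both models.  The indirect
effect ab = a * b is the quantity of interest; its sampling distribution is
built by case resampling (percentile bootstrap), and mediation is claimed
when the 95% percentile CI excludes zero.  Coefficient standard errors use
heteroscedasticity-consistent sandwich estimators (HC4 by default, suited to
small samples).  A Huber-type robust variant downweights extreme cases via
robust Mahalanobis distances over (M, Y, covariates), with the tuning cutoff
chosen so that a fraction kappa of cases is expected to be downweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "MediationData",
    "MediationResult",
    "fit_paths",
    "percentile_bootstrap",
    "robust_mediation",
    "spearman",
]


@dataclass
class MediationData:
    """Complete-case data for an X -> M -> Y mediation model.

    X binary treatment (0 = control, 1 = intervention); M one column per
    mediator; covariates enter both path models.  Rows with any missing
    value are dropped (listwise deletion) and counted.
    """

    X: np.ndarray
    M: np.ndarray
    Y: np.ndarray
    covariates: Optional[np.ndarray] = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64).ravel()
        self.M = np.atleast_2d(np.asarray(self.M, dtype=np.float64))
        if self.M.shape[0] != len(self.X) and self.M.shape[1] == len(self.X):
            self.M = self.M.T
        self.Y = np.asarray(self.Y, dtype=np.float64).ravel()
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
            if self.covariates.shape[0] != len(self.X):
                self.covariates = self.covariates.T
        cols = [self.X[:, None], self.M, self.Y[:, None]]
        if self.covariates is not None:
            cols.append(self.covariates)
        full = np.hstack(cols)
        keep = np.all(np.isfinite(full), axis=1)
        self.n_dropped = int((~keep).sum())
        if self.n_dropped:
            self.X, self.M, self.Y = self.X[keep], self.M[keep], self.Y[keep]
            if self.covariates is not None:
                self.covariates = self.covariates[keep]
        if set(np.unique(self.X)) - {0.0, 1.0}:
            raise ValueError("X must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def n_mediators(self) -> int:
        return self.M.shape[1]


@dataclass
class MediationResult:
    a: np.ndarray                 # X -> M path per mediator
    b: np.ndarray                 # M -> Y path per mediator
    c_prime: float                # direct effect
    ab: np.ndarray                # indirect effect per mediator
    se_a: np.ndarray = None
    se_b: np.ndarray = None
    se_c_prime: float = np.nan
    ci95: np.ndarray = None       # (n_mediators, 2) percentile bounds
    se_boot: np.ndarray = None
    ab_ps: np.ndarray = None      # partially standardized ab = ab / SD(Y)
    ab_ps_ci95: np.ndarray = None
    B: int = 0
    seed: int = 0
    n_redrawn: int = 0
    ci_excludes_point: bool = False


def _ols(Xd: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return coef


def _hc_se(Xd: np.ndarray, resid: np.ndarray, kind: str) -> np.ndarray:
    """Heteroscedasticity-consistent sandwich SEs (HC0 / HC3 / HC4)."""
    n, p = Xd.shape
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    h = np.einsum("ij,jk,ik->i", Xd, XtX_inv, Xd)
    e2 = resid ** 2
    if kind == "HC0":
        w = e2
    elif kind == "HC3":
        w = e2 / (1.0 - h) ** 2
    elif kind == "HC4":
        delta = np.minimum(4.0, n * h / p)
        w = e2 / (1.0 - h) ** delta
    else:
        raise ValueError(f"unknown sandwich flavor {kind!r}")
    meat = (Xd * w[:, None]).T @ Xd
    cov = XtX_inv @ meat @ XtX_inv
    return np.sqrt(np.diag(cov))


def _path_estimates(X, M, Y, cov):
    """(a, b, c_prime, designs) by two OLS stages; raises on rank deficiency."""
    n = len(X)
    base = [np.ones(n), X]
    if cov is not None:
        base.extend(cov.T)
    Xm = np.column_stack(base)                      # mediator model design
    Xy = np.column_stack([np.ones(n), X, M] + ([*(cov.T)] if cov is not None else []))
    for name, D in (("mediator", Xm), ("outcome", Xy)):
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError(f"{name} model design is rank deficient")
    a = np.array([_ols(Xm, M[:, j])[1] for j in range(M.shape[1])])
    coef_y = _ols(Xy, Y)
    c_prime = coef_y[1]
    b = coef_y[2:2 + M.shape[1]]
    return a, b, c_prime, Xm, Xy, coef_y


def fit_paths(data: MediationData, hc: str = "HC4") -> MediationResult:
    """Point estimates of the mediation paths with sandwich SEs.

    M_j = a_j X + covariates + e ; Y = c' X + sum_j b_j M_j + covariates +
    e'.  SEs come from the chosen heteroscedasticity-consistent estimator.
    """
    if data.n < 10:
        raise ValueError("mediation model needs n >= 10")
    a, b, c_prime, Xm, Xy, coef_y = _path_estimates(data.X, data.M, data.Y,
                                                    data.covariates)
    se_a = np.empty_like(a)
    for j in range(data.n_mediators):
        cj = _ols(Xm, data.M[:, j])
        se_a[j] = _hc_se(Xm, data.M[:, j] - Xm @ cj, hc)[1]
    se_y = _hc_se(Xy, data.Y - Xy @ coef_y, hc)
    return MediationResult(a=a, b=b, c_prime=float(c_prime), ab=a * b,
                           se_a=se_a, se_b=se_y[2:2 + data.n_mediators],
                           se_c_prime=float(se_y[1]),
                           ab_ps=a * b / data.Y.std(ddof=1))


def percentile_bootstrap(data: MediationData, B: int = 50000, seed: int = 0,
                         stratified: bool = False, hc: str = "HC4") -> MediationResult:
    """Percentile-bootstrap CI for the indirect effect(s).

    Rows are resampled with replacement B times (unstratified by default);
    ab is recomputed per draw and the CI taken at the empirical 2.5/97.5
    percentiles.  The partially standardized effect ab / SD(Y) gets its own
    percentile CI.  Draws in which X becomes constant are discarded and
    redrawn (counted in ``n_redrawn``).
    """
    if B < 1000:
        raise ValueError("B must be >= 1000 for stable percentile CIs")
    res = fit_paths(data, hc=hc)
    rng = np.random.default_rng(seed)
    n, m = data.n, data.n_mediators
    idx1 = np.flatnonzero(data.X == 1)
    idx0 = np.flatnonzero(data.X == 0)
    ab_draws = np.empty((B, m))
    abps_draws = np.empty((B, m))
    redrawn = 0
    for bi in range(B):
        while True:
            if stratified:
                rows = np.concatenate([idx1[rng.integers(0, len(idx1), len(idx1))],
                                       idx0[rng.integers(0, len(idx0), len(idx0))]])
            else:
                rows = rng.integers(0, n, n)
            X = data.X[rows]
            if X.min() == X.max():
                redrawn += 1
                continue
            M = data.M[rows]
            Y = data.Y[rows]
            cov = data.covariates[rows] if data.covariates is not None else None
            try:
                a, b, _, _, _, _ = _path_estimates(X, M, Y, cov)
            except ValueError:
                redrawn += 1
                continue
            break
        ab_draws[bi] = a * b
        abps_draws[bi] = a * b / Y.std(ddof=1)
    ci = np.percentile(ab_draws, [2.5, 97.5], axis=0).T
    ci_ps = np.percentile(abps_draws, [2.5, 97.5], axis=0).T
    res.ci95 = ci
    res.ab_ps_ci95 = ci_ps
    res.se_boot = ab_draws.std(axis=0, ddof=1)
    res.B = B
    res.seed = seed
    res.n_redrawn = redrawn
    res.ci_excludes_point = bool(np.any((res.ab < ci[:, 0]) | (res.ab > ci[:, 1])))
    return res


# ---------------------------------------------------------------------------
# Huber-type robust variant
# ---------------------------------------------------------------------------

def _huber_case_weights(U: np.ndarray, kappa: float, max_iter: int = 100,
                        tol: float = 1e-9) -> np.ndarray:
    """Case weights from Huber-type robust distances.

    Location and scatter of the joint sample U (columns: mediators, outcome,
    covariates; the binary treatment is excluded from the metric) are
    estimated by an iteratively reweighted mean/covariance.  The distance
    cutoff is the chi-square quantile at 1 - kappa, so a fraction ~kappa of
    Gaussian cases would be downweighted; weights are w_i = min(1, c / d_i).
    """
    n, p = U.shape
    if kappa == 0:
        return np.ones(n)
    c = np.sqrt(stats.chi2.ppf(1.0 - kappa, df=p))
    mu = np.median(U, axis=0)
    S = np.cov(U.T, ddof=1) if p > 1 else np.atleast_2d(np.var(U[:, 0], ddof=1))
    w = np.ones(n)
    for _ in range(max_iter):
        Sc = S + 1e-12 * np.eye(p)
        try:
            Sinv = np.linalg.inv(Sc)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("robust scatter became singular") from exc
        diff = U - mu
        d = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", diff, Sinv, diff), 1e-300))
        w_new = np.minimum(1.0, c / d)
        mu_new = (w_new[:, None] * U).sum(axis=0) / w_new.sum()
        diffn = U - mu_new
        S_new = (w_new[:, None] * diffn).T @ diffn / w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        mu, S, w = mu_new, S_new, w_new
    raise RuntimeError(f"Huber reweighting did not converge in {max_iter} iterations")


def _weighted_paths(X, M, Y, cov, w):
    sw = np.sqrt(w)
    n = len(X)
    base = [np.ones(n), X]
    if cov is not None:
        base.extend(cov.T)
    Xm = np.column_stack(base) * sw[:, None]
    Xy = np.column_stack([np.ones(n), X, M] + ([*(cov.T)] if cov is not None else [])) * sw[:, None]
    a = np.array([_ols(Xm, sw * M[:, j])[1] for j in range(M.shape[1])])
    coef_y = _ols(Xy, sw * Y)
    return a, coef_y[2:2 + M.shape[1]], coef_y[1]


def robust_mediation(data: MediationData, kappa: float = 0.05, B: int = 2000,
                     seed: int = 0, use_covariates: bool = False) -> MediationResult:
    """Huber-type robust mediation with percentile bootstrap.

    Extreme cases are downweighted via robust distances over (M, Y[,
    covariates]); both path models are then fit by weighted least squares
    and the weighted ab is bootstrapped (weights recomputed within each
    resample).  kappa = 0 reproduces the ordinary estimates.  Covariates
    default to excluded from the robust fit, mirroring the covariate-free
    configuration of the originating robust-mediation procedure.
    """
    if not (0 <= kappa < 0.5):
        raise ValueError("kappa must lie in [0, 0.5)")
    cov = data.covariates if use_covariates else None
    U = np.column_stack([data.M, data.Y[:, None]] +
                        ([cov] if cov is not None else []))
    w = _huber_case_weights(U, kappa)
    a, b, c_prime = _weighted_paths(data.X, data.M, data.Y, cov, w)

    rng = np.random.default_rng(seed)
    n, m = data.n, data.n_mediators
    ab_draws = np.empty((B, m))
    redrawn = 0
    for bi in range(B):
        while True:
            rows = rng.integers(0, n, n)
            if data.X[rows].min() == data.X[rows].max():
                redrawn += 1
                continue
            try:
                wb = _huber_case_weights(U[rows], kappa)
                ab_, bb_, _ = _weighted_paths(data.X[rows], data.M[rows], data.Y[rows],
                                              cov[rows] if cov is not None else None, wb)
            except (RuntimeError, np.linalg.LinAlgError):
                redrawn += 1
                continue
            break
        ab_draws[bi] = ab_ * bb_
    ci = np.percentile(ab_draws, [2.5, 97.5], axis=0).T
    return MediationResult(a=a, b=b, c_prime=float(c_prime), ab=a * b,
                           ci95=ci, se_boot=ab_draws.std(axis=0, ddof=1),
                           ab_ps=a * b / data.Y.std(ddof=1), B=B, seed=seed,
                           n_redrawn=redrawn)


def spearman(x, y) -> tuple:
    """Spearman rank correlation with two-sided p via the t approximation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need paired vectors of length >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
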