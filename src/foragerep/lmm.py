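"""Fast random-intercept linear mixed model (one grouping factor).

The repeatability machinery needs thousands of refits (permutation
tests, parametric bootstrap, recovery simulations), so the model

    y = X beta + alpha_g + eps,   alpha_g ~ N(0, sa2),  eps ~ N(0, se2)

is fitted with a profiled 1-D optimization: for a given variance ratio
lambda = sa2/se2 the GLS estimate of beta and the profiled se2 are closed
form via the Sherman-Morrison structure of the per-group covariance
(I + lambda * J)^-1 = I - lambda/(1 + lambda n_g) * J, so each REML/ML
evaluation is O(n).  scipy's bounded scalar minimizer searches log
lambda.  Estimates agree with statsmodels MixedLM / lme4 to optimizer
tolerance; the balanced-design ANOVA estimator is the exact closed form
the tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_LOG_LAM_LO, _LOG_LAM_HI = -30.0, 15.0


@dataclass
class LMMFit:
    """Fitted random-intercept model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_alpha2: float      # between-group variance
    sigma_eps2: float        # residual variance
    loglik: float            # REML or ML log-likelihood, per `reml`
    reml: bool
    n: int
    p: int                   # number of fixed-effect columns

    @property
    def repeatability(self) -> float:
        tot = self.sigma_alpha2 + self.sigma_eps2
        return self.sigma_alpha2 / tot if tot > 0 else 0.0

    @property
    def k_params(self) -> int:
        """Fixed effects + two variance components."""
        return self.p + 2

    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    def aicc(self) -> float:
        """AICc = -2logL + 2k + 2k(k+1)/(n-k-1)."""
        k, n = self.k_params, self.n
        if n - k - 1 <= 0:
            return np.inf
        return self.aic() + 2.0 * k * (k + 1) / (n - k - 1)


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, _ = _factorize(np.asarray(groups))
    return codes, codes.max() + 1


def _factorize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, codes = np.unique(values, return_inverse=True)
    return codes, uniq


class _Profiler:
    """Per-lambda profiled criterion with cached per-group layout."""

    def __init__(self, y, X, codes, n_groups):
        self.y = y
        self.X = X
        self.codes = codes
        self.G = n_groups
        self.n, self.p = X.shape
        self.n_g = np.bincount(codes, minlength=n_groups).astype(float)
        # per-group sums of X columns and of y
        self.Sx = np.zeros((n_groups, self.p))
        for j in range(self.p):
            self.Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_groups)
        self.Sy = np.bincount(codes, weights=y, minlength=n_groups)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def solve(self, lam: float):
        w = lam / (1.0 + lam * self.n_g)          # per-group shrinkage
        A = self.XtX - (self.Sx * w[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (w * self.Sy)
        q = self.yty - float(w @ self.Sy ** 2)     # y' Sigma^-1 y (unit scale)
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ b)
        logdet_sigma = float(np.sum(np.log1p(lam * self.n_g)))
        return beta, A, rss, logdet_sigma

    def neg2_reml(self, lam: float) -> float:
        beta, A, rss, logdet = self.solve(lam)
        df = self.n - self.p
        if rss <= 0:
            rss = 1e-300
        sign, logdet_A = np.linalg.slogdet(A)
        s2 = rss / df
        return df * np.log(2.0 * np.pi * s2) + logdet + logdet_A + df

    def neg2_ml(self, lam: float) -> float:
        beta, A, rss, logdet = self.solve(lam)
        if rss <= 0:
            rss = 1e-300
        s2 = rss / self.n
        return self.n * np.log(2.0 * np.pi * s2) + logdet + self.n


def fit_lmm(y, X, groups, reml: bool = True) -> LMMFit:
    """Fit the random-intercept model by profiled REML (default) or ML.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effects design (include the intercept column)
    groups : (n,) group labels (any hashable dtype)
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    codes, G = _group_codes(groups)
    if G < 2:
        raise ValueError("need at least two groups")
    prof = _Profiler(y, X, codes, G)
    crit = prof.neg2_reml if reml else prof.neg2_ml

    def obj(t):
        return crit(np.exp(t))

    res = minimize_scalar(obj, bounds=(_LOG_LAM_LO, _LOG_LAM_HI), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    # boundary check: a pure-residual model can beat the interior optimum
    if crit(0.0) <= res.fun:
        lam = 0.0
    beta, A, rss, _ = prof.solve(lam)
    df = prof.n - prof.p if reml else prof.n
    s2 = max(rss / df, 1e-300)
    sa2 = lam * s2
    cov_beta = s2 * np.linalg.inv(A)
    ll = -0.5 * crit(lam)
    return LMMFit(beta=beta, cov_beta=cov_beta, sigma_alpha2=float(sa2),
                  sigma_eps2=float(s2), loglik=float(ll), reml=reml,
                  n=prof.n, p=prof.p)


def anova_variance_components(y, groups) -> tuple[float, float]:
    """Closed-form one-way ANOVA variance components (balanced designs).

    sigma_eps2 = MS_within; sigma_alpha2 = (MS_between - MS_within) / n0,
    floored at zero.  For balanced data these equal the REML estimates;
    used as an independent oracle in tests.
    """
    y = np.asarray(y, dtype=float)
    codes, G = _group_codes(groups)
    n = y.size
    n_g = np.bincount(codes).astype(float)
    means = np.bincount(codes, weights=y) / n_g
    grand = y.mean()
    ss_within = float(np.sum((y - means[codes]) ** 2))
    ss_between = float(np.sum(n_g * (means - grand) ** 2))
    ms_within = ss_within / (n - G)
    ms_between = ss_between / (G - 1)
    n0 = (n - np.sum(n_g ** 2) / n) / (G - 1)
    sa2 = max((ms_between - ms_within) / n0, 0.0)
    return sa2, ms_within
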