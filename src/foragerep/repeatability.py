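"""Population-level repeatability of foraging behaviour.

Repeatability (the intraclass correlation) is the share of behavioural
variance attributable to differences between individuals:

    R = sa2 / (sa2 + se2)

with sa2 the between-individual (random intercept) variance and se2 the
within-individual (residual) variance from a mixed model with
individual as random intercept.  When morphometric fixed effects are
included (selected by all-subsets AICc), the estimate is an *adjusted*
repeatability: the repeatability for individuals of identical
morphometrics.  The individual-level repeatability is R' = 1 - R.

Gaussian behaviours use a linear mixed model (REML); significance comes
from a permutation test over individual labels and uncertainty from a
parametric bootstrap.  Proportion behaviours (benthic / daylight diving)
use a logit-link binomial formulation with an observation-level random
effect (OLRE) for overdispersion; on the link scale

    R = sa2 / (sa2 + s_olre2 + pi^2 / 3)

where pi^2/3 is the logistic distribution-specific variance.  No
bootstrap CI is produced for proportion behaviours.

The module is organised statsmodels-style: build a
:class:`RepeatabilityModel` from a trip-level behaviour table, call
``fit()``, and read estimates off the returned
:class:`RepeatabilityResults` (or print ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lmm import LMMFit, fit_lmm

LOGISTIC_VARIANCE = np.pi ** 2 / 3.0

#: behaviours cube-root transformed before Gaussian modelling
CUBE_ROOT_BEHAVIORS = ("total_distance_km", "duration_h", "dive_rate")

#: covariates dropped first when a collinear pair must lose a member
COLLINEARITY_DROP_PRIORITY = ("mass_kg", "standard_length_cm")

BANDS = ((0.25, "low"), (0.5, "considerable"), (0.75, "moderate"), (1.0, "high"))


def _ms_ratio(y: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Between/within mean-square ratio (one-way ANOVA F)."""
    n = y.size
    n_g = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.bincount(codes, weights=y, minlength=n_groups)
    means = sums / np.maximum(n_g, 1.0)
    grand = y.mean()
    ssb = float(np.sum(n_g * (means - grand) ** 2))
    ssw = float(np.sum(y ** 2) - np.sum(n_g * means ** 2))
    msw = ssw / max(n - n_groups, 1)
    msb = ssb / max(n_groups - 1, 1)
    return msb / msw if msw > 0 else np.inf


def classify_band(r: float) -> str:
    """Verbal repeatability band; boundary values go to the lower band."""
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"repeatability {r} outside [0, 1]")
    for upper, name in BANDS:
        if r <= upper:
            return name
    return "high"


def screen_collinearity(covariates: pd.DataFrame,
                        threshold: float = 0.7,
                        drop_priority: Sequence[str] = COLLINEARITY_DROP_PRIORITY,
                        ) -> list[str]:
    """Drop one member of every covariate pair with |Pearson r| > threshold.

    Pairs are handled from strongest correlation down.  Within a pair the
    member named earlier in ``drop_priority`` is dropped; if neither is
    listed, the later column is dropped.  Returns the retained columns.
    """
    cols = list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("need at least two covariates to screen")
    for c in cols:
        if covariates[c].std() == 0:
            raise ValueError(f"constant covariate {c!r}")
    corr = covariates.corr().abs()
    pairs = sorted(((corr.loc[a, b], a, b) for a, b in combinations(cols, 2)),
                   reverse=True)
    retained = set(cols)
    for r, a, b in pairs:
        if r <= threshold or a not in retained or b not in retained:
            continue
        prio = {name: i for i, name in enumerate(drop_priority)}
        if a in prio or b in prio:
            drop = a if prio.get(a, 99) <= prio.get(b, 99) else b
        else:
            drop = b
        retained.discard(drop)
    return [c for c in cols if c in retained]


@dataclass
class SubsetFit:
    covariates: tuple
    aicc: float
    loglik: float
    k: int


def _design(data: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(data))] +
                        [data[c].to_numpy(dtype=float) for c in covariates])
    return X


def select_fixed_effects(data: pd.DataFrame, response: str,
                         covariates: Sequence[str], groups: str = "individual_id",
                         delta_threshold: float = 4.0,
                         ) -> tuple[list[str], list[SubsetFit]]:
    """All-subsets ("dredge") fixed-effect selection by AICc.

    Every subset of ``covariates`` is fitted by maximum likelihood with
    an individual random intercept and ranked by AICc.  Among models
    within ``delta_threshold`` of the best AICc the most parsimonious
    (fewest parameters; ties broken by AICc) is selected.  Refit the
    winner with REML for reported estimates.
    """
    y = data[response].to_numpy(dtype=float)
    g = data[groups].to_numpy()
    table: list[SubsetFit] = []
    for k in range(len(covariates) + 1):
        for subset in combinations(covariates, k):
            X = _design(data, subset)
            try:
                fit = fit_lmm(y, X, g, reml=False)
            except (np.linalg.LinAlgError, ValueError):
                continue  # non-convergent / singular subset excluded
            table.append(SubsetFit(subset, fit.aicc(), fit.loglik, fit.k_params))
    if not table:
        raise RuntimeError("no candidate model converged")
    best_aicc = min(f.aicc for f in table)
    contenders = [f for f in table if f.aicc - best_aicc < delta_threshold]
    winner = min(contenders, key=lambda f: (f.k, f.aicc))
    return list(winner.covariates), sorted(table, key=lambda f: f.aicc)


@dataclass
class RepeatabilityResults:
    """Estimates for one behaviour. ``r_individual`` is 1 - r exactly."""

    behavior: str
    kind: str                       # "gaussian" | "proportion"
    covariates: tuple
    sigma_alpha2: float
    sigma_eps2: float               # residual (gaussian) or OLRE (proportion)
    r: float
    adjusted: bool
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_perm: Optional[float]
    band: str
    n_obs: int
    n_individuals: int
    fit: LMMFit = field(repr=False, default=None)
    link_variance: Optional[float] = None   # pi^2/3 for logit models

    @property
    def r_individual(self) -> float:
        return 1.0 - self.r

    def summary(self) -> str:
        lines = [
            f"Repeatability of {self.behavior} ({self.kind})",
            "=" * 50,
            f"n = {self.n_obs} trips, {self.n_individuals} individuals",
            f"fixed effects: {', '.join(self.covariates) or '(intercept only)'}"
            + ("  [adjusted R]" if self.adjusted else ""),
            f"sigma_alpha^2 (between) = {self.sigma_alpha2:.4f}",
            f"sigma_eps^2 ({'OLRE' if self.kind == 'proportion' else 'residual'})"
            f" = {self.sigma_eps2:.4f}",
        ]
        if self.link_variance is not None:
            lines.append(f"link variance (pi^2/3)  = {self.link_variance:.4f}")
        lines.append(f"R  = {self.r:.3f}  [{self.band}]")
        if self.ci_low is not None:
            lines.append(f"95% bootstrap CI: [{self.ci_low:.3f}, {self.ci_high:.3f}]")
        if self.p_perm is not None:
            lines.append(f"permutation p = {self.p_perm:.4f}")
        lines.append(f"R' (individual level) = {self.r_individual:.3f}")
        return "\n".join(lines)


class RepeatabilityModel:
    """Mixed-model repeatability of one behaviour across foraging trips.

    Parameters
    ----------
    data : trip-level table (one row per trip).
    response : behaviour column.  For ``kind="proportion"`` this is the
        proportion in [0, 1] and ``denominator`` names the per-trip count
        of trials (dives).
    groups : individual identifier column.
    covariates : candidate fixed effects (individual-level morphometrics);
        the fitted set after AICc selection may be smaller.
    kind : "gaussian" or "proportion".
    transform : optional callable applied to the response (e.g. cube root).
    select : run all-subsets AICc selection (otherwise use ``covariates``
        as given).
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 groups: str = "individual_id",
                 covariates: Sequence[str] = (),
                 kind: str = "gaussian",
                 denominator: Optional[str] = None,
                 transform=None, select: bool = True):
        if kind not in ("gaussian", "proportion"):
            raise ValueError(f"unknown kind {kind!r}")
        if kind == "proportion" and denominator is None:
            raise ValueError("proportion models need a denominator column")
        self.data = data.reset_index(drop=True)
        self.response = response
        self.groups = groups
        self.covariates = list(covariates)
        self.kind = kind
        self.denominator = denominator
        self.transform = transform
        self.select = select
        if self.data[groups].nunique() < 2:
            raise ValueError("need at least two individuals")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, **kw):
        return cls(data, response, **kw)

    # -- response construction -------------------------------------------
    def _gaussian_response(self) -> np.ndarray:
        y = self.data[self.response].to_numpy(dtype=float)
        return self.transform(y) if self.transform else y

    def _logit_response(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical logit and its per-observation binomial sampling
        variance on the link scale."""
        p = self.data[self.response].to_numpy(dtype=float)
        n = self.data[self.denominator].to_numpy(dtype=float)
        if np.all((p <= 0) | (p >= 1)):
            raise ValueError("all proportions are 0 or 1; logit model degenerate")
        k = p * n
        y = np.log((k + 0.5) / (n - k + 0.5))
        p_tilde = (k + 0.5) / (n + 1.0)
        v_binom = 1.0 / (n * p_tilde * (1.0 - p_tilde))
        return y, v_binom

    # -- fitting ----------------------------------------------------------
    def fit(self, n_permutations: int = 1000, n_bootstrap: int = 1000,
            seed: Optional[int] = None) -> RepeatabilityResults:
        rng = np.random.default_rng(seed)
        if self.kind == "gaussian":
            y = self._gaussian_response()
            v_binom = None
        else:
            y, v_binom = self._logit_response()
        work = self.data.copy()
        work["_y"] = y
        g = work[self.groups].to_numpy()

        if self.select and self.covariates:
            chosen, _ = select_fixed_effects(work, "_y", self.covariates, self.groups)
        else:
            chosen = list(self.covariates)
        X = _design(work, chosen)
        fit = fit_lmm(y, X, g, reml=True)

        if self.kind == "gaussian":
            r = fit.repeatability
            p_perm = self._permutation_p(y, X, g, r, n_permutations, rng) \
                if n_permutations else None
            ci = self._bootstrap_ci(fit, X, g, n_bootstrap, rng) if n_bootstrap else None
            sigma_eps2 = fit.sigma_eps2
            link_var = None
        else:
            # residual on the logit scale = OLRE + binomial sampling noise;
            # subtract the estimated sampling part, floor at zero
            s_olre2 = max(fit.sigma_eps2 - float(np.mean(v_binom)), 0.0)
            r = fit.sigma_alpha2 / (fit.sigma_alpha2 + s_olre2 + LOGISTIC_VARIANCE)
            sigma_eps2 = s_olre2
            p_perm = None
            ci = None
            link_var = LOGISTIC_VARIANCE

        return RepeatabilityResults(
            behavior=self.response, kind=self.kind, covariates=tuple(chosen),
            sigma_alpha2=fit.sigma_alpha2, sigma_eps2=sigma_eps2, r=float(r),
            adjusted=bool(chosen),
            ci_low=None if ci is None else ci[0],
            ci_high=None if ci is None else ci[1],
            p_perm=p_perm, band=classify_band(float(np.clip(r, 0.0, 1.0))),
            n_obs=len(work), n_individuals=work[self.groups].nunique(),
            fit=fit, link_variance=link_var,
        )

    def _permutation_p(self, y, X, g, r_obs, n_perm, rng) -> float:
        """Permutation test of R > 0: individual labels are permuted
        across rows and the fraction of permuted statistics at or above
        the observed one is reported (with the +1 correction).

        The permuted statistic is the between/within mean-square ratio of
        the fixed-effect residuals — a strictly monotone transform of the
        (unconstrained) repeatability estimate.  Using it instead of the
        boundary-floored REML R keeps the statistic continuous, so null
        p-values are uniform rather than piling up at the R = 0 atom.
        """
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        codes = pd.factorize(g)[0]
        n_groups = codes.max() + 1
        f_obs = _ms_ratio(resid, codes, n_groups)
        count = 0
        perm = codes.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            if _ms_ratio(resid, perm, n_groups) >= f_obs:
                count += 1
        return (count + 1) / (n_perm + 1)

    def _bootstrap_ci(self, fit: LMMFit, X, g, n_boot, rng,
                      level: float = 0.95) -> tuple[float, float]:
        """Parametric bootstrap percentile CI for R: simulate from the
        fitted variance components, refit, take percentiles."""
        codes, uniq = np.unique(g, return_inverse=True)[1], np.unique(g)
        G = uniq.size
        mu = X @ fit.beta
        sa = np.sqrt(fit.sigma_alpha2)
        se = np.sqrt(fit.sigma_eps2)
        r_stars = np.empty(n_boot)
        for b in range(n_boot):
            alpha = rng.normal(0.0, sa, G)
            y_star = mu + alpha[codes] + rng.normal(0.0, se, len(mu))
            r_stars[b] = fit_lmm(y_star, X, g, reml=True).repeatability
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(r_stars, [a, 1.0 - a])
        return float(lo), float(hi)


def repeatability_gaussian(data: pd.DataFrame, response: str,
                           covariates: Sequence[str] = (),
                           groups: str = "individual_id",
                           transform=None, n_permutations: int = 1000,
                           n_bootstrap: int = 1000, seed=None,
                           select: bool = True) -> RepeatabilityResults:
    """Gaussian repeatability with AICc-selected morphometric fixed effects."""
    return RepeatabilityModel(data, response, groups=groups, covariates=covariates,
                              kind="gaussian", transform=transform, select=select
                              ).fit(n_permutations, n_bootstrap, seed)


def repeatability_proportion(data: pd.DataFrame, response: str, denominator: str,
                             covariates: Sequence[str] = (),
                             groups: str = "individual_id", seed=None,
                             select: bool = True) -> RepeatabilityResults:
    """Logit-link proportion repeatability (no CI, per the method)."""
    return RepeatabilityModel(data, response, groups=groups, covariates=covariates,
                              kind="proportion", denominator=denominator,
                              select=select).fit(0, 0, seed)
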