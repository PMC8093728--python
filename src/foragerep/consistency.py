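"""Individual-level behavioural consistency and its link to foraging
success/efficiency.

Per individual, consistency in each behaviour across trips is the
coefficient of variation CV = sd / mean (smaller = more consistent);
bearing, being circular, is summarised instead by the circular standard
deviation sqrt(-2 ln Rbar) with Rbar the mean resultant length of the
trip bearings.  Four linear models then relate the per-individual
consistency profile (behaviour CVs, bearing circular SD, foraging site
fidelity) to the mean and CV of the trip success (FTSI) and efficiency
(FTEI) indices, with the same all-subsets AICc selection used for the
repeatability fixed effects.  The CVs of total and horizontal distance
are excluded a priori (collinear with trip-duration CV).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


#: predictors offered to the consistency models
CONSISTENCY_PREDICTORS = (
    "cv_duration_h", "cv_max_range_km", "cv_modal_depth", "cv_dive_rate",
    "cv_prop_benthic", "cv_prop_daylight", "bearing_circ_sd", "fsfi",
)

CONSISTENCY_RESPONSES = ("mean_ftsi", "mean_ftei", "cv_ftsi", "cv_ftei")

#: behaviours summarised by CV in the per-individual profile
CV_BEHAVIORS = ("duration_h", "max_range_km", "modal_depth", "dive_rate",
                "prop_benthic", "prop_daylight", "total_distance_km",
                "horizontal_distance_km")


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation sd/mean (sample sd); NaN when mean == 0."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def circular_sd_deg(bearings_deg: Sequence[float]) -> float:
    """Circular standard deviation of bearings, in degrees.

    sqrt(-2 ln Rbar) where Rbar is the mean resultant length; 0 when all
    bearings coincide.
    """
    a = np.radians(np.asarray(bearings_deg, dtype=float))
    rbar = float(np.hypot(np.mean(np.cos(a)), np.mean(np.sin(a))))
    rbar = min(rbar, 1.0)
    if rbar <= 0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def consistency_profile(trips: pd.DataFrame, fsfi_value: float,
                        individual_id: Optional[str] = None) -> dict:
    """Per-individual consistency profile from that individual's trips.

    ``trips`` holds one row per trip with the behaviour columns plus
    ``bearing_distal``, ``ftsi`` and ``ftei``.  Requires >= 3 trips.
    """
    if len(trips) < 3:
        raise ValueError("consistency profile needs >= 3 trips")
    prof = {"individual_id": individual_id if individual_id is not None
            else trips["individual_id"].iloc[0],
            "n_trips": len(trips), "fsfi": float(fsfi_value)}
    for col in CV_BEHAVIORS:
        if col in trips:
            prof[f"cv_{col}"] = cv(trips[col])
    prof["bearing_circ_sd"] = circular_sd_deg(trips["bearing_distal"])
    prof["mean_ftsi"] = float(trips["ftsi"].mean())
    prof["mean_ftei"] = float(trips["ftei"].mean())
    prof["cv_ftsi"] = cv(trips["ftsi"])
    prof["cv_ftei"] = cv(trips["ftei"])
    return prof


@dataclass
class ModelReport:
    """One fitted consistency model, mirroring the reporting layout:
    formula, df, AIC, likelihood ratio vs the null, p, r^2 and the
    per-covariate estimate table."""

    response: str
    formula: str
    predictors: tuple
    df_model: int
    aic: float
    loglik: float
    lratio: Optional[float]
    p_lratio: Optional[float]
    r2: float
    coef: pd.DataFrame  # index = covariate; est, se, t, ci_low, ci_high

    def summary(self) -> str:
        lines = [f"{self.response}: {self.formula}",
                 f"  df={self.df_model}  AIC={self.aic:.2f}  logLik={self.loglik:.2f}"
                 f"  r2={self.r2:.3f}"]
        if self.lratio is not None:
            lines.append(f"  L-ratio={self.lratio:.2f}  p={self.p_lratio:.4g}")
        with pd.option_context("display.float_format", "{:.3f}".format):
            lines.append(self.coef.to_string())
        return "\n".join(lines)


def _ols_aicc(res) -> float:
    k = res.df_model + 2  # coefficients incl. intercept + residual variance
    n = res.nobs
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * res.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class ConsistencyLM:
    """All-subsets linear model of one success/efficiency response on the
    consistency profile; statsmodels OLS underneath."""

    def __init__(self, profiles: pd.DataFrame, response: str,
                 predictors: Sequence[str] = CONSISTENCY_PREDICTORS,
                 delta_threshold: float = 4.0, max_predictors: Optional[int] = None):
        cols = [response] + [p for p in predictors if p in profiles.columns]
        data = profiles[cols].dropna()
        if len(data) < 10:
            raise ValueError("need >= 10 complete profiles")
        self.data = data
        self.response = response
        self.predictors = tuple(p for p in predictors if p in profiles.columns)
        self.delta = delta_threshold
        self.max_predictors = max_predictors

    def fit(self) -> ModelReport:
        y = self.data[self.response].to_numpy(dtype=float)
        n = len(y)
        max_k = self.max_predictors if self.max_predictors is not None \
            else min(len(self.predictors), n - 4)
        fits = []
        for k in range(max_k + 1):
            for subset in combinations(self.predictors, k):
                X = sm.add_constant(self.data[list(subset)].to_numpy(dtype=float)) \
                    if subset else np.ones((n, 1))
                res = sm.OLS(y, X).fit()
                aicc = _ols_aicc(res)
                fits.append((subset, aicc, res))
        best_aicc = min(f[1] for f in fits)
        contenders = [f for f in fits if f[1] - best_aicc < self.delta]
        subset, _, res = min(contenders, key=lambda f: (len(f[0]), f[1]))
        null_res = next(r for s, _, r in fits if s == ())
        if subset:
            lr = 2.0 * (res.llf - null_res.llf)
            p_lr = float(stats.chi2.sf(lr, df=len(subset)))
        else:
            lr = p_lr = None
        names = ["(Intercept)"] + list(subset)
        ci = res.conf_int()
        coef = pd.DataFrame({
            "est": res.params, "se": res.bse, "t": res.tvalues,
            "ci_low": ci[:, 0], "ci_high": ci[:, 1]}, index=names)
        formula = f"{self.response} ~ " + (" + ".join(subset) if subset else "1")
        return ModelReport(
            response=self.response, formula=formula, predictors=subset,
            df_model=int(res.df_model) + 2, aic=float(res.aic),
            loglik=float(res.llf), lratio=lr, p_lratio=p_lr,
            r2=float(res.rsquared) if subset else 0.0, coef=coef,
        )


def fit_consistency_models(profiles: pd.DataFrame,
                           predictors: Sequence[str] = CONSISTENCY_PREDICTORS,
                           responses: Sequence[str] = CONSISTENCY_RESPONSES,
                           ) -> dict[str, ModelReport]:
    """Fit the four consistency models (FTSI, FTEI and their CVs)."""
    return {resp: ConsistencyLM(profiles, resp, predictors).fit()
            for resp in responses}
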