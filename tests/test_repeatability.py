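"""Repeatability estimation: collinearity screen, AICc dredge, Gaussian
and proportion repeatability, bands."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from foragerep.repeatability import (LOGISTIC_VARIANCE, classify_band, repeatability_gaussian,
                                     repeatability_proportion,
                                     screen_collinearity, select_fixed_effects)


def gaussian_table(rng, n_ind=30, n_trips=6, sa=1.0, se=1.0, beta_girth=0.0):
    g = np.repeat(np.arange(n_ind), n_trips)
    girth = rng.normal(99.2, 4.5, n_ind)
    flip = rng.normal(42.5, 1.8, n_ind)
    axis = rng.normal(63.2, 2.8, n_ind)
    y = beta_girth * (girth[g] - girth.mean()) / girth.std() + \
        rng.normal(0, sa, n_ind)[g] + rng.normal(0, se, g.size)
    return pd.DataFrame({
        "individual_id": [f"F{i:02d}" for i in g], "y": y,
        "axillary_girth_cm": girth[g], "flipper_length_cm": flip[g],
        "axis_length_cm": axis[g]})


class TestCollinearityScreen:
    def _morph(self, rng, rho=0.0):
        n = 40
        z = rng.normal(0, 1, n)
        mass = 70 + 8 * (rho * z + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n))
        girth = 99 + 4.5 * z
        flip = rng.normal(42.5, 1.8, n)
        return pd.DataFrame({"mass_kg": mass, "axillary_girth_cm": girth,
                             "flipper_length_cm": flip})

    def test_perfectly_correlated_pair_loses_one(self):
        rng = np.random.default_rng(1)
        df = self._morph(rng)
        df["mass2"] = 2.0 * df["mass_kg"] + 1.0
        kept = screen_collinearity(df)
        assert ("mass_kg" in kept) != ("mass2" in kept)

    def test_orthogonal_columns_all_retained(self):
        rng = np.random.default_rng(2)
        kept = screen_collinearity(self._morph(rng, rho=0.0))
        assert set(kept) == {"mass_kg", "axillary_girth_cm", "flipper_length_cm"}

    def test_mass_dropped_first_when_correlated_with_girth(self):
        # correlation built by construction (Cholesky-style mixing)
        rng = np.random.default_rng(3)
        kept = screen_collinearity(self._morph(rng, rho=0.85))
        assert "mass_kg" not in kept
        assert "axillary_girth_cm" in kept

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError):
            screen_collinearity(df)


COVARS = ["axillary_girth_cm", "flipper_length_cm", "axis_length_cm"]


class TestFixedEffectSelection:
    def test_null_prefers_intercept_only(self):
        rng = np.random.default_rng(4)
        wins = 0
        for _ in range(50):
            df = gaussian_table(rng, n_ind=25, n_trips=5)
            chosen, _ = select_fixed_effects(df, "y", COVARS)
            wins += chosen == []
        assert wins >= 40  # >= 80% of replicates

    def test_strong_girth_effect_retained(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(30):
            df = gaussian_table(rng, n_ind=50, n_trips=4, beta_girth=0.8)
            chosen, _ = select_fixed_effects(df, "y", COVARS)
            hits += "axillary_girth_cm" in chosen
        assert hits >= 27  # >= 90%

    def test_ranking_table_sorted_by_aicc(self):
        rng = np.random.default_rng(6)
        df = gaussian_table(rng)
        _, table = select_fixed_effects(df, "y", COVARS)
        aiccs = [f.aicc for f in table]
        assert aiccs == sorted(aiccs)
        assert len(table) == 8  # all subsets of three covariates


class TestGaussianRepeatability:
    def test_equal_components_give_half(self):
        rng = np.random.default_rng(7)
        df = gaussian_table(rng, n_ind=60, n_trips=8, sa=1.0, se=1.0)
        res = repeatability_gaussian(df, "y", n_permutations=0, n_bootstrap=0)
        assert res.r == pytest.approx(0.5, abs=0.08)
        assert res.r == pytest.approx(
            res.sigma_alpha2 / (res.sigma_alpha2 + res.sigma_eps2))

    def test_complement_identity_exact(self):
        rng = np.random.default_rng(8)
        df = gaussian_table(rng)
        res = repeatability_gaussian(df, "y", n_permutations=0, n_bootstrap=0)
        assert res.r + res.r_individual == 1.0

    def test_null_gives_low_r_and_high_p(self):
        rng = np.random.default_rng(9)
        good = 0
        for i in range(20):
            df = gaussian_table(rng, n_ind=20, n_trips=5, sa=0.0, se=1.0)
            res = repeatability_gaussian(df, "y", n_permutations=99,
                                         n_bootstrap=0, seed=i)
            good += (res.r < 0.15) and (res.p_perm > 0.05)
        assert good >= 18  # >= 90% of replicates

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(10)
        df = gaussian_table(rng)
        r1 = repeatability_gaussian(df, "y", n_permutations=0, n_bootstrap=0).r
        df2 = df.copy()
        df2["y"] = df2["y"] + 1000.0
        r2 = repeatability_gaussian(df2, "y", n_permutations=0, n_bootstrap=0).r
        assert r1 == pytest.approx(r2, abs=1e-5)

    def test_adjusted_r_invariant_to_covariate_recentering(self):
        rng = np.random.default_rng(11)
        df = gaussian_table(rng, beta_girth=1.0)
        kw = dict(covariates=COVARS, n_permutations=0, n_bootstrap=0, select=False)
        r1 = repeatability_gaussian(df, "y", **kw).r
        df2 = df.copy()
        for c in COVARS:
            df2[c] = df2[c] - df2[c].mean()
        r2 = repeatability_gaussian(df2, "y", **kw).r
        assert r1 == pytest.approx(r2, abs=1e-5)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(12)
        df = gaussian_table(rng, n_ind=30, n_trips=6, sa=1.0, se=1.0)
        res = repeatability_gaussian(df, "y", n_permutations=0, n_bootstrap=200,
                                     seed=0)
        assert res.ci_low <= res.r <= res.ci_high


def proportion_table(rng, n_ind=40, n_trips=6, sa2=1.0, s_olre2=0.3,
                     n_dives=300, mu=1.1):
    g = np.repeat(np.arange(n_ind), n_trips)
    eta = mu + rng.normal(0, np.sqrt(sa2), n_ind)[g] + \
        rng.normal(0, np.sqrt(s_olre2), g.size)
    k = rng.binomial(n_dives, expit(eta))
    return pd.DataFrame({"individual_id": [f"F{i:02d}" for i in g],
                         "prop": k / n_dives,
                         "n_dives": np.full(g.size, n_dives)})


class TestProportionRepeatability:
    def test_link_variance_is_logistic_constant(self):
        rng = np.random.default_rng(13)
        res = repeatability_proportion(proportion_table(rng), "prop", "n_dives")
        assert res.link_variance == pytest.approx(np.pi ** 2 / 3, abs=1e-9)
        assert res.link_variance == pytest.approx(3.28987, abs=1e-5)
        assert LOGISTIC_VARIANCE == pytest.approx(3.28987, abs=1e-5)

    def test_zero_between_variance_gives_zero_r(self):
        rng = np.random.default_rng(14)
        df = proportion_table(rng, sa2=0.0)
        res = repeatability_proportion(df, "prop", "n_dives")
        assert res.r < 0.05

    def test_no_ci_reported(self):
        rng = np.random.default_rng(15)
        res = repeatability_proportion(proportion_table(rng), "prop", "n_dives")
        assert res.ci_low is None and res.ci_high is None

    def test_degenerate_all_extreme_proportions_rejected(self):
        df = pd.DataFrame({"individual_id": ["a"] * 3 + ["b"] * 3,
                           "prop": [0, 0, 1, 1, 0, 1],
                           "n_dives": [10] * 6})
        with pytest.raises(ValueError):
            repeatability_proportion(df, "prop", "n_dives")


class TestBands:
    @pytest.mark.parametrize("r,band", [
        (0.1, "low"), (0.25, "low"), (0.3, "considerable"), (0.5, "considerable"),
        (0.6, "moderate"), (0.75, "moderate"), (0.9, "high"), (1.0, "high"),
        (0.0, "low"),
    ])
    def test_band_assignment(self, r, band):
        assert classify_band(r) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_band(1.2)

    def test_summary_mentions_band(self):
        rng = np.random.default_rng(16)
        df = gaussian_table(rng)
        res = repeatability_gaussian(df, "y", n_permutations=0, n_bootstrap=0)
        assert res.band in res.summary()
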