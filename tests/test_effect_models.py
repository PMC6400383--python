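import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from teamskill.effect_models import (
    EffectFit,
    MIXED_TERMS,
    cross_section_table,
    fit_cross_section,
    fit_mixed,
    mixed_model_table,
    normalize_estimates,
    tob_reversal_threshold,
    vif,
)


def linear_table(n, b0, b1, b2, b3, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    L = rng.uniform(0, 1, n)
    T = rng.uniform(0, 1, n)
    skill = b0 + b1 * L + b2 * T + b3 * L * T + rng.normal(0, noise_sd, n)
    return pd.DataFrame(
        {
            "player_id": [f"p{i}" for i in range(n)],
            "skill": skill,
            "loyalty": L,
            "tob": T,
            "faithfulness": L * T,
        }
    )


def effect_fit(b1, b2, b3, b0=28.0):
    est = {"intercept": b0, "loyalty": b1, "tob": b2, "faithfulness": b3}
    return EffectFit(
        terms=tuple(est), estimates=est, std_errors={}, t_values={},
        p_values={}, vif={}, n=0,
    )


class TestCrossSection:
    def test_zero_noise_interpolation(self):
        fit = fit_cross_section(linear_table(300, 28.0, 1.0, -1.0, 4.0))
        assert fit.estimates["intercept"] == pytest.approx(28.0, abs=1e-8)
        assert fit.estimates["loyalty"] == pytest.approx(1.0, abs=1e-8)
        assert fit.estimates["tob"] == pytest.approx(-1.0, abs=1e-8)
        assert fit.estimates["faithfulness"] == pytest.approx(4.0, abs=1e-8)

    def test_null_response_has_no_large_t(self):
        # under a pure-noise response each |t| should essentially never
        # approach 4 (per-term tail probability ~6e-5)
        for seed in range(25):
            tab = linear_table(500, 0, 0, 0, 0, noise_sd=1.0, seed=seed)
            tab["skill"] = np.random.default_rng(1000 + seed).normal(0, 1, 500)
            fit = fit_cross_section(tab)
            assert all(
                abs(t) < 4 for k, t in fit.t_values.items() if k != "intercept"
            )

    def test_duplicated_covariate_names_collinear_column(self):
        tab = linear_table(100, 28, 1, -1, 4)
        tab["faithfulness"] = tab["tob"]
        with pytest.raises(ValueError, match="collinear"):
            fit_cross_section(tab)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            fit_cross_section(linear_table(4, 28, 1, -1, 4))


class TestVif:
    def test_orthogonal_design_is_unity(self):
        # mutually orthogonal +/-1 contrasts
        L = np.tile([1, 1, -1, -1], 25)
        T = np.tile([1, -1, 1, -1], 25)
        tab = pd.DataFrame(
            {"skill": 0.0, "loyalty": L, "tob": T, "faithfulness": L * T}
        )
        assert vif(tab) == pytest.approx({"loyalty": 1.0, "tob": 1.0, "faithfulness": 1.0})

    def test_near_duplicate_blows_up(self):
        rng = np.random.default_rng(0)
        L = rng.uniform(0, 1, 500)
        tab = pd.DataFrame(
            {
                "skill": 0.0,
                "loyalty": L,
                "tob": L + rng.normal(0, 1e-3, 500),
                "faithfulness": rng.uniform(0, 1, 500),
            }
        )
        assert vif(tab)["loyalty"] > 10

    def test_known_correlation_closed_form(self):
        # corr(loyalty, tob) = 0.6 with an independent third covariate:
        # VIF ~ 1/(1-0.36) = 1.5625
        rng = np.random.default_rng(3)
        n = 100_000
        z = rng.normal(size=n)
        L = 0.6 * z + math.sqrt(1 - 0.36) * rng.normal(size=n)
        tab = pd.DataFrame(
            {"skill": 0.0, "loyalty": L, "tob": z, "faithfulness": rng.normal(size=n)}
        )
        assert vif(tab)["loyalty"] == pytest.approx(1.5625, abs=0.02)


class TestReversalThreshold:
    def test_published_coefficients_give_027(self):
        thr = tob_reversal_threshold(effect_fit(0.7594, -1.0042, 3.7077))
        assert thr == pytest.approx(0.2709, abs=1e-4)
        assert round(thr, 2) == 0.27

    def test_simple_ratio(self):
        assert tob_reversal_threshold(effect_fit(0, -1, 2)) == pytest.approx(0.5)

    def test_no_reversal_in_unit_interval(self):
        thr = tob_reversal_threshold(effect_fit(0, 1, 2))
        assert thr == pytest.approx(-0.5)
        assert not 0 <= thr <= 1

    def test_zero_interaction_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            tob_reversal_threshold(effect_fit(1, -1, 0))

    @given(k=st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, k):
        a = tob_reversal_threshold(effect_fit(0.76, -1.0, 3.7))
        b = tob_reversal_threshold(effect_fit(0.76 * k, -1.0 * k, 3.7 * k))
        assert a == pytest.approx(b, rel=1e-9)


class TestNormalization:
    def test_published_table_values(self):
        # back-transform of the printed log10 estimates, rounded to 2 dp
        est = {
            "intercept": 1.415, "exp": 0.016, "loyal": -0.007, "tob": -0.044,
            "loyal:tob": 0.090, "exp:tob": 0.016, "exp:loyal": 0.004,
            "exp:loyal:tob": -0.026,
        }
        norm = {k: round(v, 2) for k, v in normalize_estimates(est).items()}
        assert norm["intercept"] == 26.00
        assert norm["exp"] == 0.98
        assert norm["loyal"] == -0.42
        assert norm["tob"] == -2.51
        assert norm["loyal:tob"] == 5.99
        assert norm["exp:loyal:tob"] == -1.51

    def test_zero_term_normalizes_to_zero(self):
        assert normalize_estimates({"intercept": 1.415, "exp": 0.0})["exp"] == 0.0

    @given(
        I=st.floats(0.5, 2.0),
        c=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, I, c):
        norm = normalize_estimates({"intercept": I, "term": c})["term"]
        assert math.log10(norm + 10**I) - I == pytest.approx(c, abs=1e-12)


def direct_mixed_table(seed, n_players=120, n_games=120, re_sd=0.045, noise_sd=0.02,
                       truth=None):
    """Long table generated directly from the longitudinal model structure."""
    if truth is None:
        truth = {
            "intercept": 1.415, "exp": 0.016, "loyal": 0.05, "tob": -0.044,
            "loyal:tob": 0.090, "exp:tob": 0.016, "exp:loyal": 0.004,
            "exp:loyal:tob": -0.026,
        }
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_players):
        L, T = rng.beta(0.5, 0.5), rng.beta(0.5, 0.5)
        u = rng.normal(0, re_sd)
        le = np.log10(np.arange(10, n_games + 1))
        y = (
            truth["intercept"] + u + truth["loyal"] * L + truth["tob"] * T
            + truth["loyal:tob"] * L * T
            + (truth["exp"] + truth["exp:tob"] * T + truth["exp:loyal"] * L
               + truth["exp:loyal:tob"] * L * T) * le
            + rng.normal(0, noise_sd, le.size)
        )
        frames.append(
            pd.DataFrame({"player": f"p{i}", "log_exp": le, "loyal": L, "tob": T,
                          "log_skill": y})
        )
    return pd.concat(frames, ignore_index=True), truth


class TestMixedModel:
    def test_zero_random_effect_matches_ols(self):
        import statsmodels.api as sm

        tab, _ = direct_mixed_table(1, n_players=60, n_games=60, re_sd=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mfit = fit_mixed(tab)
        X = np.column_stack(
            [
                np.ones(len(tab)), tab.log_exp, tab.loyal, tab.tob,
                tab.loyal * tab.tob, tab.log_exp * tab.tob,
                tab.log_exp * tab.loyal, tab.log_exp * tab.loyal * tab.tob,
            ]
        )
        ols = sm.OLS(tab.log_skill.to_numpy(), X).fit()
        for j, term in enumerate(MIXED_TERMS):
            assert mfit.estimates[term] == pytest.approx(ols.params[j], abs=1e-4)

    def test_parameter_recovery_within_99_ci(self):
        tab, truth = direct_mixed_table(2, n_players=250, n_games=150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mfit = fit_mixed(tab)
        inside = sum(
            mfit.conf_int[k][0] <= truth[k] <= mfit.conf_int[k][1] for k in truth
        )
        assert inside >= 7  # at most one of eight 99% intervals may miss
        assert mfit.group_var == pytest.approx(0.045**2, rel=0.35)

    def test_constant_covariate_rejected(self):
        tab, _ = direct_mixed_table(3, n_players=30, n_games=40)
        tab["tob"] = 0.5
        with pytest.raises(ValueError, match="collinear"):
            fit_mixed(tab)


class TestCrossSectionTable:
    def test_experience_cutoff_and_skill_source(self, small_world_rated):
        _, _, _, histories, traj = small_world_rated
        E = 30
        tab = cross_section_table(traj, histories, E)
        assert not tab.empty
        for _, row in tab.head(5).iterrows():
            h = histories[row.player_id]
            assert h.games_played >= E
            mu = traj[(traj.player_id == row.player_id) & (traj.experience == E)][
                "mu"
            ].iloc[0]
            assert row.skill == mu

    def test_short_history_excluded(self, small_world_rated):
        _, _, _, histories, traj = small_world_rated
        E = 30
        tab = cross_section_table(traj, histories, E)
        short = {p for p, h in histories.items() if h.games_played < E}
        assert short.isdisjoint(set(tab.player_id))

    def test_empty_table_fit_fails_cleanly(self, small_world_rated):
        _, _, _, histories, traj = small_world_rated
        tab = cross_section_table(traj, histories, 10_000)
        assert tab.empty
        with pytest.raises(ValueError):
            fit_cross_section(tab)

    def test_mixed_table_covariates_within_window(self, small_world_rated):
        _, _, _, histories, traj = small_world_rated
        tab = mixed_model_table(traj, histories, experience_range=(10, 60))
        assert not tab.empty
        assert tab.log_exp.between(1.0, np.log10(60) + 1e-12).all()
        assert tab.loyal.between(0, 1).all() and tab.tob.between(0, 1).all()
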