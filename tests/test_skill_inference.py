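import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from teamskill.skill_inference import (
    PerformanceModel,
    Rating,
    difference_summary,
    elo_update,
    elo_win_probability,
    exact_posterior_moments,
    moment_matched_update,
    multi_team_update,
    quadrature_update,
    rate_history,
    site_points_delta,
    team_performance_distribution,
    v_win,
    w_win,
    win_probability,
)

from conftest import make_game, random_two_team_stream

PM = PerformanceModel()
R0 = Rating()

ratings_st = st.builds(
    Rating,
    mu=st.floats(-50, 100),
    sigma=st.floats(0.1, 20),
)


class TestTeamPerformance:
    def test_single_default_player(self):
        mean, var = team_performance_distribution([R0], PM)
        assert mean == 25
        assert var == pytest.approx((25 / 6) ** 2 + (25 / 3) ** 2)
        assert var == pytest.approx(86.806, abs=1e-3)

    def test_additivity(self):
        mean, var = team_performance_distribution([R0, R0], PM)
        assert (mean, var) == pytest.approx((50, 2 * 86.80555555555556))

    def test_zero_variance_limit(self):
        team = [Rating(25, 0)] * 3
        _, var = team_performance_distribution(team, PM)
        assert var == pytest.approx(3 * PM.beta**2)

    def test_empty_team_rejected(self):
        with pytest.raises(ValueError):
            team_performance_distribution([], PM)


class TestDifference:
    def test_worked_example(self):
        d = difference_summary([R0], [Rating(20, 25 / 3)], PM)
        assert d.delta == pytest.approx(5)
        assert d.theta == pytest.approx(173.611, abs=1e-2)

    def test_antisymmetry(self):
        a, b = [Rating(30, 5), Rating(20, 5)], [Rating(25, 5), Rating(25, 5)]
        d1 = difference_summary(a, b, PM)
        d2 = difference_summary(b, a, PM)
        assert d1.delta == pytest.approx(-d2.delta) == pytest.approx(0)
        assert d1.theta == pytest.approx(d2.theta)

    def test_shared_player_rejected(self):
        with pytest.raises(ValueError, match="both teams"):
            difference_summary({"a": R0, "b": R0}, {"b": R0, "c": R0}, PM)


class TestWinProbability:
    def test_equal_skills_is_half(self):
        assert win_probability([R0], [R0], PM) == pytest.approx(0.5, abs=1e-15)

    def test_five_point_gap(self):
        # independent oracle: normal CDF at delta/sqrt(theta)
        p = win_probability([R0], [Rating(20, 25 / 3)], PM)
        theta = 2 * PM.beta**2 + 2 * R0.sigma**2
        assert p == pytest.approx(stats.norm.cdf(5 / math.sqrt(theta)), abs=1e-12)
        assert p == pytest.approx(0.648, abs=1e-3)

    def test_overwhelming_gap_saturates(self):
        p = win_probability([Rating(1e6, 25 / 3)], [R0], PM)
        assert p == pytest.approx(1.0, abs=1e-12)

    @given(
        a=st.lists(ratings_st, min_size=1, max_size=3),
        b=st.lists(ratings_st, min_size=1, max_size=3),
    )
    @settings(max_examples=100, deadline=None)
    def test_complement_law(self, a, b):
        assert win_probability(a, b, PM) + win_probability(b, a, PM) == pytest.approx(
            1.0, abs=1e-12
        )

    @given(shift=st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_teammate_redistribution_invariance(self, shift):
        # moving mean skill between teammates (sigmas fixed) leaves the
        # team's win probability unchanged
        a = [Rating(25 + shift, 6), Rating(25 - shift, 4)]
        ref = [Rating(25, 6), Rating(25, 4)]
        b = [Rating(27, 5), Rating(24, 5)]
        assert win_probability(a, b, PM) == pytest.approx(
            win_probability(ref, b, PM), abs=1e-12
        )


class TestExactPosterior:
    theta = 2 * PM.beta**2 + 2 * R0.sigma**2

    def test_winning_is_good_news(self):
        mean, _ = exact_posterior_moments(R0, 0.0, self.theta - R0.sigma**2, True)
        assert mean > R0.mu

    def test_win_lose_mirror_symmetry(self):
        win_mean, win_var = exact_posterior_moments(
            R0, 0.0, self.theta - R0.sigma**2, True
        )
        lose_mean, lose_var = exact_posterior_moments(
            R0, 0.0, self.theta - R0.sigma**2, False
        )
        assert win_mean - R0.mu == pytest.approx(R0.mu - lose_mean, abs=1e-9)
        assert win_var == pytest.approx(lose_var, abs=1e-9)

    def test_worked_example_against_monte_carlo(self):
        # equal single opponents: mean ~29.2, sd ~7.19; cross-checked by
        # rejection sampling from the exact posterior
        mean, var = exact_posterior_moments(R0, 0.0, self.theta - R0.sigma**2, True)
        assert mean == pytest.approx(29.205, abs=1e-3)
        assert math.sqrt(var) == pytest.approx(7.194, abs=1e-3)
        rng = np.random.default_rng(0)
        s = rng.normal(R0.mu, R0.sigma, 400_000)
        accept = rng.random(400_000) < stats.norm.cdf(
            (s - R0.mu) / math.sqrt(self.theta - R0.sigma**2)
        )
        kept = s[accept]
        assert mean == pytest.approx(kept.mean(), abs=0.05)
        assert math.sqrt(var) == pytest.approx(kept.std(), abs=0.05)


class TestMomentMatch:
    def test_agrees_with_quadrature_oracle_on_grid(self):
        c = 12.0
        for ratio in (0.1, 0.5, 0.9):
            sigma = ratio * c
            for t in (-3.0, -1.0, 0.0, 1.0, 3.0):
                prior = Rating(25, sigma)
                delta = t * c
                var_rest = c**2 - sigma**2
                beta = math.sqrt(var_rest / 2)  # 1v1 with equal-sigma=0 peer
                opp = Rating(25 - delta, 0.0)
                (w,), _ = moment_matched_update(
                    [prior], [opp], PerformanceModel(beta=beta)
                )
                em, ev = exact_posterior_moments(prior, delta, var_rest, True)
                assert w.mu == pytest.approx(em, abs=1e-6)
                assert w.sigma == pytest.approx(math.sqrt(ev), abs=1e-6)

    def test_equal_opponents_worked_example(self):
        (w,), (l,) = moment_matched_update([R0], [R0], PM)
        assert w.mu == pytest.approx(29.205, abs=1e-3)
        assert l.mu == pytest.approx(20.795, abs=1e-3)
        assert w.sigma == l.sigma == pytest.approx(7.194, abs=1e-3)

    def test_symmetric_priors_gain_equals_loss(self):
        (w,), (l,) = moment_matched_update([Rating(30, 4)], [Rating(30, 4)], PM)
        assert w.mu - 30 == pytest.approx(30 - l.mu, abs=1e-12)

    def test_upset_moves_more_than_expected_result(self):
        (wu,), _ = moment_matched_update([Rating(20, 6)], [Rating(30, 6)], PM)
        (we,), _ = moment_matched_update([Rating(30, 6)], [Rating(20, 6)], PM)
        assert (wu.mu - 20) > (we.mu - 30) > 0

    def test_all_zero_sigma_is_noop_with_warning(self, caplog):
        frozen = [Rating(27, 0.0)]
        with caplog.at_level("WARNING"):
            w, l = moment_matched_update(frozen, [Rating(25, 0.0)], PM)
        assert w == frozen
        assert any("no-op" in r.message for r in caplog.records)

    @given(
        winners=st.lists(ratings_st, min_size=1, max_size=3),
        losers=st.lists(ratings_st, min_size=1, max_size=3),
    )
    @settings(max_examples=100, deadline=None)
    def test_update_directions_and_sigma_shrink(self, winners, losers):
        new_w, new_l = moment_matched_update(winners, losers, PM)
        # sigma shrinks strictly unless the shrink factor underflows to 1 in
        # double precision (a result that carried no surprise for a
        # low-uncertainty player)
        d = difference_summary(winners, losers, PM)
        t = d.delta / math.sqrt(d.theta)
        for old, new, won in [(o, n, True) for o, n in zip(winners, new_w)] + [
            (o, n, False) for o, n in zip(losers, new_l)
        ]:
            assert (new.mu >= old.mu) if won else (new.mu <= old.mu)
            shrink = (old.sigma**2 / d.theta) * w_win(t)
            if shrink > 1e-12:
                assert new.sigma < old.sigma
            else:
                assert new.sigma <= old.sigma


class TestMultiTeam:
    def test_two_teams_reduce_to_pairwise(self):
        teams = [{"a": R0, "b": R0}, {"c": Rating(20, 5), "d": R0}]
        got = multi_team_update(teams, (1, 0), PM)
        (w1, w2), (l1, l2) = moment_matched_update(
            [Rating(20, 5), R0], [R0, R0], PM
        )
        assert got["c"] == w1 and got["d"] == w2
        assert got["a"] == l1 and got["b"] == l2

    def test_three_way_free_for_all_ordering(self):
        teams = [{p: R0} for p in "abc"]
        got = multi_team_update(teams, (0, 1, 2), PM)
        assert got["a"].mu > 25 > got["c"].mu

    def test_player_relabeling_invariance(self):
        teams = [{"a": Rating(28, 5)}, {"b": R0}, {"c": Rating(22, 7)}]
        renamed = [{"x": Rating(28, 5)}, {"y": R0}, {"z": Rating(22, 7)}]
        got = multi_team_update(teams, (2, 0, 1), PM)
        got2 = multi_team_update(renamed, (2, 0, 1), PM)
        for old, new in zip("abc", "xyz"):
            assert got[old] == got2[new]

    def test_ties_rejected(self):
        with pytest.raises(ValueError, match="ranking"):
            multi_team_update([{"a": R0}, {"b": R0}], (0, 0), PM)


class TestElo:
    def test_equal_skills(self):
        assert elo_win_probability(10, 10) == pytest.approx(0.5)

    def test_four_point_gap_oracle(self):
        p = elo_win_probability(4, 0, beta=25 / 6)
        assert p == pytest.approx(stats.norm.cdf(4 / (math.sqrt(2) * 25 / 6)), abs=1e-12)
        assert p == pytest.approx(0.751, abs=1e-3)

    def test_limit(self):
        assert elo_win_probability(1e9, 0) == pytest.approx(1.0)

    def test_equal_skill_update_splits_K(self):
        si, sj = elo_update(0, 0, True, K=32)
        assert (si, sj) == (16, -16)

    def test_zero_sum(self):
        si, sj = elo_update(3, -1, False, K=24)
        assert si + sj == pytest.approx(3 - 1)

    def test_heavy_favorite_gains_nothing(self):
        si, sj = elo_update(1000, 0, True, K=32)
        assert si - 1000 == pytest.approx(0, abs=1e-6)

    def test_underdog_win_gains_most(self):
        si, sj = elo_update(4, 0, False, K=32, beta=25 / 6)
        assert sj == pytest.approx(32 * 0.7514, abs=1e-2)


class TestSitePoints:
    @pytest.mark.parametrize(
        "winner,loser,expected",
        [(2000, 1000, 10), (100, 10000, 100), (1500, 1500, 20)],
    )
    def test_formula(self, winner, loser, expected):
        assert site_points_delta(winner, loser) == pytest.approx(expected)

    def test_bounds(self):
        with pytest.raises(ValueError):
            site_points_delta(0, 10)


class TestStableV:
    def test_deep_tail_matches_asymptote(self):
        for t in (-10.0, -20.0, -35.0):
            assert v_win(t) == pytest.approx(-t, rel=1e-2)
            assert 0 < w_win(t) < 1

    @given(t=st.floats(-40, 8))
    @settings(max_examples=200, deadline=None)
    def test_v_positive_w_unit_interval(self, t):
        assert v_win(t) > 0
        assert 0 < w_win(t) < 1


class TestRateHistory:
    def test_first_game_moves_both_players(self):
        games = [make_game("g0", 0, [["a"], ["b"]], [0, 1])]
        traj, final = rate_history(games)
        assert final["a"].mu > 25 > final["b"].mu
        assert final["a"].sigma < 25 / 3
        assert set(traj["player_id"]) == {"a", "b"}

    def test_player_without_games_has_no_trajectory(self):
        traj, final = rate_history([])
        assert traj.empty and final == {}

    def test_winner_streak_is_monotone(self):
        # one player repeatedly beating fresh opponents: mu nondecreasing
        games = [
            make_game(f"g{i}", i, [["champ"], [f"victim{i}"]], [0, 1])
            for i in range(30)
        ]
        traj, _ = rate_history(games)
        mus = traj[traj.player_id == "champ"].sort_values("experience")["mu"]
        assert (mus.diff().dropna() >= 0).all()

    def test_quadrature_differential_on_stream(self):
        # the closed-form update against the slow numerical-quadrature
        # reference over a mixed 1v1/2v2 stream
        games = random_two_team_stream(60, n_players=12, seed=9)
        t1, _ = rate_history(games)
        t2, _ = rate_history(games, update=quadrature_update)
        diff = np.abs(
            t1[["mu", "sigma"]].to_numpy() - t2[["mu", "sigma"]].to_numpy()
        ).max()
        assert diff <= 1e-6
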