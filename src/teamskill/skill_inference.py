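"""Bayesian skill inference for ranked team games (TrueSkill-style), plus Elo.

The generative model: each player carries a Gaussian skill belief
``s_i ~ N(mu_i, sigma_i^2)`` (default prior mu=25, sigma=25/3, in TrueSkill
points, "tsp"). In a game every participant exhibits a noisy performance
``p_i ~ N(s_i, beta^2)``; a team's performance is the *sum* of its members'
performances, and the team with the larger sum wins. For two teams the
performance difference is Gaussian with mean ``delta`` (difference of team
skill means) and variance ``theta`` (beta^2 + sigma_i^2 summed over *all*
players of both teams), so the win probability is ``Phi(delta / sqrt(theta))``.

Conditioning a player's Gaussian prior on the binary game outcome yields a
Gaussian-times-normal-CDF posterior. The update used in practice replaces it
with the Gaussian matching its first two moments (which minimizes the KL
divergence from the exact posterior); :func:`exact_posterior_moments`
computes those moments by adaptive quadrature and serves as the slow,
independent reference for the closed form in :func:`moment_matched_update`.

Games with more than two teams are handled by sequential pairwise updates of
adjacently ranked teams — an approximation to the full factor-graph
marginalization, adequate here because the analyses downstream use two-team
games.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence
from scipy import integrate
from scipy.special import erfc, erfcx

from .game_records import GameRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Rating",
    "PerformanceModel",
    "DifferenceSummary",
    "EloState",
    "team_performance_distribution",
    "difference_summary",
    "win_probability",
    "exact_posterior_moments",
    "moment_matched_update",
    "quadrature_update",
    "multi_team_update",
    "elo_win_probability",
    "elo_update",
    "site_points_delta",
    "rate_history",
]

DEFAULT_MU = 25.0
DEFAULT_SIGMA = 25.0 / 3.0
DEFAULT_BETA = 25.0 / 6.0

_SQRT2 = math.sqrt(2.0)
_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class Rating:
    """Gaussian belief over a player's skill (tsp)."""

    mu: float = DEFAULT_MU
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class PerformanceModel:
    """Per-game performance noise, and an optional skill-dynamics term.

    ``beta`` is the standard deviation of the performance around the latent
    skill. ``tau`` inflates every player's sigma before each game
    (``sigma^2 += tau^2``); the default 0 keeps beliefs static between games.
    """

    beta: float = DEFAULT_BETA
    tau: float = 0.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class DifferenceSummary:
    """Two-team performance-difference distribution: N(delta, theta)."""

    delta: float  # expected difference of team performances (tsp)
    theta: float  # total variance: sum of beta^2 + sigma_i^2, both teams (tsp^2)


@dataclass(frozen=True)
class EloState:
    """Scalar Elo skill with its maximum per-game stake K."""

    s: float
    K: float = 32.0

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")


def _phi_cdf(x: float) -> float:
    return 0.5 * erfc(-x / _SQRT2)


def _as_ratings(team) -> list[Rating]:
    if isinstance(team, Mapping):
        return list(team.values())
    return list(team)


def team_performance_distribution(
    ratings: Iterable[Rating], perf_model: PerformanceModel
) -> tuple[float, float]:
    """Mean and variance of a team's summed performance:
    (sum mu_i, sum beta^2 + sigma_i^2)."""
    ratings = _as_ratings(ratings)
    if not ratings:
        raise ValueError("team must have at least one rating")
    b2 = perf_model.beta**2
    mean = sum(r.mu for r in ratings)
    variance = sum(b2 + r.sigma**2 for r in ratings)
    return mean, variance


def difference_summary(team_a, team_b, perf_model: PerformanceModel) -> DifferenceSummary:
    """Distribution of (team a performance − team b performance).

    Teams may be given as mappings player_id → Rating (overlap is rejected)
    or as plain rating sequences.
    """
    if isinstance(team_a, Mapping) and isinstance(team_b, Mapping):
        shared = set(team_a) & set(team_b)
        if shared:
            raise ValueError(f"players {sorted(shared)} appear in both teams")
    mean_a, var_a = team_performance_distribution(team_a, perf_model)
    mean_b, var_b = team_performance_distribution(team_b, perf_model)
    return DifferenceSummary(delta=mean_a - mean_b, theta=var_a + var_b)


def win_probability(team_a, team_b, perf_model: PerformanceModel) -> float:
    """P(team a beats team b) = Phi(delta / sqrt(theta))."""
    d = difference_summary(team_a, team_b, perf_model)
    return _phi_cdf(d.delta / math.sqrt(d.theta))


# ---------------------------------------------------------------------------
# posterior: exact moments (quadrature) and the closed-form moment match
# ---------------------------------------------------------------------------


def exact_posterior_moments(
    prior: Rating, delta: float, var_rest: float, won: bool
) -> tuple[float, float]:
    """First two moments of the exact single-player posterior after a
    two-team game, by adaptive quadrature.

    ``delta`` is the expected performance difference oriented as (player's
    team − opposing team); ``var_rest = theta − sigma_i^2`` is the
    performance-difference variance excluding the player's own skill
    uncertainty. The exact posterior is proportional to
    ``N(s; mu, sigma^2) * Phi(±(delta − mu + s) / sqrt(var_rest))`` with the
    positive sign when the player's team won. Returns ``(mean, variance)``.
    """
    if var_rest <= 0:
        raise ValueError(f"var_rest must be > 0, got {var_rest}")
    mu, sigma = prior.mu, prior.sigma
    if sigma == 0:
        return mu, 0.0
    sign = 1.0 if won else -1.0
    sv = math.sqrt(var_rest)

    def integrand(x: float, k: int) -> float:
        s = mu + sigma * x
        dens = math.exp(-0.5 * x * x)
        lik = _phi_cdf(sign * (delta - mu + s) / sv)
        return x**k * dens * lik

    lim = 12.0
    m0 = integrate.quad(integrand, -lim, lim, args=(0,), limit=200)[0]
    m1 = integrate.quad(integrand, -lim, lim, args=(1,), limit=200)[0]
    m2 = integrate.quad(integrand, -lim, lim, args=(2,), limit=200)[0]
    if not (math.isfinite(m0) and m0 > 0):
        raise ValueError("posterior normalization integral is not finite/positive")
    ex = m1 / m0  # E[x] in standardized units
    vx = m2 / m0 - ex**2
    return mu + sigma * ex, sigma**2 * vx


def v_win(t: float) -> float:
    """v(t) = phi(t)/Phi(t), the truncated-Gaussian mean shift.

    Computed as sqrt(2/pi) / erfcx(-t/sqrt(2)), which is stable for
    arbitrarily negative t (where v(t) ~ -t) — no series switchover needed.
    """
    return float(_SQRT_2_OVER_PI / erfcx(-t / _SQRT2))


def w_win(t: float) -> float:
    """w(t) = v(t) * (v(t) + t), the truncated-Gaussian variance shrink;
    lies in (0, 1)."""
    v = v_win(t)
    return v * (v + t)


def moment_matched_update(
    winners: Sequence[Rating], losers: Sequence[Rating], perf_model: PerformanceModel
) -> tuple[list[Rating], list[Rating]]:
    """Closed-form Gaussian (moment-matched) posterior for every player of a
    decided two-team game.

    With ``c = sqrt(theta)`` and ``t = delta/c`` (delta oriented
    winner − loser): each winner i gets ``mu + (sigma_i^2/c) v(t)`` and each
    loser j gets ``mu − (sigma_j^2/c) v(t)``; every player's variance shrinks
    by the factor ``1 − (sigma^2/c^2) w(t)``.
    """
    winners = _as_ratings(winners)
    losers = _as_ratings(losers)
    if all(r.sigma == 0 for r in winners + losers):
        logger.warning("all ratings have sigma=0; skill update is a no-op")
        return list(winners), list(losers)
    d = difference_summary(winners, losers, perf_model)
    c = math.sqrt(d.theta)
    t = d.delta / c
    v = v_win(t)
    w = w_win(t)

    def updated(r: Rating, sign: float) -> Rating:
        s2 = r.sigma**2
        mu = r.mu + sign * (s2 / c) * v
        sigma = math.sqrt(s2 * (1.0 - (s2 / c**2) * w))
        return Rating(mu=mu, sigma=sigma)

    return [updated(r, +1.0) for r in winners], [updated(r, -1.0) for r in losers]


def quadrature_update(
    winners: Sequence[Rating], losers: Sequence[Rating], perf_model: PerformanceModel
) -> tuple[list[Rating], list[Rating]]:
    """Like :func:`moment_matched_update` but with every player's moments
    taken from :func:`exact_posterior_moments`. Slow; reference path only."""
    winners = _as_ratings(winners)
    losers = _as_ratings(losers)
    d = difference_summary(winners, losers, perf_model)

    def updated(r: Rating, won: bool, delta: float) -> Rating:
        var_rest = d.theta - r.sigma**2
        mean, var = exact_posterior_moments(r, delta, var_rest, won)
        return Rating(mu=mean, sigma=math.sqrt(max(var, 0.0)))

    new_w = [updated(r, True, d.delta) for r in winners]
    new_l = [updated(r, False, -d.delta) for r in losers]
    return new_w, new_l


def multi_team_update(
    teams: Sequence[Mapping[str, Rating]],
    outcome: Sequence[int],
    perf_model: PerformanceModel,
    update=moment_matched_update,
) -> dict[str, Rating]:
    """Update ratings for a ranked game of >= 2 teams.

    Two teams reduce to a single :func:`moment_matched_update`. More teams
    are processed as sequential pairwise updates of adjacently ranked teams
    (1st vs 2nd, then 2nd vs 3rd, ...), each pair using ratings as updated so
    far — a documented approximation to the joint multi-team posterior.
    """
    if len(teams) < 2:
        raise ValueError("need at least two teams")
    if sorted(outcome) != list(range(len(teams))):
        raise ValueError(f"outcome {outcome} is not a strict ranking (no ties)")
    current: dict[str, Rating] = {}
    for team in teams:
        for pid, r in team.items():
            if pid in current:
                raise ValueError(f"player {pid!r} appears in more than one team")
            current[pid] = r
    ranked = [list(teams[i].keys()) for i in outcome]
    for better, worse in zip(ranked, ranked[1:]):
        new_w, new_l = update(
            [current[p] for p in better], [current[p] for p in worse], perf_model
        )
        current.update(zip(better, new_w))
        current.update(zip(worse, new_l))
    return current


# ---------------------------------------------------------------------------
# Elo
# ---------------------------------------------------------------------------


def elo_win_probability(si: float, sj: float, beta: float = DEFAULT_BETA) -> float:
    """P(i beats j) = Phi((si − sj) / (sqrt(2) beta)): the performance
    difference of two scalar skills has variance 2 beta^2."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return _phi_cdf((si - sj) / (_SQRT2 * beta))


def elo_update(
    si: float,
    sj: float,
    i_won: bool,
    K: float = 32.0,
    beta: float = DEFAULT_BETA,
) -> tuple[float, float]:
    """One Elo step: the winner gains K·(1 − P(observed result)), the loser
    loses the same amount (zero-sum)."""
    if K <= 0:
        raise ValueError("K must be > 0")
    p_i = elo_win_probability(si, sj, beta)
    p_observed = p_i if i_won else 1.0 - p_i
    step = K * (1.0 - p_observed)
    if i_won:
        return si + step, sj - step
    return si - step, sj + step


def site_points_delta(winner_score: float, loser_score: float) -> float:
    """The analysed platform's ladder-point stake:
    min((loser score / winner score) · 20, 100)."""
    if winner_score <= 0 or loser_score <= 0:
        raise ValueError("scores must be > 0")
    return min(loser_score / winner_score * 20.0, 100.0)


# ---------------------------------------------------------------------------
# history-wide rating
# ---------------------------------------------------------------------------


def rate_history(
    games: Iterable[GameRecord],
    defaults: Rating = Rating(),
    perf_model: PerformanceModel = PerformanceModel(),
    update=moment_matched_update,
):
    """Run the rating system over a chronological game stream.

    New players are initialized at ``defaults``; after every game all
    participants' beliefs are replaced by their (approximate) posteriors, and
    a trajectory row ``(seq, experience, mu, sigma)`` is recorded per
    participant. The scalar "skill" used by all downstream analyses is the
    post-game posterior mean ``mu``.

    Returns ``(trajectories, final)`` where ``trajectories`` is a pandas
    DataFrame with columns ``player_id, seq, experience, mu, sigma`` and
    ``final`` maps player_id → final :class:`Rating`.

    ``update`` selects the per-pair update rule; the default is the
    closed-form moment match, :func:`quadrature_update` is the slow
    reference.
    """
    import pandas as pd

    ratings: dict[str, Rating] = {}
    experience: dict[str, int] = {}
    rows_pid: list[str] = []
    rows_seq: list[int] = []
    rows_exp: list[int] = []
    rows_mu: list[float] = []
    rows_sigma: list[float] = []

    tau2 = perf_model.tau**2
    ordered = sorted(games, key=lambda g: g.seq)
    for g in ordered:
        teams = []
        for members in g.teams:
            team = {}
            for pid in members:
                r = ratings.get(pid, defaults)
                if tau2 > 0:
                    r = replace(r, sigma=math.sqrt(r.sigma**2 + tau2))
                team[pid] = r
            teams.append(team)
        updated = multi_team_update(teams, g.outcome, perf_model, update=update)
        for pid, r in updated.items():
            ratings[pid] = r
            experience[pid] = experience.get(pid, 0) + 1
            rows_pid.append(pid)
            rows_seq.append(g.seq)
            rows_exp.append(experience[pid])
            rows_mu.append(r.mu)
            rows_sigma.append(r.sigma)

    trajectories = pd.DataFrame(
        {
            "player_id": rows_pid,
            "seq": rows_seq,
            "experience": rows_exp,
            "mu": rows_mu,
            "sigma": rows_sigma,
        }
    )
    return trajectories, ratings
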