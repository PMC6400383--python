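"""Synthetic game-history generator.

Produces chronological game streams with the statistical structure the
analysis pipeline assumes, so every stage can be tested without external
data:

* each player i carries a latent true-skill curve growing as a power law of
  experience, modulated on the log10 scale by their grouping behavior:

  ``log10 S_i(n) = I0 + u_i + c_loyal*L_i + c_tob*T_i + c_lt*L_i*T_i
  + (alpha0 + c_et*T_i + c_el*L_i + c_elt*L_i*T_i) * log10(n)``

  with ``u_i`` a per-player Gaussian random intercept, ``T_i`` (team-game
  propensity) and ``L_i`` (partner-repetition propensity) drawn from Beta
  distributions;
* per game, an initiator is drawn uniformly among players still below their
  activity budget and chooses a team game with probability q_i = T_i/(2-T_i),
  else a 1v1. Matchmaking is type-respecting: each team side is a "leader"
  plus partner slots (the leader's first slot is their preferred partner with
  probability L, else a draft weighted by q(1-L)); the opposing leader is
  drafted with weight q, and 1v1 opponents with weight 1-q. Preferred pairs
  are mutual and assorted on activity budget and faithfulness propensity.
  This balance makes each player's *realized* team-game fraction and
  partner-repetition fraction converge to their targets T_i and L_i (a
  uniform-drafting scheme would dilute both toward the population mean);
* every participant's performance is Normal(true skill at their current
  experience, beta^2); team performance is the sum; the higher sum wins.

Because outcomes are generated from exactly the additive Gaussian team model
the rating system assumes, rating estimates are consistent for the injected
true skills, making parameter-recovery tests clean identity checks.

Default effect sizes mirror the sign structure of the empirical findings the
pipeline is built to detect (negative main TOB effect, positive
loyalty-by-TOB "faithfulness" interaction) at magnitudes detectable at
desk-scale sample sizes; see docs/methods.md for the rationale behind each
default.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .game_records import GameRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TruePlayer",
    "generate_population",
    "true_skill_at",
    "simulate_history",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic world.

    Growth defaults (``intercept_log10`` = 1.415, i.e. Skill0 ~ 26;
    ``alpha0`` = 0.016; ``player_sd`` ~ sqrt(0.002)) and the behavior-effect
    defaults are on the log10-skill scale. ``tob_*``/``loyalty_*`` are the
    Beta parameters of the behavioral-target distributions (U-shaped by
    default: populations split between solo-leaning and team-dedicated
    players). Activity budgets are log-uniform on [budget_min, budget_max],
    a heavy-tailed activity mix giving both short-lived and persistent
    players.
    """

    n_players: int = 6000
    games_total: int = 70_000
    seed: int = 0
    beta: float = 25.0 / 6.0
    # law-of-practice growth of true skill
    intercept_log10: float = 1.415
    alpha0: float = 0.016
    # injected behavior effects on log10 true skill
    c_loyal: float = 0.05
    c_tob: float = -0.044
    c_loyal_tob: float = 0.090
    c_exp_tob: float = 0.0
    c_exp_loyal: float = 0.0
    c_exp_loyal_tob: float = 0.0
    player_sd: float = 0.045  # SD of the per-player random intercept u_i
    # behavioral target distributions (independent Betas)
    tob_alpha: float = 0.5
    tob_beta: float = 0.5
    loyalty_alpha: float = 0.5
    loyalty_beta: float = 0.5
    team_size: int = 2  # players per side in a team game
    #: activity budgets are lognormal (median budget_median, log-scale SD
    #: budget_log_sd), clipped to [budget_min, budget_max]: most players are
    #: short-lived with a heavy tail of persistent ones. A novice-dominated
    #: participant pool keeps the rating scale anchored near the prior —
    #: with a veteran-heavy pool the fixed entry prior causes systematic
    #: rating deflation under population-wide skill growth
    budget_median: float = 16.0
    budget_log_sd: float = 1.5
    budget_min: int = 2
    budget_max: int = 2000
    #: fraction of the stream over which player entries are staggered; a
    #: continuous influx of newcomers (who start at the rating prior) anchors
    #: the rating scale, which is what lets population-wide skill growth show
    #: up in a relative rating system at all
    entry_stagger: float = 0.75
    churn_per_loss: float = 0.0  # optional hazard of quitting after a loss

    def __post_init__(self):
        if self.n_players < 2:
            raise ValueError("need at least 2 players to form games")
        if self.team_size < 2:
            raise ValueError("team games need team_size >= 2")
        if self.beta <= 0 or self.player_sd < 0 or self.alpha0 < 0:
            raise ValueError("beta must be > 0; player_sd and alpha0 must be >= 0")
        if not (0 < self.budget_min <= self.budget_max):
            raise ValueError("need 0 < budget_min <= budget_max")
        if self.budget_median <= 0 or self.budget_log_sd < 0:
            raise ValueError("budget_median must be > 0 and budget_log_sd >= 0")
        if not 0.0 <= self.churn_per_loss <= 1.0:
            raise ValueError("churn_per_loss must be in [0, 1]")
        if not 0.0 <= self.entry_stagger <= 1.0:
            raise ValueError("entry_stagger must be in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class TruePlayer:
    player_id: str
    u: float  # random intercept on log10 skill
    tob_target: float
    loyalty_target: float
    preferred_partner: str
    budget: int
    entry_game: int = 0  # stream position at which the player becomes active


def _rngs(config: SimulationConfig):
    """Fan a single config seed out to the per-stage generators."""
    pop_ss, game_ss = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(pop_ss), np.random.default_rng(game_ss)


def generate_population(config: SimulationConfig) -> list[TruePlayer]:
    """Draw the player population (deterministic given the config seed).

    Preferred partners form a mutual perfect matching, assorted on activity
    budget (log2 band) and then on faithfulness propensity q*L, so that loyal
    pairs stay jointly available and drafted team play does not dilute a
    player's realized loyalty. With an odd player count the last player
    prefers a random other.
    """
    rng, _ = _rngs(config)
    n = config.n_players
    ids = [f"p{i:05d}" for i in range(n)]
    u = rng.normal(0.0, config.player_sd, size=n)
    tob = rng.beta(config.tob_alpha, config.tob_beta, size=n)
    loyalty = rng.beta(config.loyalty_alpha, config.loyalty_beta, size=n)
    q = tob / (2.0 - tob)
    order = np.lexsort((rng.random(n), q * loyalty))
    partner = np.empty(n, dtype=int)
    for k in range(0, n - 1, 2):
        partner[order[k]] = order[k + 1]
        partner[order[k + 1]] = order[k]
    if n % 2 == 1:
        lone = order[-1]
        other = int(rng.integers(n - 1))
        partner[lone] = other if other < lone else other + 1
    # one log-uniform activity budget per preferred pair: partners share it,
    # so a loyal pair stays jointly available for its whole lifetime
    pair_budget = np.clip(
        np.rint(
            config.budget_median
            * np.exp(rng.normal(0.0, config.budget_log_sd, size=(n + 1) // 2))
        ),
        config.budget_min,
        config.budget_max,
    ).astype(int)
    # entry times are also drawn per pair, so loyal partners arrive together
    pair_entry = rng.integers(
        0,
        max(int(config.games_total * config.entry_stagger), 1),
        size=(n + 1) // 2,
    )
    budgets = np.empty(n, dtype=int)
    entries = np.empty(n, dtype=int)
    for k in range(0, n - 1, 2):
        budgets[order[k]] = budgets[order[k + 1]] = pair_budget[k // 2]
        entries[order[k]] = entries[order[k + 1]] = pair_entry[k // 2]
    if n % 2 == 1:
        budgets[order[-1]] = pair_budget[-1]
        entries[order[-1]] = pair_entry[-1]
    return [
        TruePlayer(
            player_id=ids[i],
            u=float(u[i]),
            tob_target=float(tob[i]),
            loyalty_target=float(loyalty[i]),
            preferred_partner=ids[partner[i]],
            budget=int(budgets[i]),
            entry_game=int(entries[i]),
        )
        for i in range(n)
    ]


def true_skill_at(player: TruePlayer, n: int, config: SimulationConfig) -> float:
    """Latent true skill (tsp) of a player at their n-th game."""
    if n < 1:
        raise ValueError("experience n starts at 1")
    L, T = player.loyalty_target, player.tob_target
    level = (
        config.intercept_log10
        + player.u
        + config.c_loyal * L
        + config.c_tob * T
        + config.c_loyal_tob * L * T
    )
    slope = (
        config.alpha0
        + config.c_exp_tob * T
        + config.c_exp_loyal * L
        + config.c_exp_loyal_tob * L * T
    )
    return 10.0 ** (level + slope * math.log10(n))


class _ActivePool:
    """Uniform sampling without replacement from a shrinking player pool."""

    def __init__(self, indices):
        self.items = list(indices)
        self.pos = {p: i for i, p in enumerate(self.items)}

    def __len__(self):
        return len(self.items)

    def __contains__(self, p):
        return p in self.pos

    def add(self, p):
        if p not in self.pos:
            self.pos[p] = len(self.items)
            self.items.append(p)

    def remove(self, p):
        i = self.pos.pop(p)
        last = self.items.pop()
        if last != p:
            self.items[i] = last
            self.pos[last] = i

    def sample(self, rng, k, exclude, weight=None):
        """k distinct members not in ``exclude``, accepted with probability
        ``weight(pid)`` (rejection sampling; weights must lie in [0, 1]).
        Falls back to uniform sampling if the weighted draw stalls; returns
        None if even that is infeasible."""
        avail = len(self.items) - len(exclude & self.pos.keys())
        if avail < k:
            return None
        out: list[str] = []
        taken = set(exclude)
        tries = 0
        max_tries = 200 * max(k, 1)
        while len(out) < k:
            p = self.items[int(rng.integers(len(self.items)))]
            if p in taken:
                continue
            tries += 1
            if weight is None or tries > max_tries or rng.random() < weight(p):
                taken.add(p)
                out.append(p)
        return out


def simulate_history(
    population: list[TruePlayer],
    config: SimulationConfig,
    collect_truth: bool = False,
):
    """Simulate a chronological stream of games (see module docstring for
    the per-game mechanics).

    Participants are drawn from players still below their activity budget;
    the stream is truncated with a warning if the pool can no longer form a
    game. Returns the list of :class:`GameRecord` (and, with
    ``collect_truth=True``, a DataFrame of per-participant true skills at
    play time).
    """
    if len(population) < 2 * config.team_size:
        raise ValueError(
            f"population of {len(population)} cannot form "
            f"{config.team_size}v{config.team_size} team games"
        )
    _, rng = _rngs(config)
    by_id = {p.player_id: p for p in population}
    games_played = {p.player_id: 0 for p in population}
    pending = sorted(population, key=lambda p: (p.entry_game, p.player_id))
    pool = _ActivePool([])
    next_pending = 0
    records: list[GameRecord] = []
    truth_rows = [] if collect_truth else None
    beta = config.beta
    k = config.team_size

    def perf(pid: str):
        p = by_id[pid]
        s = true_skill_at(p, games_played[pid] + 1, config)
        return s, s + beta * rng.standard_normal()

    def q_of(pid: str) -> float:
        t = by_id[pid].tob_target
        return t / (2.0 - t)

    def w_team_leader(pid: str) -> float:
        return q_of(pid)

    def w_random_partner(pid: str) -> float:
        return q_of(pid) * (1.0 - by_id[pid].loyalty_target)

    def w_solo(pid: str) -> float:
        return 1.0 - q_of(pid)

    def fill_side(leader: str, taken: set[str]) -> list[str] | None:
        """Leader plus k-1 partners: the first slot is the leader's preferred
        partner with probability L, remaining slots are weighted drafts."""
        side = [leader]
        pref = by_id[leader].preferred_partner
        if (
            pref in pool
            and pref not in taken
            and rng.random() < by_id[leader].loyalty_target
        ):
            side.append(pref)
        extra = pool.sample(
            rng, k - len(side), exclude=taken | set(side), weight=w_random_partner
        )
        if extra is None:
            return None
        return side + extra

    for g in range(config.games_total):
        while next_pending < len(pending) and pending[next_pending].entry_game <= g:
            pool.add(pending[next_pending].player_id)
            next_pending += 1
        if len(pool) < 2:
            if next_pending >= len(pending):
                logger.warning(
                    "player budgets exhausted after %d of %d games; truncating",
                    g,
                    config.games_total,
                )
                break
            continue  # waiting for more entrants
        init_id = pool.items[int(rng.integers(len(pool)))]
        team_a = None
        if rng.random() < q_of(init_id) and len(pool) >= 2 * k:
            side_a = fill_side(init_id, set())
            if side_a is not None:
                opp_leader = pool.sample(
                    rng, 1, exclude=set(side_a), weight=w_team_leader
                )
                if opp_leader is not None:
                    side_b = fill_side(opp_leader[0], set(side_a))
                    if side_b is not None:
                        team_a, team_b = side_a, side_b
        if team_a is None:
            opp = pool.sample(rng, 1, exclude={init_id}, weight=w_solo)
            if opp is None:
                logger.warning("no opponent available at game %d; truncating", g)
                break
            team_a, team_b = [init_id], opp

        while True:
            pa = [perf(pid) for pid in team_a]
            pb = [perf(pid) for pid in team_b]
            ta = sum(x[1] for x in pa)
            tb = sum(x[1] for x in pb)
            if ta != tb:  # exact ties have probability 0; resample if hit
                break
        outcome = (0, 1) if ta > tb else (1, 0)
        rec = GameRecord(
            game_id=f"g{g:07d}",
            seq=g,
            teams=(frozenset(team_a), frozenset(team_b)),
            outcome=outcome,
        )
        records.append(rec)
        if truth_rows is not None:
            for (pid, (s, _)) in zip(team_a + team_b, pa + pb):
                truth_rows.append(
                    {
                        "game_id": rec.game_id,
                        "player_id": pid,
                        "experience": games_played[pid] + 1,
                        "true_skill": s,
                    }
                )
        losers = team_b if ta > tb else team_a
        for pid in team_a + team_b:
            games_played[pid] += 1
            if pid in pool and games_played[pid] >= by_id[pid].budget:
                pool.remove(pid)
        if config.churn_per_loss > 0:
            for pid in losers:
                if pid in pool and rng.random() < config.churn_per_loss:
                    pool.remove(pid)

    if truth_rows is not None:
        return records, pd.DataFrame(truth_rows)
    return records


TRUTH_COLUMNS = [
    "player_id",
    "u",
    "tob_target",
    "loyalty_target",
    "preferred_partner",
    "budget",
    "entry_game",
]


def write_truth(population: list[TruePlayer], config: SimulationConfig, path) -> None:
    """CSV of per-player true parameters, headed by a commented echo of the
    full config (including the seed) for provenance."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("# config: " + json.dumps(asdict(config), sort_keys=True) + "\n")
        writer = csv.writer(fh)
        writer.writerow(TRUTH_COLUMNS)
        for p in population:
            writer.writerow(
                [
                    p.player_id,
                    repr(p.u),
                    repr(p.tob_target),
                    repr(p.loyalty_target),
                    p.preferred_partner,
                    p.budget,
                    p.entry_game,
                ]
            )


def read_truth(path) -> tuple[pd.DataFrame, SimulationConfig]:
    """Read a truth table back; float fields round-trip exactly (written
    with repr)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("# config: "):
            raise ValueError("truth file missing config echo header")
        config = SimulationConfig(**json.loads(header[len("# config: ") :]))
        df = pd.read_csv(fh, float_precision="round_trip")
    return df, config
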