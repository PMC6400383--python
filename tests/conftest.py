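import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from teamskill.game_records import GameRecord, build_histories
from teamskill.skill_inference import rate_history
from teamskill.synthetic_data import (
    SimulationConfig,
    generate_population,
    simulate_history,
)


def make_game(gid, seq, teams, outcome):
    return GameRecord(
        game_id=gid,
        seq=seq,
        teams=tuple(frozenset(t) for t in teams),
        outcome=tuple(outcome),
    )


def random_two_team_stream(n_games, n_players=30, seed=0, team_sizes=(1, 2)):
    """Random decided two-team games (mix of 1v1 and kvk)."""
    rng = np.random.default_rng(seed)
    pids = [f"p{i}" for i in range(n_players)]
    games = []
    for g in range(n_games):
        k = int(rng.choice(team_sizes))
        ps = rng.choice(n_players, size=2 * k, replace=False)
        outcome = (0, 1) if rng.random() < 0.5 else (1, 0)
        games.append(
            make_game(
                f"g{g}",
                g,
                [[pids[i] for i in ps[:k]], [pids[i] for i in ps[k:]]],
                outcome,
            )
        )
    return games


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic world shared by read-only tests."""
    config = SimulationConfig(
        n_players=800, games_total=9000, seed=77, budget_median=40.0
    )
    population = generate_population(config)
    games = simulate_history(population, config)
    return config, population, games


@pytest.fixture(scope="session")
def small_world_rated(small_world):
    config, population, games = small_world
    histories = build_histories(games)
    trajectories, final = rate_history(games)
    return config, population, games, histories, trajectories
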