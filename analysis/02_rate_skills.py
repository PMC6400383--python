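"""Run Bayesian skill inference over the simulated corpus.

Every player starts at the prior N(25, 8.33^2); after each game all
participants' beliefs are replaced by the moment-matched posterior. The
per-game trajectories (player, seq, experience, mu, sigma) go to
scratch/run/trajectories.csv; a small summary of belief convergence goes to
results/.
"""

import json
from pathlib import Path

from teamskill.game_records import read_games
from teamskill.skill_inference import rate_history

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main():
    games = read_games(RUN / "games.jsonl")
    trajectories, final = rate_history(games)
    trajectories.to_csv(RUN / "trajectories.csv", index=False)

    sigma_at = {
        n: float(trajectories[trajectories.experience == n].sigma.median())
        for n in (1, 10, 50, 100)
        if (trajectories.experience == n).any()
    }
    summary = {
        "n_games": len(games),
        "n_rated_players": len(final),
        "trajectory_rows": len(trajectories),
        "median_sigma_at_experience": sigma_at,
    }
    with open(RESULTS / "rating_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(
        f"rated {len(final)} players over {len(games)} games; belief sigma "
        f"shrinks from {sigma_at.get(1, float('nan')):.2f} (1 game) to "
        f"{sigma_at.get(100, float('nan')):.2f} (100 games)"
    )


if __name__ == "__main__":
    main()
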