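"""Learning curves and the law of practice.

Splits players into activity cohorts [2^n, 2^(n+1)), aggregates each
cohort's estimated skill by experience (Hodges-Lehmann pseudomedian with
signed-rank CI over the cohort's first 2^n games), fits the power law
Skill = Skill0 * Experience^alpha to each curve, and compares final-skill
distributions between TOB classes with the two-sample rank-sum test.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from teamskill.behavior_metrics import profiles_table
from teamskill.game_records import build_histories, read_games
from teamskill.learning_curves import (
    activity_cohorts,
    aggregate_curve,
    compare_curves,
    fit_power_law,
)

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main():
    games = read_games(RUN / "games.jsonl")
    histories = build_histories(games)
    traj = pd.read_csv(RUN / "trajectories.csv")

    # cohort curves and power-law fits
    cohorts = activity_cohorts(histories)
    tables, fits = [], {}
    for n in sorted(cohorts):
        label = f"[{2**n},{2**(n+1)})"
        curve = aggregate_curve(
            traj, cohorts[n], label=label, max_experience=2**n
        )
        tab = curve.table.copy()
        tab.insert(0, "cohort", label)
        tables.append(tab)
        if len(curve.table) >= 4:
            f = fit_power_law(curve)
            fits[label] = {
                "alpha": round(f.alpha, 4),
                "skill0": round(f.skill0, 2),
                "alpha_se": round(f.alpha_se, 4),
                "r2": round(f.r2, 3),
                "n_players": len(cohorts[n]),
            }
    pd.concat(tables).to_csv(RESULTS / "curves.csv", index=False)
    with open(RESULTS / "power_law_fits.json", "w") as fh:
        json.dump(fits, fh, indent=2)

    # strong vs weak TOB separation at a common experience level
    prof = profiles_table(histories)
    eligible = prof[prof.eligible]
    level = 64
    at_level = traj[traj.experience == level]
    skills = dict(zip(at_level.player_id, at_level.mu))
    groups = {
        cls: [skills[p] for p in eligible[eligible.tob_class == cls].player_id
              if p in skills]
        for cls in ("strong", "medium", "weak")
    }
    comparisons = {}
    for a, b in (("strong", "weak"), ("strong", "medium"), ("medium", "weak")):
        if len(groups[a]) >= 3 and len(groups[b]) >= 3:
            comparisons[f"{a}_vs_{b}"] = {
                "p_value": compare_curves(groups[a], groups[b]),
                "median_diff": float(np.median(groups[a]) - np.median(groups[b])),
                "n": [len(groups[a]), len(groups[b])],
            }
    with open(RESULTS / "tob_curve_comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=2)

    print(f"fitted {len(fits)} cohort curves; alphas:",
          {k: v["alpha"] for k, v in fits.items()})
    for name, c in comparisons.items():
        print(f"  skill at {level} games, {name}: median diff "
              f"{c['median_diff']:+.2f} tsp, rank-sum p = {c['p_value']:.2g}")


if __name__ == "__main__":
    main()
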