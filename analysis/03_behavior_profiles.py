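"""Compute grouping-behavior profiles (TOB, loyalty, faithfulness).

Profiles every player over their whole history, classifies them into the
strong/medium/weak TOB and loyal/casual bins, applies the >= 4 team games
eligibility filter, and verifies the exact identity
faithfulness = loyalty * TOB. Full profiles go to scratch/run/; class counts
and the identity check go to results/.
"""

import json
from pathlib import Path

from teamskill.behavior_metrics import profiles_table
from teamskill.game_records import build_histories, read_games

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main():
    games = read_games(RUN / "games.jsonl")
    histories = build_histories(games)
    table = profiles_table(histories)
    table.to_csv(RUN / "profiles.csv", index=False)

    team = table[table.team_games > 0]
    identity_err = float((team.faithfulness - team.loyalty * team.tob).abs().max())
    summary = {
        "n_players": len(table),
        "n_eligible": int(table.eligible.sum()),
        "tob_class_counts": table.tob_class.value_counts().to_dict(),
        "loyalty_class_counts": table.loyalty_class.value_counts().to_dict(),
        "faithfulness_identity_max_abs_error": identity_err,
    }
    with open(RESULTS / "behavior_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(
        f"profiled {len(table)} players ({summary['n_eligible']} eligible); "
        f"faithfulness = loyalty*TOB holds to {identity_err:.1e}"
    )


if __name__ == "__main__":
    main()
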