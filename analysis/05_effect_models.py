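"""Effect models: how loyalty, TOB and faithfulness relate to skill.

Fits the cross-sectional model skill ~ loyalty + TOB + faithfulness at
experience 100 (and repeated at higher levels while enough players qualify),
reports collinearity (VIF) and the loyalty threshold at which faithfulness
reverses the TOB contribution, then fits the longitudinal mixed model
log10(skill) ~ log10(exp) * loyalty * TOB with a per-player random
intercept and back-transforms the estimates to skill points.
"""

import json
from pathlib import Path

import pandas as pd

from teamskill import effect_models as em
from teamskill.game_records import build_histories, read_games

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main():
    games = read_games(RUN / "games.jsonl")
    histories = build_histories(games)
    traj = pd.read_csv(RUN / "trajectories.csv")

    report = {"cross_section": {}}
    for E in range(100, 1301, 100):
        table = em.cross_section_table(traj, histories, E)
        if len(table) < 30:
            break
        fit = em.fit_cross_section(table, experience=E)
        thr = em.tob_reversal_threshold(fit)
        report["cross_section"][str(E)] = {
            "n": fit.n,
            "estimates": {k: round(v, 4) for k, v in fit.estimates.items()},
            "std_errors": {k: round(v, 4) for k, v in fit.std_errors.items()},
            "p_values": {k: float(f"{v:.3g}") for k, v in fit.p_values.items()},
            "vif": {k: round(v, 2) for k, v in fit.vif.items()},
            "tob_reversal_threshold": round(thr, 3),
        }

    mixed_table = em.mixed_model_table(traj, histories, experience_range=(10, 500))
    mfit = em.fit_mixed(mixed_table)
    report["mixed"] = {
        "n_obs": mfit.n_obs,
        "n_groups": mfit.n_groups,
        "estimates": {k: round(v, 4) for k, v in mfit.estimates.items()},
        "conf_int_99": {k: [round(x, 4) for x in v] for k, v in mfit.conf_int.items()},
        "group_var": round(mfit.group_var, 5),
        "normalized_estimates_tsp": {k: round(v, 2) for k, v in mfit.normalized.items()},
    }
    with open(RESULTS / "effects.json", "w") as fh:
        json.dump(report, fh, indent=2)

    cs = report["cross_section"].get("100")
    if cs:
        e = cs["estimates"]
        print(
            f"experience 100 (n={cs['n']}): loyalty {e['loyalty']:+.2f}, "
            f"TOB {e['tob']:+.2f}, faithfulness {e['faithfulness']:+.2f} tsp; "
            f"TOB contribution reverses at loyalty > {cs['tob_reversal_threshold']}"
        )
    print(
        f"mixed model ({mfit.n_obs} rows, {mfit.n_groups} players): "
        f"normalized estimates {report['mixed']['normalized_estimates_tsp']}"
    )


if __name__ == "__main__":
    main()
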