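"""Effect models for grouping behavior on skill.

Two model families quantify how loyalty and team-oriented behavior (TOB)
relate to skill:

* a cross-sectional linear model at a fixed experience level E,
  ``skill ~ b1*loyalty + b2*tob + b3*faithfulness`` (with intercept), where
  faithfulness = loyalty*tob is the interaction term. A negative TOB slope is
  reversed by a positive faithfulness slope once loyalty exceeds ``-b2/b3``
  (the TOB-reversal threshold).
* a longitudinal linear mixed model on the log10 scale over an experience
  window, ``log10(skill) ~ log10(exp) * loyal * tob`` with a random intercept
  per player, fitted by REML. Estimates on the log10 scale are mapped back to
  skill points via the normalization intercept -> 10^I, term c -> 10^(I+c) -
  10^I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .behavior_metrics import eligible, profile
from .game_records import PlayerHistory

__all__ = [
    "EffectFit",
    "MixedFit",
    "cross_section_table",
    "fit_cross_section",
    "vif",
    "tob_reversal_threshold",
    "mixed_model_table",
    "fit_mixed",
    "normalize_estimates",
]

CROSS_SECTION_TERMS = ["intercept", "loyalty", "tob", "faithfulness"]

#: canonical order of the mixed model's fixed effects (log10 scale)
MIXED_TERMS = [
    "intercept",
    "exp",
    "loyal",
    "tob",
    "loyal:tob",
    "exp:tob",
    "exp:loyal",
    "exp:loyal:tob",
]

# patsy's names for the full three-way interaction, mapped to ours
_PATSY_TO_TERM = {
    "Intercept": "intercept",
    "log_exp": "exp",
    "loyal": "loyal",
    "tob": "tob",
    "loyal:tob": "loyal:tob",
    "log_exp:tob": "exp:tob",
    "log_exp:loyal": "exp:loyal",
    "log_exp:loyal:tob": "exp:loyal:tob",
}


@dataclass(frozen=True)
class EffectFit:
    """OLS fit of the cross-sectional model (skill in tsp)."""

    terms: tuple[str, ...]
    estimates: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    vif: dict[str, float]
    n: int
    experience: int | None = None


@dataclass(frozen=True)
class MixedFit:
    """REML mixed-model fit on the log10 scale, with Wald CIs."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    conf_int: dict[str, tuple[float, float]]  # 99% by default
    group_var: float
    n_groups: int
    n_obs: int
    converged: bool
    ci_level: float = 0.99

    @property
    def normalized(self) -> dict[str, float]:
        return normalize_estimates(self)


def cross_section_table(
    trajectories: pd.DataFrame,
    histories: dict[str, PlayerHistory],
    experience: int,
    covariate_mode: str = "running",
) -> pd.DataFrame:
    """One row per player with >= ``experience`` games who passes the
    team-games eligibility filter: skill (post-game-E posterior mean) and the
    behavior covariates.

    ``covariate_mode``: "running" evaluates TOB/loyalty/faithfulness on the
    first E games only; "final" uses the whole history.
    """
    if covariate_mode not in ("running", "final"):
        raise ValueError(f"unknown covariate_mode {covariate_mode!r}")
    at_e = trajectories[trajectories["experience"] == experience]
    skills = dict(zip(at_e["player_id"], at_e["mu"]))
    rows = []
    for pid in sorted(skills):
        h = histories.get(pid)
        if h is None or h.games_played < experience:
            continue
        p = profile(h, upto=experience if covariate_mode == "running" else None)
        if not eligible(p) or p.loyalty is None:
            continue
        rows.append(
            {
                "player_id": pid,
                "skill": skills[pid],
                "loyalty": p.loyalty,
                "tob": p.tob,
                "faithfulness": p.faithfulness,
            }
        )
    return pd.DataFrame(
        rows, columns=["player_id", "skill", "loyalty", "tob", "faithfulness"]
    )


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y = table["skill"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(table)),
            table["loyalty"].to_numpy(dtype=float),
            table["tob"].to_numpy(dtype=float),
            table["faithfulness"].to_numpy(dtype=float),
        ]
    )
    return y, X


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        culprits = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")


def fit_cross_section(table: pd.DataFrame, experience: int | None = None) -> EffectFit:
    """OLS of skill on loyalty, TOB and faithfulness with classical standard
    errors and two-sided t-test p-values."""
    if len(table) <= len(CROSS_SECTION_TERMS):
        raise ValueError(
            f"need more rows than terms ({len(CROSS_SECTION_TERMS)}), got {len(table)}"
        )
    y, X = _design(table)
    _check_rank(X, CROSS_SECTION_TERMS)
    res = sm.OLS(y, X).fit()
    names = CROSS_SECTION_TERMS
    return EffectFit(
        terms=tuple(names),
        estimates=dict(zip(names, map(float, res.params))),
        std_errors=dict(zip(names, map(float, res.bse))),
        t_values=dict(zip(names, map(float, res.tvalues))),
        p_values=dict(zip(names, map(float, res.pvalues))),
        vif=vif(table),
        n=len(table),
        experience=experience,
    )


def vif(table: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors: VIF_k = 1/(1 - R^2_k) from regressing
    covariate k on the other covariates (with intercept)."""
    cols = ["loyalty", "tob", "faithfulness"]
    X = table[cols].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(cols):
        y = X[:, j]
        others = np.column_stack(
            [np.ones(len(X))] + [X[:, k] for k in range(X.shape[1]) if k != j]
        )
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        out[name] = float("inf") if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def tob_reversal_threshold(fit: EffectFit) -> float:
    """Loyalty level at which the faithfulness interaction flips the sign of
    TOB's contribution: b2*tob + b3*loyalty*tob changes sign at
    loyalty = -b2/b3. Values outside [0, 1] mean no reversal occurs over the
    attainable loyalty range."""
    b2 = fit.estimates["tob"]
    b3 = fit.estimates["faithfulness"]
    if b3 == 0:
        raise ValueError("faithfulness coefficient is 0; threshold undefined")
    return -b2 / b3


def mixed_model_table(
    trajectories: pd.DataFrame,
    histories: dict[str, PlayerHistory],
    experience_range: tuple[int, int] = (10, 500),
    covariate_mode: str = "running",
) -> pd.DataFrame:
    """Per-game long table for the mixed model: one row per (player,
    experience) within the window, with log10 experience, the behavior
    covariates and log10 skill. Rows with nonpositive skill or undefined
    loyalty are dropped."""
    from .behavior_metrics import MIN_TEAM_GAMES, running_counts

    lo, hi = experience_range
    df = trajectories[
        (trajectories["experience"] >= lo) & (trajectories["experience"] <= hi)
    ]
    rows = []
    for pid, grp in df.groupby("player_id", sort=True):
        h = histories.get(pid)
        if h is None:
            continue
        if covariate_mode == "final":
            p = profile(h)
            if not eligible(p) or p.loyalty is None:
                continue
            covs = {
                exp: (p.loyalty, p.tob) for exp in range(lo, h.games_played + 1)
            }
        else:
            covs = {}
            for exp, played, team_g, max_p in running_counts(h):
                if exp < lo or exp > hi:
                    continue
                if team_g < MIN_TEAM_GAMES:
                    continue
                covs[exp] = (max_p / team_g, team_g / played)
        for exp, mu in zip(grp["experience"], grp["mu"]):
            if mu <= 0 or int(exp) not in covs:
                continue
            loyal, tob = covs[int(exp)]
            rows.append(
                {
                    "player": pid,
                    "log_exp": math.log10(exp),
                    "loyal": loyal,
                    "tob": tob,
                    "log_skill": math.log10(mu),
                }
            )
    return pd.DataFrame(rows, columns=["player", "log_exp", "loyal", "tob", "log_skill"])


def fit_mixed(table: pd.DataFrame, ci_level: float = 0.99) -> MixedFit:
    """REML fit of log10(skill) on the full three-way interaction of log10
    experience, loyalty and TOB, with a random intercept per player.

    Raises on a rank-deficient fixed-effects design or REML non-convergence
    (the error carries the optimizer diagnostics).
    """
    required = {"player", "log_exp", "loyal", "tob", "log_skill"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    X = np.column_stack(
        [
            np.ones(len(table)),
            table["log_exp"],
            table["loyal"],
            table["tob"],
            table["loyal"] * table["tob"],
            table["log_exp"] * table["tob"],
            table["log_exp"] * table["loyal"],
            table["log_exp"] * table["loyal"] * table["tob"],
        ]
    )
    _check_rank(X, MIXED_TERMS)
    # lbfgs can report convergence on a degenerate infinite-likelihood spike
    # when the random-effect variance is (near) zero; fall back to the slower
    # derivative-free optimizer in that case
    res = None
    failures = []
    for method in ("lbfgs", "powell", "nm"):
        model = smf.mixedlm(
            "log_skill ~ log_exp * loyal * tob", data=table, groups=table["player"]
        )
        candidate = model.fit(reml=True, method=method)
        if candidate.converged and np.isfinite(candidate.llf):
            res = candidate
            break
        failures.append(
            f"{method}: converged={candidate.converged}, llf={candidate.llf}"
        )
    if res is None:
        raise RuntimeError(f"REML did not converge: {'; '.join(failures)}")
    ci = res.conf_int(alpha=1.0 - ci_level)
    estimates, ses, ts, cis = {}, {}, {}, {}
    for patsy_name, term in _PATSY_TO_TERM.items():
        estimates[term] = float(res.fe_params[patsy_name])
        ses[term] = float(res.bse_fe[patsy_name])
        ts[term] = float(res.tvalues[patsy_name])
        cis[term] = (float(ci.loc[patsy_name, 0]), float(ci.loc[patsy_name, 1]))
    return MixedFit(
        estimates=estimates,
        std_errors=ses,
        t_values=ts,
        conf_int=cis,
        group_var=float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0,
        n_groups=int(res.model.n_groups),
        n_obs=int(len(table)),
        converged=bool(res.converged),
        ci_level=ci_level,
    )


def normalize_estimates(fit: MixedFit | dict) -> dict[str, float]:
    """Back-transform log10-scale mixed-model estimates to skill points:
    intercept I -> 10^I, every other term c -> 10^(I+c) - 10^I."""
    est = fit.estimates if isinstance(fit, MixedFit) else dict(fit)
    if "intercept" not in est:
        raise ValueError("estimates must include 'intercept'")
    I = est["intercept"]
    out = {"intercept": 10.0**I}
    for term, c in est.items():
        if term != "intercept":
            out[term] = 10.0 ** (I + c) - 10.0**I
    return out
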