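"""End-to-end validation experiments.

Each function runs one self-contained study on synthetic data — worked
examples with published constants, the quadrature-vs-closed-form oracle
check, the rating differential, outcome calibration, and the parameter
recovery suite — and returns plain numbers. They are shared by the
acceptance script and the acceptance test suite so that both always measure
the same computation.

Problem sizes are fixed here (they are part of each experiment's design and
are documented in docs/methods.md); randomness is controlled through the
``seed`` arguments.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import effect_models as em
from .behavior_metrics import profile
from .game_records import GameRecord, build_histories
from .learning_curves import LearningCurve, aggregate_curve, fit_power_law
from .skill_inference import (
    PerformanceModel,
    Rating,
    exact_posterior_moments,
    moment_matched_update,
    quadrature_update,
    rate_history,
    win_probability,
)
from .synthetic_data import (
    SimulationConfig,
    generate_population,
    simulate_history,
    true_skill_at,
)

#: printed cross-sectional coefficients used as inputs to the worked
#: examples (loyalty, TOB, faithfulness slopes of the published fit)
PUBLISHED_CROSS_SECTION = {"loyalty": 0.7594, "tob": -1.0042, "faithfulness": 3.7077}

#: printed log10-scale longitudinal estimates used as inputs to the
#: normalization worked example
PUBLISHED_MIXED_LOG10 = {
    "intercept": 1.415,
    "exp": 0.016,
    "loyal": -0.007,
    "tob": -0.044,
    "loyal:tob": 0.090,
    "exp:tob": 0.016,
    "exp:loyal": 0.004,
    "exp:loyal:tob": -0.026,
}


def _child_seeds(seed: int, n: int) -> list[int]:
    """Fan one base seed out to n independent 31-bit child seeds."""
    return [
        int(child.generate_state(1, dtype=np.uint32)[0] % 2**31)
        for child in np.random.SeedSequence(seed).spawn(n)
    ]


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


def worked_examples() -> dict[str, float]:
    pm = PerformanceModel()
    p_equal = win_probability([Rating()], [Rating()], pm)
    threshold = em.tob_reversal_threshold(
        em.EffectFit(
            terms=("intercept", "loyalty", "tob", "faithfulness"),
            estimates={"intercept": 28.5707, **PUBLISHED_CROSS_SECTION},
            std_errors={}, t_values={}, p_values={}, vif={}, n=0,
        )
    )
    norm = em.normalize_estimates(PUBLISHED_MIXED_LOG10)
    return {
        "equal_skill_win_probability": p_equal,
        "default_prior_sigma": round(Rating().sigma, 2),
        "tob_reversal_loyalty_threshold": round(threshold, 2),
        "normalized_intercept_tsp": round(norm["intercept"], 2),
        "normalized_exp_tsp": round(norm["exp"], 2),
        "normalized_tob_tsp": round(norm["tob"], 2),
        "normalized_loyal_tob_tsp": round(norm["loyal:tob"], 2),
        "normalized_exp_loyal_tob_tsp": round(norm["exp:loyal:tob"], 2),
    }


# ---------------------------------------------------------------------------
# oracle equivalence and rating differential
# ---------------------------------------------------------------------------


def oracle_grid_error(
    sigma_ratios=tuple(np.arange(0.1, 0.91, 0.1)),
    ts=tuple(np.linspace(-5, 5, 11)),
    c: float = 12.0,
) -> dict[str, float]:
    """Max |mean| and |sd| discrepancy between the closed-form moment match
    and the numerically integrated exact posterior over a (sigma/c, t) grid."""
    worst_mean = worst_sd = 0.0
    for ratio in sigma_ratios:
        sigma = ratio * c
        var_rest = c**2 - sigma**2
        beta = math.sqrt(var_rest / 2)
        pm = PerformanceModel(beta=beta)
        for t in ts:
            prior = Rating(25.0, sigma)
            opponent = Rating(25.0 - t * c, 0.0)
            (w,), _ = moment_matched_update([prior], [opponent], pm)
            m, v = exact_posterior_moments(prior, t * c, var_rest, True)
            worst_mean = max(worst_mean, abs(w.mu - m))
            worst_sd = max(worst_sd, abs(w.sigma - math.sqrt(v)))
    return {
        "max_abs_mean_error": worst_mean,
        "max_abs_sd_error": worst_sd,
        "n": len(sigma_ratios) * len(ts),
    }


def random_two_team_games(n_games: int, seed: int, n_players: int = 40):
    rng = np.random.default_rng(seed)
    pids = [f"p{i}" for i in range(n_players)]
    games = []
    for g in range(n_games):
        k = int(rng.integers(1, 3))  # 1v1 or 2v2
        ps = rng.choice(n_players, size=2 * k, replace=False)
        outcome = (0, 1) if rng.random() < 0.5 else (1, 0)
        games.append(
            GameRecord(
                game_id=f"g{g}",
                seq=g,
                teams=(
                    frozenset(pids[i] for i in ps[:k]),
                    frozenset(pids[i] for i in ps[k:]),
                ),
                outcome=outcome,
            )
        )
    return games


def rating_differential_error(n_games: int = 1000, seed: int = 0) -> dict[str, float]:
    """Closed-form vs quadrature-reference rating over a random two-team
    stream: max |difference| across every per-game mu and sigma."""
    games = random_two_team_games(n_games, seed)
    fast, _ = rate_history(games)
    slow, _ = rate_history(games, update=quadrature_update)
    diff = np.abs(
        fast[["mu", "sigma"]].to_numpy() - slow[["mu", "sigma"]].to_numpy()
    )
    return {"max_abs_error": float(diff.max()), "n": n_games}


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def outcome_calibration(n_games: int = 10_000, seed: int = 0) -> dict[str, float]:
    """Simulate games, predict every outcome from the *known true skills*
    (win probability Phi(delta/sqrt(2 k beta^2))), and compare the empirical
    win frequency with the mean prediction per predicted-probability decile.

    Returns the worst decile discrepancy in binomial standard errors.
    """
    cfg = SimulationConfig(n_players=2000, games_total=n_games, seed=seed)
    pop = generate_population(cfg)
    games, truth = simulate_history(pop, cfg, collect_truth=True)
    skills = truth.set_index(["game_id", "player_id"]).true_skill
    preds, outcomes = [], []
    for g in games:
        k = len(g.teams[0])
        if k != len(g.teams[1]):
            continue
        s0 = sum(skills[(g.game_id, p)] for p in g.teams[0])
        s1 = sum(skills[(g.game_id, p)] for p in g.teams[1])
        preds.append(stats.norm.cdf((s0 - s1) / math.sqrt(2 * k * cfg.beta**2)))
        outcomes.append(g.outcome[0] == 0)
    df = pd.DataFrame({"pred": preds, "won": outcomes})
    df["decile"] = pd.qcut(df.pred, 10, duplicates="drop")
    max_z = 0.0
    for _, grp in df.groupby("decile", observed=True):
        p = grp.pred.mean()
        se = math.sqrt(p * (1 - p) / len(grp))
        max_z = max(max_z, abs(grp.won.mean() - p) / se)
    return {"max_abs_z": max_z, "n": len(df)}


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

TRUE_ALPHA = SimulationConfig().alpha0
TRUE_SKILL0 = 10.0 ** SimulationConfig().intercept_log10


def _curve_experiences(lo: int = 8, hi: int = 256, n: int = 25):
    return sorted(set(np.unique(np.rint(np.logspace(
        math.log10(lo), math.log10(hi), n))).astype(int)))


def powerlaw_identity() -> dict[str, float]:
    """Feeding the generator's noiseless population curve to the fitter
    returns the generator's own (alpha, skill0) exactly."""
    cfg = SimulationConfig(c_loyal=0, c_tob=0, c_loyal_tob=0, player_sd=0.0)
    ns = np.array(_curve_experiences())
    from .synthetic_data import TruePlayer

    ghost = TruePlayer("g", 0.0, 0.5, 0.5, "h", 1)
    skills = [true_skill_at(ghost, int(n), cfg) for n in ns]
    curve = LearningCurve(
        label="identity",
        table=pd.DataFrame(
            {
                "experience": ns, "n_obs": 1, "pseudomedian": skills,
                "ci_low": np.nan, "ci_high": np.nan,
            }
        ),
    )
    fit = fit_power_law(curve)
    return {"alpha": fit.alpha, "skill0": fit.skill0, "n": len(ns)}


def powerlaw_end_to_end(n_seeds: int = 5, seed: int = 0) -> dict[str, float]:
    """Simulate zero-effect worlds, rate them, and fit the law of practice
    to the population pseudomedian curve; alpha is summarized across
    replicate worlds (mean and empirical SE)."""
    alphas = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimulationConfig(seed=s, c_loyal=0, c_tob=0, c_loyal_tob=0)
        pop = generate_population(cfg)
        games = simulate_history(pop, cfg)
        traj, _ = rate_history(games)
        curve = aggregate_curve(traj, experiences=_curve_experiences())
        alphas.append(fit_power_law(curve).alpha)
    a = np.asarray(alphas)
    se = float(a.std(ddof=1) / math.sqrt(len(a))) if len(a) > 1 else float("nan")
    return {
        "alpha_mean": float(a.mean()),
        "alpha_se": se,
        "alpha_abs_z": abs(float(a.mean()) - TRUE_ALPHA) / se,
        "per_seed": [float(x) for x in a],
        "n": n_seeds,
    }


def cross_section_exact_recovery(seed: int = 0, n: int = 500) -> dict[str, float]:
    """Zero-noise linear synthetic table: the cross-sectional fit
    interpolates the injected coefficients exactly."""
    rng = np.random.default_rng(seed)
    injected = {"intercept": 28.0, "loyalty": 1.0, "tob": -1.0, "faithfulness": 4.0}
    L, T = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
    table = pd.DataFrame(
        {
            "player_id": [f"p{i}" for i in range(n)],
            "skill": injected["intercept"] + injected["loyalty"] * L
            + injected["tob"] * T + injected["faithfulness"] * L * T,
            "loyalty": L,
            "tob": T,
            "faithfulness": L * T,
        }
    )
    fit = em.fit_cross_section(table)
    err = max(abs(fit.estimates[k] - injected[k]) for k in injected)
    return {"max_abs_coef_error": err, "n": n}


def sign_pattern_recovery(n_seeds: int = 20, seed: int = 0, experience: int = 100):
    """Full pipeline per seed (simulate, rate, profile, cross-sectional fit
    at the given experience on *estimated* skills): fraction of seeds whose
    fitted (loyalty, tob, faithfulness) slopes are (+, -, +)."""
    hits, fits = 0, []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimulationConfig(seed=s)
        pop = generate_population(cfg)
        games = simulate_history(pop, cfg)
        histories = build_histories(games)
        traj, _ = rate_history(games)
        table = em.cross_section_table(traj, histories, experience)
        fit = em.fit_cross_section(table, experience=experience)
        e = fit.estimates
        ok = e["loyalty"] > 0 and e["tob"] < 0 and e["faithfulness"] > 0
        hits += ok
        fits.append({k: e[k] for k in ("loyalty", "tob", "faithfulness")} | {"n": fit.n})
    return {"rate": hits / n_seeds, "n": n_seeds, "fits": fits}


MIXED_TRUTH = {
    "intercept": 1.415,
    "exp": 0.016,
    "loyal": 0.05,
    "tob": -0.044,
    "loyal:tob": 0.090,
    "exp:tob": 0.016,
    "exp:loyal": 0.004,
    "exp:loyal:tob": -0.026,
}


def mixed_model_recovery(
    n_seeds: int = 3,
    seed: int = 0,
    n_players: int = 500,
    n_games: int = 200,
    re_sd: float = 0.045,
    noise_sd: float = 0.02,
) -> dict[str, float]:
    """Generate longitudinal data directly from the three-way-interaction
    mixed-model structure and refit it; coverage is the fraction of
    (replicate, fixed effect) pairs whose 99% CI contains the truth."""
    inside = total = 0
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        frames = []
        for i in range(n_players):
            L, T = rng.beta(0.5, 0.5), rng.beta(0.5, 0.5)
            u = rng.normal(0, re_sd)
            le = np.log10(np.arange(10, n_games + 1))
            y = (
                MIXED_TRUTH["intercept"] + u
                + MIXED_TRUTH["loyal"] * L + MIXED_TRUTH["tob"] * T
                + MIXED_TRUTH["loyal:tob"] * L * T
                + (
                    MIXED_TRUTH["exp"] + MIXED_TRUTH["exp:tob"] * T
                    + MIXED_TRUTH["exp:loyal"] * L
                    + MIXED_TRUTH["exp:loyal:tob"] * L * T
                ) * le
                + rng.normal(0, noise_sd, le.size)
            )
            frames.append(
                pd.DataFrame(
                    {"player": f"p{i}", "log_exp": le, "loyal": L, "tob": T,
                     "log_skill": y}
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = em.fit_mixed(pd.concat(frames, ignore_index=True))
        for term, truth in MIXED_TRUTH.items():
            lo, hi = fit.conf_int[term]
            inside += lo <= truth <= hi
            total += 1
    return {"coverage": inside / total, "n": total}


def metric_identity_check(seed: int = 0) -> dict[str, float]:
    """Exactness of faithfulness = loyalty * TOB on a simulated stream."""
    cfg = SimulationConfig(n_players=400, games_total=4000, seed=seed,
                           budget_median=30.0)
    games = simulate_history(generate_population(cfg), cfg)
    histories = build_histories(games)
    worst = 0.0
    checked = 0
    for h in histories.values():
        p = profile(h)
        if p.loyalty is None:
            continue
        worst = max(worst, abs(p.faithfulness - p.loyalty * p.tob))
        checked += 1
    return {"max_abs_identity_error": worst, "n": checked}
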