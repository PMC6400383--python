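"""Learning curves: activity cohorts, robust skill-by-experience aggregation,
and the law-of-practice power-law fit.

The law of practice states Skill = Skill0 * Experience^alpha: a straight line
of slope alpha in log10-log10 coordinates. Population curves are summarized
at each experience level by the Hodges-Lehmann pseudomedian (the median of
all Walsh averages (x_i + x_j)/2, i <= j) with the confidence band obtained
by inverting the one-sample Wilcoxon signed-rank statistic: the band's
endpoints are order statistics of the sorted Walsh averages at the signed-rank
critical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .game_records import PlayerHistory

__all__ = [
    "LearningCurve",
    "PowerLawFit",
    "activity_cohorts",
    "pseudomedian",
    "hodges_lehmann_ci",
    "aggregate_curve",
    "fit_power_law",
    "compare_curves",
]

#: above this sample size the Walsh-average matrix is computed on a seeded
#: subsample (memory is quadratic in n; the estimator's precision at this n
#: far exceeds the curve-level differences of interest)
MAX_EXACT_N = 2000

#: largest n for which the signed-rank critical value uses the exact null
#: distribution; beyond it the normal approximation is used
MAX_EXACT_SIGNRANK_N = 50


@dataclass(frozen=True)
class LearningCurve:
    """Per-experience pseudomedian skill (with CI) for one player cohort."""

    label: str
    table: pd.DataFrame = field(repr=False)
    # columns: experience, n_obs, pseudomedian, ci_low, ci_high


@dataclass(frozen=True)
class PowerLawFit:
    """log10-log10 least-squares fit of Skill = skill0 * Experience^alpha."""

    alpha: float
    skill0: float
    alpha_se: float
    log10_skill0_se: float
    r2: float
    resid_se: float  # residual SE on the log10 scale
    n_points: int


def activity_cohorts(
    histories: dict[str, PlayerHistory], min_exponent: int = 3
) -> dict[int, set[str]]:
    """Partition players by total activity into bins [2^n, 2^(n+1)).

    Returns {n: player ids}; players below 2^min_exponent games are left out.
    The curve for bin n should use only each member's first 2^n games (pass
    ``max_experience=2**n`` to :func:`aggregate_curve`).
    """
    cohorts: dict[int, set[str]] = {}
    for pid, h in histories.items():
        g = h.games_played
        if g < 2**min_exponent:
            continue
        n = int(math.floor(math.log2(g)))
        cohorts.setdefault(n, set()).add(pid)
    return cohorts


def _walsh_averages(x: np.ndarray) -> np.ndarray:
    """All (x_i + x_j)/2 for i <= j, sorted."""
    s = np.sort(np.asarray(x, dtype=float))
    iu = np.triu_indices(len(s))
    return np.sort((s[iu[0]] + s[iu[1]]) / 2.0)


def pseudomedian(x) -> float:
    """Hodges-Lehmann one-sample estimator: median of the Walsh averages."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    return float(np.median(_walsh_averages(x)))


def _signrank_cdf(n: int) -> np.ndarray:
    """Exact null CDF of the one-sample signed-rank statistic T for sample
    size n (no ties/zeros), via the generating-polynomial recursion."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return np.cumsum(counts) / 2.0**n


def _signrank_critical(n: int, alpha: float) -> int | None:
    """Largest k with P(T <= k) <= alpha/2 under the null; None if even k=0
    exceeds it (the requested confidence is unachievable at this n)."""
    if n <= MAX_EXACT_SIGNRANK_N:
        cdf = _signrank_cdf(n)
        ks = np.nonzero(cdf <= alpha / 2.0)[0]
        return int(ks[-1]) if ks.size else None
    mean = n * (n + 1) / 4.0
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    k = int(math.floor(mean + stats.norm.ppf(alpha / 2.0) * sd - 0.5))
    return k if k >= 0 else None


def hodges_lehmann_ci(
    x, confidence: float = 0.95, rng: np.random.Generator | None = None
) -> tuple[float, float, float]:
    """Pseudomedian with its signed-rank confidence interval.

    Returns (estimate, ci_low, ci_high); the CI endpoints are NaN when the
    sample has fewer than 2 observations, and fall back to the sample's
    Walsh-average range when n is too small for the requested confidence.
    Samples above ``MAX_EXACT_N`` are subsampled (seeded via ``rng``).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if x.size > MAX_EXACT_N:
        rng = rng or np.random.default_rng(0)
        x = rng.choice(x, size=MAX_EXACT_N, replace=False)
    w = _walsh_averages(x)
    est = float(np.median(w))
    n = x.size
    if n < 2:
        return est, float("nan"), float("nan")
    k = _signrank_critical(n, 1.0 - confidence)
    if k is None:
        return est, float(w[0]), float(w[-1])
    lo = float(w[k]) if k < w.size else float(w[0])
    hi = float(w[w.size - 1 - k])
    return est, lo, hi


def aggregate_curve(
    trajectories: pd.DataFrame,
    players: set[str] | None = None,
    label: str = "all",
    max_experience: int | None = None,
    experiences=None,
    confidence: float = 0.95,
) -> LearningCurve:
    """Pseudomedian skill (posterior mean mu) by experience over a cohort.

    ``trajectories`` is the rate_history output (player_id, experience, mu).
    ``max_experience`` caps the curve (e.g. 2^n for the [2^n, 2^(n+1))
    activity cohort); ``experiences`` optionally selects the levels reported
    (default: every level with at least one observation).
    """
    df = trajectories
    if players is not None:
        df = df[df["player_id"].isin(players)]
    if max_experience is not None:
        df = df[df["experience"] <= max_experience]
    if experiences is not None:
        df = df[df["experience"].isin(list(experiences))]
    if df.empty:
        raise ValueError(f"no trajectory data for cohort {label!r}")
    rows = []
    rng = np.random.default_rng(0)
    for n, grp in df.groupby("experience", sort=True):
        skills = grp["mu"].to_numpy()
        est, lo, hi = hodges_lehmann_ci(skills, confidence=confidence, rng=rng)
        rows.append(
            {
                "experience": int(n),
                "n_obs": len(skills),
                "pseudomedian": est,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return LearningCurve(label=label, table=pd.DataFrame(rows))


def fit_power_law(
    curve: LearningCurve, experience_range: tuple[int, int] | None = None
) -> PowerLawFit:
    """Ordinary least squares of log10(skill) on log10(experience).

    alpha is the slope; skill0 = 10^intercept is the population skill after
    the first game. All fitted skills must be positive.
    """
    tab = curve.table
    if experience_range is not None:
        lo, hi = experience_range
        tab = tab[(tab["experience"] >= lo) & (tab["experience"] <= hi)]
    if len(tab) < 2:
        raise ValueError("need at least two curve points to fit")
    skill = tab["pseudomedian"].to_numpy(dtype=float)
    if np.any(skill <= 0):
        raise ValueError("nonpositive skill on the fitted range; log10 undefined")
    x = np.log10(tab["experience"].to_numpy(dtype=float))
    y = np.log10(skill)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, alpha = coef
    resid = y - X @ coef
    dof = max(n - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
    return PowerLawFit(
        alpha=float(alpha),
        skill0=float(10.0**intercept),
        alpha_se=float(math.sqrt(cov[1, 1])),
        log10_skill0_se=float(math.sqrt(cov[0, 0])),
        r2=r2,
        resid_se=float(math.sqrt(s2)),
        n_points=n,
    )


def compare_curves(sample_a, sample_b) -> float:
    """Two-sided two-sample Wilcoxon rank-sum p-value for the skills of two
    cohorts at one experience level; exact for small samples (<= 50 total),
    normal approximation with tie correction otherwise."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if a.size + b.size <= 50 else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses tied data; fall back to the tie-corrected
        # normal approximation
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0))
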