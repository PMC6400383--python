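# Methods

This note documents the models implemented by `teamskill`, the design of the
synthetic world the analyses are validated on, the numerical choices, and the
known limits of what the validation shows.

## 1. The rating model

Each player carries a Gaussian skill belief `s_i ~ N(mu_i, sigma_i^2)` in
TrueSkill points (tsp), initialized at `mu0 = 25`, `sigma0 = 25/3 ≈ 8.33`.
In a game every participant exhibits a performance `p_i ~ N(s_i, beta^2)`
with `beta = 25/6` by default; a team's performance is the sum of its
members' performances, and the team with the larger sum wins (no draws; the
platform being modeled has none, so tied rankings are rejected at input).

For two teams `A`, `B`, the performance difference is Gaussian with mean
`delta = sum_A mu - sum_B mu` and variance
`theta = sum_{A∪B} (beta^2 + sigma_i^2)`, so

    P(A beats B) = Phi(delta / sqrt(theta)).

Two consequences that are tested as invariants: complements sum to one, and
the win probability depends on teammates only through their sum — moving
mean skill between teammates changes nothing.

### Posterior update

Conditioning a player's prior on the binary outcome gives a posterior
proportional to `N(s; mu, sigma^2) * Phi(±(delta - mu + s)/sqrt(theta -
sigma^2))` (positive sign for a winner). The implemented update replaces
this with the Gaussian matching its first two moments — the KL-minimizing
Gaussian approximation. With `c = sqrt(theta)`, `t = delta/c` oriented
winner-minus-loser, `v(t) = phi(t)/Phi(t)` and `w(t) = v(t)(v(t)+t)`:

    winner i:  mu' = mu + (sigma_i^2/c) v(t)      loser j:  mu' = mu - (sigma_j^2/c) v(t)
    everyone:  sigma'^2 = sigma^2 (1 - (sigma^2/c^2) w(t))

`v` is computed as `sqrt(2/pi)/erfcx(-t/sqrt(2))`, which is stable for
arbitrarily negative `t` (where `v(t) → -t`) with no series switchover.

`exact_posterior_moments` integrates the exact posterior by adaptive
quadrature and is the in-package oracle: the closed form must agree with it
to 1e-6 over a grid of `sigma/c ∈ {0.1..0.9}` and `t ∈ [-5, 5]`, and a
quadrature-driven rating pass over a 1,000-game stream must agree with the
closed-form pass to 1e-6 per rating. The orientation of the two posterior
cases is fixed by the testable requirement that winning is good news
(winner's posterior mean ≥ prior mean).

Games with more than two teams are rated by sequential pairwise updates of
adjacently ranked teams (1st vs 2nd, then 2nd vs 3rd, ...), using ratings as
updated so far. This is an approximation to the joint multi-team posterior;
the synthetic worlds default to two-team games so no downstream analysis
depends on it.

A dynamics term `tau` (sigma inflation per game) is exposed on
`PerformanceModel` and defaults to 0: beliefs are static between games.
Elo (`Phi((s_i - s_j)/(sqrt(2) beta))` win probability, zero-sum update of
at most `K` points) and the platform ladder stake
`min((loser/winner)·20, 100)` are provided as utility references.

The scalar "skill" used by every downstream analysis is the post-game
posterior mean `mu`, not a conservative quantile like `mu - 3 sigma`: the
longitudinal intercept of interest sits near the prior mean, which is only
consistent with `mu`.

## 2. Grouping-behavior metrics

For a player with `g` games, `t` of them team games (a game is a team game
iff any side has ≥ 2 members), and `m` games with their most recurrent
teammate:

    TOB = t/g        loyalty = m/t        faithfulness = m/g = loyalty · TOB

Loyalty is *undefined* (not zero) when `t = 0`. The identity
`faithfulness = loyalty · TOB` is exact as a ratio of counts and is asserted
exactly in tests. Partner games are counted per game (a 3-player team adds
one game to each of two partner counts); ties for the most recurrent
teammate do not affect the maximum.

Class bins are half-open exactly as used in the analyses: strong TOB
`(0.8, 1]`, medium `(0.4, 0.6]`, weak `(0, 0.2]`, `TOB = 0` its own class;
loyal `> 0.5`, casual `≤ 0.2`. Players with fewer than four team games are
excluded from behavior analyses. Profiles can be computed at any history
prefix; cross-sectional models default to the running value at the evaluated
game (the whole-history variant is a flag), since the evaluation experience
is the only point both conventions agree is observable.

## 3. Learning curves and the law of practice

Players are partitioned by total activity into cohorts `[2^n, 2^(n+1))`;
each cohort's curve uses only members' first `2^n` games. At each experience
level the curve reports the Hodges–Lehmann pseudomedian (median of all Walsh
averages) with the 95% confidence band obtained by inverting the one-sample
Wilcoxon signed-rank statistic: band endpoints are order statistics of the
sorted Walsh averages at the signed-rank critical value (exact null
distribution up to n = 50, normal approximation beyond; verified against R's
`wilcox.test` to machine precision on both paths). Samples larger than
2,000 are subsampled with a seeded generator before forming the quadratic
Walsh matrix. Note the one-sample signed-rank interval is the appropriate
band for a single group; the two-sample rank-sum test (exact for ≤ 50 total
observations, tie-corrected normal approximation otherwise) is used for
between-cohort comparisons.

The law of practice `Skill = Skill0 · Experience^alpha` is fit by ordinary
least squares of `log10(skill)` on `log10(experience)` over the aggregated
pseudomedian curve, not over individual trajectories (individual curves of
relative-skill measurements are too volatile to fit reliably). Fits on
log-spaced experience grids are preferred; the fitter requires positive
skills and reports `alpha`, `skill0 = 10^intercept`, their SEs, and R².

### What the end-to-end curve can and cannot recover

A rating system measures *relative* skill; its absolute scale is anchored
only by the convention that newcomers start at `mu0`. Three consequences,
all observed and quantified during design:

* With a fixed population entering at once, population-wide growth is
  invisible: updates are zero-sum in the mean when uncertainties match, so
  the estimated population curve is flat regardless of the true learning
  rate. Continuous newcomer influx is what makes growth measurable; the
  synthetic world therefore staggers entries (uniformly over the first 75%
  of the stream, per preferred pair).
* With a veteran-dominated pool the fixed entry prior causes runaway
  deflation: entrants are systematically overrated relative to genuinely
  better veterans, each entrant discharges rating mass as its large-sigma
  belief corrects, and the scale slides down without bound. A
  novice-dominated activity mix (see §5) keeps the scale stable, at a small
  constant offset below the prior.
* The absolute level `Skill0` is therefore *not identifiable* end to end —
  the measured curve level reflects the prior anchor plus the equilibrium
  offset, not the generator's `10^1.415`. `Skill0` recovery is validated
  through the fitter identity (noiseless curve in, exact parameters out) and
  through noisy-curve simulations with valid SEs. The learning *rate*
  `alpha` is identified, but the OLS slope SE of a single aggregated curve
  understates the true uncertainty by an order of magnitude (curve points
  share players and one realization of the scale's wander), so end-to-end
  alpha recovery is assessed against the empirical SE across replicate
  simulated worlds (5 worlds by default).

## 4. Effect models

**Cross-sectional.** At a fixed experience `E` (default 100), qualifying
players (≥ `E` games, eligible) contribute one row: skill = post-game-`E`
mu, covariates = running behavior metrics at `E`. The model

    skill ~ b1 · loyalty + b2 · TOB + b3 · faithfulness   (+ intercept)

is fit by OLS with classical SEs and two-sided t tests. Collinearity is
reported as VIFs (`1/(1 - R_k^2)` regressing each covariate on the others
with intercept); a rank-deficient design raises an error naming the
collinear columns. When `b2 < 0 < b3`, the TOB contribution
`b2·TOB + b3·loyalty·TOB` reverses sign at `loyalty = -b2/b3` (scale
invariant in the coefficients); values outside `[0, 1]` mean no reversal is
attainable. The fit is repeated at experience 100, 200, ... while enough
players qualify; no multiple-testing correction is applied.

**Longitudinal.** Over the experience window `[10, 500]`,

    log10(skill) ~ log10(exp) * loyalty * TOB  +  (1 | player)

is fit by REML (statsmodels MixedLM) with the full three-way fixed-effect
interaction and a random intercept per player; 99% Wald CIs are reported.
The default optimizer (lbfgs) can report convergence on a degenerate
infinite-likelihood spike when the random-effect variance is near zero, so
the fit validates `llf` finiteness and falls back to derivative-free
optimizers (Powell, then Nelder–Mead). Log-scale estimates are
back-transformed to tsp as `intercept → 10^I`, `term c → 10^(I+c) − 10^I`,
reported to 2 decimals.

## 5. The synthetic world

The generator produces data with exactly the structure the analyses assume,
so recovery tests are identity tests up to sampling noise.

**True skill.** On the log10 scale,

    log10 S_i(n) = I0 + u_i + c_loyal L_i + c_tob T_i + c_lt L_i T_i
                   + (alpha0 + c_et T_i + c_el L_i + c_elt L_i T_i) log10 n

with defaults `I0 = 1.415` (Skill0 ≈ 26 tsp), `alpha0 = 0.016`,
`u_i ~ N(0, 0.045^2)` (group variance 0.002 on the log10 scale), behavior
propensities `T_i, L_i ~ Beta(0.5, 0.5)` (U-shaped: populations split
between solo-leaning and team-dedicated, spread-out loyalty). Effect
defaults: `c_tob = -0.044` and `c_lt = +0.090` (the published longitudinal
sign structure: team play alone hurts, faithful team play helps);
`c_loyal = +0.05`, set by two design computations made before any
acceptance run — (a) the population least-squares projection of this
exponential skill surface onto the level-scale cross-sectional design must
give a loyalty slope that stays positive after rating-estimation shrinkage
and covariate measurement error (at smaller values the convex `10^(0.09 LT)`
interaction drives the projected loyalty slope into the noise), and (b) it
reproduces a ≈ 4 tsp short-run separation between loyal and casual
strong-TOB players, the magnitude of the faithfulness boost the pipeline is
meant to detect. Experience-interaction coefficients default to 0 (the
validation suite is cross-sectionally focused); all are configurable.

**Outcomes.** Every participant's performance is drawn
`N(true skill at current experience, beta^2)`; the higher team sum wins
(exact ties are resampled). This is precisely the rating model's likelihood,
so estimated skills are consistent for the true ones, and the win rate
binned by true-skill difference must follow `Phi(delta/sqrt(2k beta^2))` —
checked within 3 binomial SEs per decile.

**Matchmaking.** The naive scheme (uniform drafting of partners and
opponents) does *not* reproduce per-player behavior targets: drafted
participation dilutes everyone's realized TOB and loyalty toward the
population mean (measured: realized TOB ≈ 0.5·target + 0.25). Matchmaking
is therefore type-respecting. An initiator opens a team game with
probability `q = T/(2-T)` (so that the realized team-game fraction, which
includes drafts, equals `T`); each team side is a leader plus partner slots,
the first slot being the leader's preferred partner with probability `L`
and weighted drafts otherwise; drafts are accepted with probability
proportional to `q` (opposing leader), `q(1-L)` (random partner slots) and
`1-q` (solo opponents). A balance computation gives realized TOB = `T` and
realized loyalty = `L` in expectation; simulations confirm median absolute
errors ≤ 0.02 for long-lived players. The ±0.05 convergence contract is
asserted at the median, not per player: binomial noise alone at 200 games
has SD ≈ 0.035, so no generator could satisfy a per-player bound.

**Preferred pairs** are mutual, assorted on faithfulness propensity `q·L`
(so a loyal player's partner initiates loyal team games at a matching rate —
required for the loyalty balance above), and share one activity budget and
one entry time per pair, so loyal pairs remain jointly available.

**Activity and entry.** Budgets are lognormal (median 16 games, log-SD 1.5,
clipped to [2, 2000]): most players are short-lived, with a heavy tail of
persistent ones — mean ≈ 49 games per player, matching the modeled
platform's ~54. The default world (6,000 players, 70,000 games) saturates
this capacity, so realized activity follows the budget distribution.
Entries are staggered (uniform over the first 75% of the stream); both
choices are load-bearing for the rating scale (§3). An optional
churn-after-loss hazard exists (off by default) as a stand-in mechanism, not
a claim about the modeled platform.

**What the generator does not emulate:** game mechanics (maps, dice,
turns), opponent loyalty, skill-based matchmaking (the modeled platform has
none), calendar-time effects (site growth, rule changes), draws, and any
behavior-skill feedback (a player's propensities are fixed traits).
Passing recovery tests therefore show that the pipeline correctly inverts
its own assumed data-generating process at realistic sizes — not that the
effects exist in any real corpus.

## 6. Validation experiment sizes

Chosen once, as each experiment's design (see `teamskill.experiments`):

* oracle grid: 9 × 11 (sigma/c, t) points, tolerance 1e-6;
* rating differential: 1,000 random two-team games, tolerance 1e-6;
* calibration: 10,000 simulated games, 3 binomial SEs per predicted decile;
* alpha recovery: 5 replicate default-sized worlds with zero injected
  effects, log-spaced curve grid 8..256, judged against the replicate SE;
* cross-sectional exact recovery: 500 rows, zero noise, tolerance 1e-8;
* sign-pattern recovery: 20 replicate default worlds, cross-section at
  experience 100 on estimated skills (~350 qualifying players each; an
  a-priori power computation at the chosen effect sizes puts the per-world
  probability of the correct (+, −, +) pattern near 0.99);
* mixed-model recovery: 3 replicates of 500 players × 200 games generated
  directly from the longitudinal structure, 99% CI coverage over all
  (replicate, fixed-effect) pairs.

## 7. Degenerate inputs and tie-breaks

Empty teams, overlapping teams, tied rankings and non-permutation outcomes
are rejected at parse time with line numbers. Games with equal `seq` keep
file order; out-of-order files are re-sorted with a warning. An all-zero-
sigma update is a warned no-op. Exact performance ties are resampled (a
probability-zero event under the continuous model). Loyalty of a player
with no team games propagates as undefined, never as zero.
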