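# teamskill

Skill acquisition and team-formation behavior in competitive game
histories.

Online games where people play alone or in self-chosen teams are a natural
laboratory for a question from social-learning research: does *how* you
group — your tendency to play in teams, and your loyalty to a recurrent
teammate — change how fast you get better? `teamskill` implements the full
analysis chain for that question over chronological game logs, plus a
generative simulator so every stage can be validated without access to a
proprietary corpus. It is written for computational behavioral scientists
who want either the pieces (a tested TrueSkill-style rater, robust learning
curves, the behavior metrics) or the whole pipeline.

## The models

**Skill.** Each player carries a Gaussian belief `s ~ N(mu, sigma^2)`
(prior `mu0 = 25`, `sigma0 = 25/3`, in TrueSkill points). Per game, each
participant performs `p ~ N(s, beta^2)`; a team's performance is the sum of
its members'; the larger sum wins. For teams A, B this gives
`P(A wins) = Phi(delta/sqrt(theta))` with `delta` the difference of team
mean sums and `theta` the total variance. After each game, beliefs are
replaced by the moments of the exact (Gaussian × normal-CDF) posterior —
the KL-optimal Gaussian approximation, cross-checked in-package against
numerical quadrature to 1e-6.

**Behavior.** With `g` games, `t` team games, `m` games with the most
recurrent teammate:
`TOB = t/g`, `loyalty = m/t`, `faithfulness = m/g = loyalty · TOB` (exact).

**Learning.** The law of practice `Skill = Skill0 · Experience^alpha`,
fit on log-log scale to per-cohort curves summarized by the Hodges–Lehmann
pseudomedian with signed-rank confidence bands.

**Effects.** Cross-sectionally at fixed experience,
`skill ~ b1·loyalty + b2·TOB + b3·faithfulness`; a negative TOB slope is
reversed by the faithfulness interaction once `loyalty > -b2/b3`.
Longitudinally, `log10(skill) ~ log10(exp) * loyalty * TOB` with a random
intercept per player (REML), estimates back-transformed to skill points via
`10^(I+c) - 10^I`.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

The analysis is organized as numbered scripts over the library; each writes
its tables under `results/` (large intermediates go to `scratch/`):

```bash
python analysis/01_simulate_world.py
python analysis/02_rate_skills.py
python analysis/03_behavior_profiles.py
python analysis/04_learning_curves.py
python analysis/05_effect_models.py
```

Output of a full run (seed 42):

```
simulated 69930 games for 6000 players (189784 participations, 36% team games)
rated 6000 players over 69930 games; belief sigma shrinks from 7.14 (1 game) to 1.19 (100 games)
profiled 6000 players (3398 eligible); faithfulness = loyalty*TOB holds to 1.1e-16
fitted 6 cohort curves; alphas: {'[8,16)': -0.029, ..., '[256,512)': 0.0104}
  skill at 64 games, strong_vs_weak: median diff +0.97 tsp, rank-sum p = 0.049
experience 100 (n=351): loyalty +3.53, TOB -2.80, faithfulness +7.42 tsp;
  TOB contribution reverses at loyalty > 0.378
mixed model (116912 rows, 2926 players): normalized estimates {...}
```

Reading this: the simulator injected a positive loyalty effect, a negative
main team-play effect and a strong positive loyalty×TOB ("faithfulness")
interaction into the latent skills. The pipeline recovers that signature
from the *estimated* skills: at 100 games of experience, players who play
in teams without a stable partner are worse off (−2.8 tsp across the TOB
range), while loyalty (+3.5) and faithfulness (+7.4) more than compensate —
team play starts paying off once loyalty exceeds ≈ 0.38. Strong team players
are about 1 tsp ahead of weak ones at 64 games. Activity cohorts order as
expected, with long-lived cohorts approaching the injected learning rate
(alpha ≈ 0.010 for the [256,512) cohort vs 0.016 injected; short-lived
cohorts are dominated by the rating system's entry transient — see the
methods note on what a relative rating can and cannot measure).

The same stages are available as a CLI for ad-hoc use
(`teamskill simulate|rate|metrics|curves|effects|report`, JSON-Lines or
long-CSV game streams).

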