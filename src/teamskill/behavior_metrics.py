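"""Grouping-behavior metrics: team-oriented behavior, loyalty, faithfulness.

For a player with ``games_played`` total games, of which ``team_games`` were
team games (any team of size >= 2 present in the game), and whose most
recurrent teammate shared ``max_partner_games`` of those:

* TOB (team-oriented behavior) = team_games / games_played
* loyalty = max_partner_games / team_games (undefined without team games)
* faithfulness = max_partner_games / games_played = loyalty * TOB

The identity faithfulness = loyalty * TOB holds exactly as a ratio of counts.
A game with k teammates adds 1 to each of the k partner counts, so "partner
games" are counted per game, not per unique partner.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .game_records import PlayerHistory

__all__ = [
    "BehaviorProfile",
    "profile",
    "classify_tob",
    "classify_loyalty",
    "eligible",
    "profiles_table",
    "MIN_TEAM_GAMES",
]

#: eligibility floor: players with fewer team games are excluded from the
#: grouping-behavior analyses
MIN_TEAM_GAMES = 4


@dataclass(frozen=True)
class BehaviorProfile:
    player_id: str
    games_played: int
    team_games: int
    max_partner_games: int

    def __post_init__(self):
        if not (
            0 <= self.max_partner_games <= self.team_games <= self.games_played
        ):
            raise ValueError(
                "count ordering violated: need "
                "0 <= max_partner_games <= team_games <= games_played, got "
                f"{self.max_partner_games}, {self.team_games}, {self.games_played}"
            )

    @property
    def tob(self) -> float:
        return self.team_games / self.games_played

    @property
    def loyalty(self) -> float | None:
        """None (undefined, not 0) when the player has no team games."""
        if self.team_games == 0:
            return None
        return self.max_partner_games / self.team_games

    @property
    def faithfulness(self) -> float:
        return self.max_partner_games / self.games_played


def profile(history: PlayerHistory, upto: int | None = None) -> BehaviorProfile:
    """Behavior counts over the first ``upto`` games (all games if None)."""
    if len(history) == 0:
        raise ValueError(f"player {history.player_id!r} has an empty history")
    entries = history.entries if upto is None else history.entries[:upto]
    if not entries:
        raise ValueError(f"upto={upto} selects no games")
    team_games = 0
    partners: Counter[str] = Counter()
    for e in entries:
        if e.team_game:
            team_games += 1
        for mate in e.teammates:
            partners[mate] += 1
    return BehaviorProfile(
        player_id=history.player_id,
        games_played=len(entries),
        team_games=team_games,
        max_partner_games=max(partners.values()) if partners else 0,
    )


def running_counts(history: PlayerHistory):
    """Yield ``(experience, games_played, team_games, max_partner_games)``
    after each game, maintaining the counts incrementally (O(total games))."""
    team_games = 0
    max_partner = 0
    partners: Counter[str] = Counter()
    for i, e in enumerate(history.entries, start=1):
        if e.team_game:
            team_games += 1
        for mate in e.teammates:
            partners[mate] += 1
            if partners[mate] > max_partner:
                max_partner = partners[mate]
        yield i, i, team_games, max_partner


def classify_tob(tob: float) -> str:
    """Bin TOB into strong (0.8, 1], medium (0.4, 0.6], weak (0, 0.2],
    none (= 0) or other (the gaps). All bins are open below, closed above."""
    if not 0.0 <= tob <= 1.0:
        raise ValueError(f"tob must be in [0, 1], got {tob}")
    if tob == 0.0:
        return "none"
    if 0.8 < tob <= 1.0:
        return "strong"
    if 0.4 < tob <= 0.6:
        return "medium"
    if tob <= 0.2:
        return "weak"
    return "other"


def classify_loyalty(loyalty: float | None) -> str:
    """loyal when loyalty > 0.5, casual when loyalty <= 0.2, else other.
    Undefined loyalty (no team games) maps to 'other'."""
    if loyalty is None:
        return "other"
    if not 0.0 <= loyalty <= 1.0:
        raise ValueError(f"loyalty must be in [0, 1], got {loyalty}")
    if loyalty > 0.5:
        return "loyal"
    if loyalty <= 0.2:
        return "casual"
    return "other"


def eligible(p: BehaviorProfile) -> bool:
    """True iff the player has at least :data:`MIN_TEAM_GAMES` team games."""
    return p.team_games >= MIN_TEAM_GAMES


def profiles_table(
    histories: dict[str, PlayerHistory], upto: int | None = None
) -> pd.DataFrame:
    """One profile row per player (see module docstring for the columns'
    definitions); loyalty is NaN where undefined."""
    rows = []
    for pid in sorted(histories):
        p = profile(histories[pid], upto=upto)
        rows.append(
            {
                "player_id": pid,
                "games_played": p.games_played,
                "team_games": p.team_games,
                "max_partner_games": p.max_partner_games,
                "tob": p.tob,
                "loyalty": float("nan") if p.loyalty is None else p.loyalty,
                "faithfulness": p.faithfulness,
                "tob_class": classify_tob(p.tob),
                "loyalty_class": classify_loyalty(p.loyalty),
                "eligible": eligible(p),
            }
        )
    return pd.DataFrame(rows)
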