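"""Chronological game-history records and their I/O.

A game history is an ordered stream of games. Each game partitions its
participants into two or more disjoint, nonempty teams and records a strict
ranking of those teams (winner first; draws are not representable because the
analysed platform has none). Chronology is carried by an explicit integer
``seq``; ties in ``seq`` keep file order.

Two plain-text dialects are supported:

* JSON-Lines: one game per line, e.g.
  ``{"game_id": "g1", "seq": 0, "teams": [["a","b"],["c","d"]], "outcome": [1,0]}``
* long CSV: columns ``game_id, seq, team_index, player_id, rank`` with one row
  per player-game (``rank`` 0 means the team finished first).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "GameRecord",
    "HistoryEntry",
    "PlayerHistory",
    "GameValidationError",
    "read_games",
    "write_games",
    "build_histories",
]


class GameValidationError(ValueError):
    """A game record that violates the stream contract."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class GameRecord:
    """One game: teams are disjoint nonempty player-id sets, outcome is the
    ranking of team indices (winner first)."""

    game_id: str
    seq: int
    teams: tuple[frozenset[str], ...]
    outcome: tuple[int, ...]

    def __post_init__(self):
        if self.seq < 0:
            raise GameValidationError(f"game {self.game_id!r}: seq must be >= 0")
        if len(self.teams) < 2:
            raise GameValidationError(f"game {self.game_id!r}: needs >= 2 teams")
        seen: set[str] = set()
        for members in self.teams:
            if not members:
                raise GameValidationError(f"game {self.game_id!r}: empty team")
            if seen & members:
                raise GameValidationError(
                    f"game {self.game_id!r}: overlapping teams "
                    f"(shared players {sorted(seen & members)})"
                )
            seen |= members
        if sorted(self.outcome) != list(range(len(self.teams))):
            raise GameValidationError(
                f"game {self.game_id!r}: outcome {self.outcome} is not a "
                f"permutation of team indices (ties are not allowed)"
            )

    @property
    def is_team_game(self) -> bool:
        """True iff at least one team has two or more members."""
        return any(len(t) >= 2 for t in self.teams)

    @property
    def players(self) -> frozenset[str]:
        return frozenset().union(*self.teams)

    @property
    def winning_team(self) -> frozenset[str]:
        return self.teams[self.outcome[0]]


@dataclass(frozen=True)
class HistoryEntry:
    seq: int
    game_id: str
    teammates: frozenset[str]
    team_game: bool
    won: bool
    experience: int  # 1-based ordinal count of games played so far


@dataclass(frozen=True)
class PlayerHistory:
    """A single player's games in chronological order; ``experience``
    increases by exactly 1 per entry."""

    player_id: str
    entries: tuple[HistoryEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def games_played(self) -> int:
        return len(self.entries)


def _record_from_json(obj: Mapping, line: int | None = None) -> GameRecord:
    try:
        teams = tuple(frozenset(map(str, t)) for t in obj["teams"])
        rec = GameRecord(
            game_id=str(obj["game_id"]),
            seq=int(obj["seq"]),
            teams=teams,
            outcome=tuple(int(i) for i in obj["outcome"]),
        )
    except GameValidationError as err:
        raise GameValidationError(str(err), line=line) from None
    except (KeyError, TypeError, ValueError) as err:
        raise GameValidationError(f"malformed game record: {err}", line=line) from None
    # a team given twice as an identical set collapses under the disjointness
    # check above only if literally equal; guard explicitly
    if len(teams) != len(obj["teams"]):
        raise GameValidationError("duplicate identical teams", line=line)
    return rec


def _read_jsonl(path) -> list[GameRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as err:
                raise GameValidationError(f"invalid JSON: {err}", line=lineno) from None
            records.append(_record_from_json(obj, line=lineno))
    return records


CSV_COLUMNS = ["game_id", "seq", "team_index", "player_id", "rank"]


def _read_csv(path) -> list[GameRecord]:
    # long format: one row per player-game; rows of one game may be anywhere
    # in the file, grouped by game_id
    games: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise GameValidationError(f"CSV missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                gid = row["game_id"]
                seq = int(row["seq"])
                ti = int(row["team_index"])
                rank = int(row["rank"])
                pid = row["player_id"]
            except (TypeError, ValueError) as err:
                raise GameValidationError(f"malformed row: {err}", line=lineno) from None
            if gid not in games:
                games[gid] = {"seq": seq, "teams": {}, "ranks": {}, "line": lineno}
                order.append(gid)
            g = games[gid]
            if g["seq"] != seq:
                raise GameValidationError(
                    f"game {gid!r}: inconsistent seq values", line=lineno
                )
            g["teams"].setdefault(ti, set()).add(pid)
            if g["ranks"].setdefault(ti, rank) != rank:
                raise GameValidationError(
                    f"game {gid!r}: inconsistent rank for team {ti}", line=lineno
                )
    records = []
    for gid in order:
        g = games[gid]
        indices = sorted(g["teams"])
        if indices != list(range(len(indices))):
            raise GameValidationError(
                f"game {gid!r}: team indices {indices} are not 0..k-1", line=g["line"]
            )
        ranks = g["ranks"]
        if sorted(ranks.values()) != list(range(len(indices))):
            raise GameValidationError(
                f"game {gid!r}: ranks {sorted(ranks.values())} are not a "
                f"permutation of 0..k-1",
                line=g["line"],
            )
        outcome = [None] * len(indices)
        for ti, rank in ranks.items():
            outcome[rank] = ti
        records.append(
            _record_from_json(
                {
                    "game_id": gid,
                    "seq": g["seq"],
                    "teams": [sorted(g["teams"][i]) for i in indices],
                    "outcome": outcome,
                },
                line=g["line"],
            )
        )
    return records


def read_games(path, format: str = "jsonl") -> list[GameRecord]:
    """Read a game stream; returns records in nondecreasing ``seq`` order.

    An out-of-order file is re-sorted (stably, so equal ``seq`` keeps file
    order) with a logged warning. Malformed input raises
    :class:`GameValidationError` carrying the offending line number.
    """
    if format == "jsonl":
        records = _read_jsonl(path)
    elif format == "csv":
        records = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")
    if any(b.seq < a.seq for a, b in zip(records, records[1:])):
        logger.warning("game stream %s not in seq order; re-sorting", path)
        records.sort(key=lambda r: r.seq)
    return records


def write_games(games: Iterable[GameRecord], path, format: str = "jsonl") -> None:
    """Write a game stream in the chosen dialect (team members sorted for
    deterministic output)."""
    games = list(games)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for g in games:
                fh.write(
                    json.dumps(
                        {
                            "game_id": g.game_id,
                            "seq": g.seq,
                            "teams": [sorted(t) for t in g.teams],
                            "outcome": list(g.outcome),
                        }
                    )
                    + "\n"
                )
    elif format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for g in games:
                rank_of = {ti: r for r, ti in enumerate(g.outcome)}
                for ti, members in enumerate(g.teams):
                    for pid in sorted(members):
                        writer.writerow([g.game_id, g.seq, ti, pid, rank_of[ti]])
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")


def build_histories(games: Iterable[GameRecord]) -> dict[str, PlayerHistory]:
    """Per-player chronological histories with 1-based experience counters.

    ``experience`` after a player's n-th game is n: the paper-style notion of
    experience as the running count of games played.
    """
    entries: dict[str, list[HistoryEntry]] = {}
    ordered = sorted(games, key=lambda g: g.seq)
    for g in ordered:
        team_game = g.is_team_game
        winners = g.winning_team
        for team in g.teams:
            for pid in team:
                lst = entries.setdefault(pid, [])
                lst.append(
                    HistoryEntry(
                        seq=g.seq,
                        game_id=g.game_id,
                        teammates=team - {pid},
                        team_game=team_game,
                        won=pid in winners,
                        experience=len(lst) + 1,
                    )
                )
    return {
        pid: PlayerHistory(player_id=pid, entries=tuple(lst))
        for pid, lst in entries.items()
    }
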