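"""Domain types and file I/O for agonistic-interaction datasets.

The pipeline's canonical inputs are two UTF-8 comma-delimited files with
header rows:

``animals.csv``
    ``animal_id,pen_id,sex,litter_id,parity,sire_id,initial_bw_kg,
    final_bw_kg,backtest_1,backtest_2``

``interactions.csv``
    ``pen_id,t_start_s,duration_s,actor_id,receiver_id,behavior,outcome``

Times are seconds since mixing (one canonical unit internally; hours are a
presentation-layer conversion).  Missing optional metadata (weights,
backtest counts) is encoded as an empty field and propagates as ``None``;
a missing *required* field rejects the row.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Sex",
    "Behavior",
    "Outcome",
    "AnimalMeta",
    "InteractionRecord",
    "Dataset",
    "DataValidationError",
    "read_animals",
    "read_interactions",
    "read_dataset",
    "write_animals",
    "write_interactions",
    "compute_adg",
    "OBSERVATION_WINDOW_S",
]

#: Length of the post-mixing observation window, in seconds (72 h).
OBSERVATION_WINDOW_S = 72 * 3600.0


class Sex(str, Enum):
    FEMALE = "female"
    BARROW = "barrow"


class Behavior(str, Enum):
    """Dyadic agonistic behavior classes.

    ``ACTIVE_ATTACK``  — biting, pushing, chasing in a fight.
    ``BEING_BULLIED``  — the receiver suffers bites/head-knocks and
    withdraws without retaliation.
    ``STANDOFF``       — mutual side-by-side head/neck display with no
    clear aggressor.
    """

    ACTIVE_ATTACK = "active_attack"
    BEING_BULLIED = "being_bullied"
    STANDOFF = "standoff"


class Outcome(str, Enum):
    ACTOR_WINS = "actor_wins"
    RECEIVER_WINS = "receiver_wins"
    DRAW = "draw"


class DataValidationError(ValueError):
    """Raised when an input file violates the dataset contract."""


@dataclass(frozen=True)
class AnimalMeta:
    """Per-animal metadata: housing, pedigree, weights and backtest counts."""

    animal_id: str
    pen_id: str
    sex: Sex
    litter_id: str
    parity: int
    sire_id: str
    initial_bw_kg: float | None = None
    final_bw_kg: float | None = None
    backtest_1: int | None = None
    backtest_2: int | None = None

    @property
    def backtest_mean(self) -> float | None:
        """Mean struggle count over the two backtest replicates.

        The backtest is administered twice; downstream statistics use the
        replicate mean as the animal's coping-style score.
        """
        if self.backtest_1 is None or self.backtest_2 is None:
            return None
        return (self.backtest_1 + self.backtest_2) / 2.0


@dataclass(frozen=True)
class InteractionRecord:
    """One dyadic agonistic event between two pen-mates."""

    pen_id: str
    t_start: float  # seconds since mixing
    duration_s: float
    actor_id: str
    receiver_id: str
    behavior: Behavior
    outcome: Outcome

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration_s

    @property
    def pair(self) -> frozenset[str]:
        """Unordered dyad identity, used for fight merging."""
        return frozenset((self.actor_id, self.receiver_id))

    def winner_loser(self) -> tuple[str, str] | None:
        """(winner, loser) for decided outcomes, ``None`` for draws."""
        if self.outcome is Outcome.ACTOR_WINS:
            return self.actor_id, self.receiver_id
        if self.outcome is Outcome.RECEIVER_WINS:
            return self.receiver_id, self.actor_id
        return None


@dataclass
class Dataset:
    """Validated animals plus interactions sorted by onset time.

    Sorting by ``t_start`` (stable on ties) is a precondition for the
    sequential rating updates; the constructor enforces it.
    """

    animals: list[AnimalMeta]
    interactions: list[InteractionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.animal_id for a in self.animals]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate animal_id(s): {dup}")
        by_pen: dict[str, set[Sex]] = {}
        for a in self.animals:
            by_pen.setdefault(a.pen_id, set()).add(a.sex)
        mixed = sorted(p for p, sexes in by_pen.items() if len(sexes) > 1)
        if mixed:
            raise DataValidationError(f"pens are not single-sex: {mixed}")
        known = {a.animal_id: a.pen_id for a in self.animals}
        for rec in self.interactions:
            for aid in (rec.actor_id, rec.receiver_id):
                if aid not in known:
                    raise DataValidationError(
                        f"interaction references unknown animal {aid!r}"
                    )
                if known[aid] != rec.pen_id:
                    raise DataValidationError(
                        f"animal {aid!r} does not belong to pen {rec.pen_id!r}"
                    )
            if rec.actor_id == rec.receiver_id:
                raise DataValidationError(
                    f"actor equals receiver ({rec.actor_id!r})"
                )
        # stable sort: equal-t_start records keep input order
        self.interactions = sorted(self.interactions, key=lambda r: r.t_start)

    @property
    def pens(self) -> list[str]:
        return sorted({a.pen_id for a in self.animals})

    def animals_in_pen(self, pen_id: str) -> list[AnimalMeta]:
        return sorted(
            (a for a in self.animals if a.pen_id == pen_id),
            key=lambda a: a.animal_id,
        )

    def interactions_in_pen(self, pen_id: str) -> list[InteractionRecord]:
        return [r for r in self.interactions if r.pen_id == pen_id]

    def with_interactions(self, records: Iterable[InteractionRecord]) -> "Dataset":
        return Dataset(animals=list(self.animals), interactions=list(records))


def compute_adg(meta: AnimalMeta, days: float = 3.0) -> float | None:
    """Average daily gain, kg/day, over the observation window.

    Returns ``None`` when either weight is missing, so the animal can be
    excluded from downstream statistics; negative gains are legitimate
    (pigs commonly lose weight in the days after mixing).
    """
    if days <= 0:
        raise ValueError("days must be positive")
    if meta.initial_bw_kg is None or meta.final_bw_kg is None:
        return None
    return (meta.final_bw_kg - meta.initial_bw_kg) / days


# ---------------------------------------------------------------------------
# File I/O

_ANIMAL_COLUMNS = [
    "animal_id", "pen_id", "sex", "litter_id", "parity", "sire_id",
    "initial_bw_kg", "final_bw_kg", "backtest_1", "backtest_2",
]
_INTERACTION_COLUMNS = [
    "pen_id", "t_start_s", "duration_s", "actor_id", "receiver_id",
    "behavior", "outcome",
]


def _require_columns(header: Sequence[str], required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")


def _opt_float(value: str, row_no: int, col: str, path) -> float | None:
    if value == "":
        return None
    try:
        x = float(value)
    except ValueError:
        raise DataValidationError(f"{path}: row {row_no}: malformed {col} {value!r}")
    if not math.isfinite(x) or x < 0:
        raise DataValidationError(f"{path}: row {row_no}: {col} must be finite nonnegative")
    return x


def _opt_int(value: str, row_no: int, col: str, path) -> int | None:
    if value == "":
        return None
    try:
        x = int(value)
    except ValueError:
        raise DataValidationError(f"{path}: row {row_no}: malformed {col} {value!r}")
    if x < 0:
        raise DataValidationError(f"{path}: row {row_no}: {col} must be nonnegative")
    return x


def read_animals(path) -> list[AnimalMeta]:
    """Read the animal metadata table.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"no such file: {path}")
    animals: list[AnimalMeta] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], _ANIMAL_COLUMNS, path)
        for row_no, row in enumerate(reader, start=1):
            for col in ("animal_id", "pen_id", "litter_id", "sire_id"):
                if not row[col]:
                    raise DataValidationError(f"{path}: row {row_no}: empty {col}")
            try:
                sex = Sex(row["sex"])
            except ValueError:
                raise DataValidationError(
                    f"{path}: row {row_no}: unknown sex {row['sex']!r}"
                )
            parity = _opt_int(row["parity"], row_no, "parity", path)
            if parity is None:
                raise DataValidationError(f"{path}: row {row_no}: empty parity")
            animals.append(
                AnimalMeta(
                    animal_id=row["animal_id"],
                    pen_id=row["pen_id"],
                    sex=sex,
                    litter_id=row["litter_id"],
                    parity=parity,
                    sire_id=row["sire_id"],
                    initial_bw_kg=_opt_float(row["initial_bw_kg"], row_no, "initial_bw_kg", path),
                    final_bw_kg=_opt_float(row["final_bw_kg"], row_no, "final_bw_kg", path),
                    backtest_1=_opt_int(row["backtest_1"], row_no, "backtest_1", path),
                    backtest_2=_opt_int(row["backtest_2"], row_no, "backtest_2", path),
                )
            )
    return animals


def read_interactions(path, animals: Iterable[AnimalMeta]) -> Dataset:
    """Read the interaction log and return a validated, time-sorted Dataset.

    Rejects (naming the 1-based data row) malformed times or durations,
    actor==receiver rows, unknown behavior/outcome labels, and references
    to animals absent from ``animals``.
    """
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"no such file: {path}")
    animals = list(animals)
    known = {a.animal_id for a in animals}
    records: list[InteractionRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], _INTERACTION_COLUMNS, path)
        for row_no, row in enumerate(reader, start=1):
            try:
                t_start = float(row["t_start_s"])
                duration = float(row["duration_s"])
            except ValueError:
                raise DataValidationError(
                    f"{path}: row {row_no}: malformed time field"
                )
            if not (math.isfinite(t_start) and t_start >= 0):
                raise DataValidationError(
                    f"{path}: row {row_no}: t_start_s must be finite nonnegative"
                )
            if not (math.isfinite(duration) and duration > 0):
                raise DataValidationError(
                    f"{path}: row {row_no}: duration_s must be positive"
                )
            actor, receiver = row["actor_id"], row["receiver_id"]
            if actor == receiver:
                raise DataValidationError(
                    f"{path}: row {row_no}: actor equals receiver ({actor!r})"
                )
            for aid in (actor, receiver):
                if aid not in known:
                    raise DataValidationError(
                        f"{path}: row {row_no}: unknown animal {aid!r}"
                    )
            try:
                behavior = Behavior(row["behavior"])
                outcome = Outcome(row["outcome"])
            except ValueError:
                raise DataValidationError(
                    f"{path}: row {row_no}: unknown behavior/outcome label"
                )
            records.append(
                InteractionRecord(
                    pen_id=row["pen_id"],
                    t_start=t_start,
                    duration_s=duration,
                    actor_id=actor,
                    receiver_id=receiver,
                    behavior=behavior,
                    outcome=outcome,
                )
            )
    return Dataset(animals=animals, interactions=records)


def read_dataset(interactions_path, animals_path) -> Dataset:
    return read_interactions(interactions_path, read_animals(animals_path))


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_animals(animals: Iterable[AnimalMeta], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_ANIMAL_COLUMNS)
        for a in animals:
            w.writerow([
                a.animal_id, a.pen_id, a.sex.value, a.litter_id, a.parity,
                a.sire_id, _fmt(a.initial_bw_kg), _fmt(a.final_bw_kg),
                _fmt(a.backtest_1), _fmt(a.backtest_2),
            ])


def write_interactions(records: Iterable[InteractionRecord], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_INTERACTION_COLUMNS)
        for r in records:
            w.writerow([
                r.pen_id, _fmt(r.t_start), _fmt(r.duration_s),
                r.actor_id, r.receiver_id, r.behavior.value, r.outcome.value,
            ])
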