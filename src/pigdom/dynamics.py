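"""Stability analyses on hourly Glicko trajectories: per-animal time to
social stability, emergence of the eventual top-ranked animal, and
hour-by-hour correlation of ratings with the final (hour-72) ratings."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glicko import GlickoState

__all__ = [
    "hourly_ranks",
    "stability_time",
    "stability_table",
    "first_rank_emergence",
    "hourly_final_correlation",
    "StabilityResult",
]


@dataclass(frozen=True)
class StabilityResult:
    animal_id: str
    pen_id: str
    stability_h: int
    definition: str  # "rank_fixation" or "rating_plateau"


def _ratings_table(states: Mapping[str, GlickoState]) -> pd.DataFrame:
    """hours x animals rating matrix from Glicko histories."""
    cols = {aid: st.ratings_series() for aid, st in sorted(states.items())}
    return pd.DataFrame(cols)


def hourly_ranks(states: Mapping[str, GlickoState]) -> pd.DataFrame:
    """Per-hour ranks (1 = highest rating), hours as rows, animals as
    columns.

    Ties are broken by the higher previous-hour rating (the initial
    rating for hour 1), then by animal id, so ranks at every hour are a
    full permutation 1..n.
    """
    ratings = _ratings_table(states)
    ids = list(ratings.columns)
    ranks = pd.DataFrame(index=ratings.index, columns=ids, dtype=int)
    prev_row = None
    for hour, row in ratings.iterrows():
        if prev_row is None:
            # before the first period every animal sat at the initial rating
            prev_vals = pd.Series(0.0, index=ids)
        else:
            prev_vals = prev_row
        order = sorted(ids, key=lambda a: (-row[a], -prev_vals[a], a))
        for pos, aid in enumerate(order, start=1):
            ranks.loc[hour, aid] = pos
        prev_row = row
    return ranks


def stability_time(rank_table: pd.DataFrame, animal_id: str) -> int:
    """Smallest hour h such that the animal's rank is identical at every
    hour from h through the final hour (rank fixation).

    1 when the rank never changes; the final hour when the last change
    happens there.
    """
    col = rank_table[animal_id].to_numpy()
    h = len(col)  # hours are 1..len
    while h > 1 and col[h - 2] == col[h - 1]:
        h -= 1
    return h


def _plateau_time(ratings: pd.Series, eps: float) -> int:
    vals = ratings.to_numpy()
    h = len(vals)
    while h > 1 and abs(vals[h - 1] - vals[h - 2]) < eps:
        h -= 1
    return h


def stability_table(
    states_by_pen: Mapping[str, Mapping[str, GlickoState]],
    definition: str = "rank_fixation",
    plateau_eps: float = 10.0,
) -> pd.DataFrame:
    """Time to social stability for every animal in every pen.

    ``rank_fixation`` (primary definition): the hour from which the
    animal's within-pen rank no longer changes.  ``rating_plateau``
    (sensitivity alternative): the hour from which consecutive rating
    changes stay below ``plateau_eps`` points.
    """
    if definition not in ("rank_fixation", "rating_plateau"):
        raise ValueError(f"unknown stability definition {definition!r}")
    rows = []
    for pen_id, states in sorted(states_by_pen.items()):
        if definition == "rank_fixation":
            ranks = hourly_ranks(states)
            for aid in ranks.columns:
                rows.append(
                    {"animal_id": aid, "pen_id": pen_id,
                     "stability_h": stability_time(ranks, aid)}
                )
        else:
            for aid, st in sorted(states.items()):
                rows.append(
                    {"animal_id": aid, "pen_id": pen_id,
                     "stability_h": _plateau_time(st.ratings_series(), plateau_eps)}
                )
    return pd.DataFrame(rows, columns=["animal_id", "pen_id", "stability_h"])


def first_rank_emergence(rank_table: pd.DataFrame) -> tuple[str, int]:
    """(animal, hour): the final-hour top animal and the hour from which
    it holds rank 1 continuously through the end."""
    final_hour = rank_table.index[-1]
    top = rank_table.loc[final_hour].idxmin()
    col = rank_table[top].to_numpy()
    h = len(col)
    while h > 1 and col[h - 2] == 1:
        h -= 1
    return str(top), h


def hourly_final_correlation(
    states: Mapping[str, GlickoState], subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Spearman correlation between each hour's ratings and the final
    hour's ratings across ``subset`` (all animals by default).

    Needs at least three animals.  Hours where either vector is constant
    have undefined rho and are reported as missing (NaN, not
    significant).  Returns columns hour, rho, p_value, significant.
    """
    ratings = _ratings_table(states)
    if subset is not None:
        ratings = ratings[list(subset)]
    if ratings.shape[1] < 3:
        raise ValueError("correlation needs at least 3 animals")
    final = ratings.iloc[-1].to_numpy()
    rows = []
    for hour, row in ratings.iterrows():
        x = row.to_numpy()
        if np.all(x == x[0]) or np.all(final == final[0]):
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(x, final)
        rows.append(
            {"hour": int(hour), "rho": rho, "p_value": p,
             "significant": bool(p < 0.05) if np.isfinite(p) else False}
        )
    return pd.DataFrame(rows, columns=["hour", "rho", "p_value", "significant"])
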