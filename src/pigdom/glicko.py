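"""Glicko-1 ratings with rating deviations, updated in fixed rating
periods (hour buckets by default, matching the hourly trajectory plots).

Glicko extends Elo by carrying a per-individual rating deviation RD, the
standard error of the current rating.  All games inside one rating
period are aggregated into a single update per individual, computed from
opponents' pre-period ratings and deviations:

    q      = ln(10) / 400
    g(RD)  = 1 / sqrt(1 + 3 q^2 RD^2 / pi^2)
    E      = 1 / (1 + 10^(-g(RD_j) (r - r_j) / 400))
    d^2    = [ q^2 sum_j g(RD_j)^2 E_j (1 - E_j) ]^(-1)
    r'     = r + q / (1/RD^2 + 1/d^2) * sum_j g(RD_j) (s_j - E_j)
    RD'    = sqrt( (1/RD^2 + 1/d^2)^(-1) )

RD shrinks with every game played and, with the inactivity-inflation
constant c = 0 (the default here), never grows, so trajectories are
deterministic functions of the interaction record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import Dataset, Outcome

__all__ = ["GlickoParams", "GlickoState", "glicko_period_update", "glicko_hourly"]

Q = math.log(10.0) / 400.0


@dataclass(frozen=True)
class GlickoParams:
    initial_rating: float = 2200.0
    initial_rd: float = 300.0
    rd_floor: float = 30.0          # lower bound on RD (certainty never degenerates)
    c: float = 0.0                  # per-period RD inflation for inactive individuals
    period_s: float = 3600.0
    draw_mode: str = "exclude"      # "exclude" or "half" (draws enter as score 0.5)

    def __post_init__(self):
        if self.initial_rd <= 0 or self.rd_floor <= 0 or self.period_s <= 0:
            raise ValueError("initial_rd, rd_floor and period_s must be positive")
        if self.c < 0:
            raise ValueError("c must be nonnegative")
        if self.draw_mode not in ("exclude", "half"):
            raise ValueError(f"unknown draw_mode {self.draw_mode!r}")


@dataclass
class GlickoState:
    """Current rating/deviation plus the per-period history
    ``(period index, rating, rd)``."""

    animal_id: str
    rating: float
    rd: float
    history: list[tuple[int, float, float]] = field(default_factory=list)

    def ratings_series(self) -> pd.Series:
        idx = pd.Index([h[0] for h in self.history], name="hour")
        return pd.Series([h[1] for h in self.history], index=idx, name=self.animal_id)


def _g(rd: float) -> float:
    return 1.0 / math.sqrt(1.0 + 3.0 * Q * Q * rd * rd / math.pi**2)


def _expected(r: float, r_j: float, rd_j: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (-_g(rd_j) * (r - r_j) / 400.0))


def glicko_period_update(
    states: dict[str, GlickoState],
    period_results: Sequence[tuple[str, str, float]],
    params: GlickoParams = GlickoParams(),
) -> dict[str, GlickoState]:
    """One rating-period update for every individual in ``states``.

    ``period_results`` lists the period's games as ``(a, b, score_a)``
    with score 1 (a won), 0 (b won) or 0.5 (draw).  All updates use the
    opponents' pre-period ratings and deviations, so the game order
    within a period is irrelevant.  Individuals with no games keep their
    rating; their RD inflates by c per period (capped at the initial RD).
    Returns a new state dict; inputs are not mutated.
    """
    games: dict[str, list[tuple[float, float, float]]] = {aid: [] for aid in states}
    for a, b, score_a in period_results:
        if a not in states or b not in states:
            missing = a if a not in states else b
            raise KeyError(f"result references unknown id {missing!r}")
        games[a].append((states[b].rating, states[b].rd, score_a))
        games[b].append((states[a].rating, states[a].rd, 1.0 - score_a))

    out: dict[str, GlickoState] = {}
    for aid, st in states.items():
        gl = games[aid]
        if not gl:
            rd_new = min(
                math.sqrt(st.rd * st.rd + params.c * params.c), params.initial_rd
            )
            out[aid] = GlickoState(aid, st.rating, max(rd_new, params.rd_floor),
                                   list(st.history))
            continue
        d2_inv = 0.0
        delta_sum = 0.0
        for r_j, rd_j, s_j in gl:
            e = _expected(st.rating, r_j, rd_j)
            g_j = _g(rd_j)
            d2_inv += Q * Q * g_j * g_j * e * (1.0 - e)
            delta_sum += g_j * (s_j - e)
        denom = 1.0 / (st.rd * st.rd) + d2_inv
        r_new = st.rating + (Q / denom) * delta_sum
        rd_new = max(math.sqrt(1.0 / denom), params.rd_floor)
        out[aid] = GlickoState(aid, r_new, rd_new, list(st.history))
    return out


def glicko_hourly(
    dataset: Dataset,
    pen_id: str,
    params: GlickoParams = GlickoParams(),
    n_periods: int | None = None,
) -> dict[str, GlickoState]:
    """Hourly Glicko trajectories for one pen over the observation window.

    Interactions are bucketed into consecutive rating periods of
    ``params.period_s`` seconds (72 one-hour periods by default) and each
    bucket is applied with :func:`glicko_period_update`; empty buckets
    leave ratings unchanged under c = 0.  Draws are excluded or scored
    0.5 according to ``params.draw_mode``.  Each state's history holds
    one ``(period, rating, rd)`` entry per period, periods numbered from
    1.
    """
    members = dataset.animals_in_pen(pen_id)
    records = dataset.interactions_in_pen(pen_id)
    if n_periods is None:
        horizon = max([r.t_end for r in records], default=0.0)
        from .io import OBSERVATION_WINDOW_S

        horizon = max(horizon, OBSERVATION_WINDOW_S)
        n_periods = int(math.ceil(horizon / params.period_s))

    buckets: dict[int, list[tuple[str, str, float]]] = {}
    for rec in records:
        if rec.outcome is Outcome.DRAW:
            if params.draw_mode == "exclude":
                continue
            result = (rec.actor_id, rec.receiver_id, 0.5)
        else:
            winner, loser = rec.winner_loser()
            result = (winner, loser, 1.0)
        period = min(int(rec.t_start // params.period_s), n_periods - 1)
        buckets.setdefault(period, []).append(result)

    states = {
        a.animal_id: GlickoState(a.animal_id, params.initial_rating, params.initial_rd)
        for a in members
    }
    for period in range(n_periods):
        states = glicko_period_update(states, buckets.get(period, []), params)
        for st in states.values():
            st.history.append((period + 1, st.rating, st.rd))
    return states


def histories_frame(states: Iterable[GlickoState]) -> pd.DataFrame:
    """Long-format table (animal_id, hour, rating, rd)."""
    rows = [
        {"animal_id": st.animal_id, "hour": h, "rating": r, "rd": rd}
        for st in states
        for h, r, rd in st.history
    ]
    return pd.DataFrame(rows, columns=["animal_id", "hour", "rating", "rd"])
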