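"""Sequential Elo ratings from decided agonistic interactions.

Every animal starts at the same rating; after each decided interaction
the winner gains and the loser loses the same number of points, k scaled
by the surprise of the outcome: a win by the higher-rated animal moves
ratings by (1 - p) * k, an upset by p * k, where p is the expected win
probability of the *higher*-rated opponent.  Updates are therefore
exactly zero-sum within a pen, and the whole trajectory depends on the
temporal order of interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy.special import ndtr

from .io import Dataset

__all__ = ["EloParams", "RatingTrajectory", "expected_score", "elo_update", "elo_sequence"]


@dataclass(frozen=True)
class EloParams:
    """k: points at stake per interaction; expected-score model maps the
    rating difference to the favourite's win probability (``normal_cdf``:
    p = Phi(diff / 200); ``logistic``: p = 1 / (1 + 10^(-diff / 400)))."""

    k: float = 100.0
    initial_rating: float = 1000.0
    expected_score_model: str = "normal_cdf"

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.expected_score_model not in ("normal_cdf", "logistic"):
            raise ValueError(f"unknown model {self.expected_score_model!r}")


@dataclass
class RatingTrajectory:
    """Time-stamped rating samples for one animal; the first sample (at
    t = 0) is the initial rating."""

    animal_id: str
    samples: list[tuple[float, float]] = field(default_factory=list)

    @property
    def final_rating(self) -> float:
        return self.samples[-1][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["t_s", "rating"]).assign(
            animal_id=self.animal_id
        )


def expected_score(
    r_high: float, r_low: float, model: str = "normal_cdf"
) -> float:
    """Win probability of the higher-rated opponent, in [0.5, 1]."""
    if r_high < r_low:
        raise ValueError("r_high must be >= r_low")
    diff = r_high - r_low
    if model == "normal_cdf":
        return float(ndtr(diff / 200.0))
    if model == "logistic":
        return 1.0 / (1.0 + 10.0 ** (-diff / 400.0))
    raise ValueError(f"unknown model {model!r}")


def elo_update(
    r_winner: float, r_loser: float, params: EloParams = EloParams()
) -> tuple[float, float]:
    """One decided interaction: returns the post-interaction ratings.

    Equal pre-interaction ratings take the favourite-wins branch; the two
    branches coincide there since p = 0.5.
    """
    if r_winner >= r_loser:
        p = expected_score(r_winner, r_loser, params.expected_score_model)
        delta = (1.0 - p) * params.k
    else:
        p = expected_score(r_loser, r_winner, params.expected_score_model)
        delta = p * params.k
    return r_winner + delta, r_loser - delta


def elo_sequence(
    dataset: Dataset, pen_id: str, params: EloParams = EloParams()
) -> dict[str, RatingTrajectory]:
    """Replay a pen's decided interactions in time order.

    Draws are skipped entirely.  Returns one trajectory per pen member;
    animals never involved in a decided interaction stay flat at the
    initial rating.
    """
    ratings = {
        a.animal_id: params.initial_rating for a in dataset.animals_in_pen(pen_id)
    }
    traj = {
        aid: RatingTrajectory(aid, [(0.0, params.initial_rating)])
        for aid in ratings
    }
    for rec in dataset.interactions_in_pen(pen_id):
        wl = rec.winner_loser()
        if wl is None:
            continue
        winner, loser = wl
        ratings[winner], ratings[loser] = elo_update(
            ratings[winner], ratings[loser], params
        )
        traj[winner].samples.append((rec.t_start, ratings[winner]))
        traj[loser].samples.append((rec.t_start, ratings[loser]))
    return traj


def trajectories_frame(trajectories: Iterable[RatingTrajectory]) -> pd.DataFrame:
    """Long-format table (animal_id, t_s, rating) across trajectories."""
    frames = [t.to_frame() for t in trajectories]
    return pd.concat(frames, ignore_index=True)[["animal_id", "t_s", "rating"]]
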