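"""Per-pen win/loss frequency sociomatrices and their binarized
dominance form (winners in rows, losers in columns)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import InteractionRecord

__all__ = ["Sociomatrix", "BinaryDominanceMatrix", "build_sociomatrix", "binarize"]


@dataclass(frozen=True)
class Sociomatrix:
    """W[i, j] = number of decided interactions in which i beat j."""

    pen_id: str
    ids: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.W)
        n = len(self.ids)
        if W.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(W < 0):
            raise ValueError("counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class BinaryDominanceMatrix:
    """B[i, j] = 1 iff i won the dyad against j more often than it lost;
    tied dyads (including never-interacted) are 0 both ways."""

    pen_id: str
    ids: tuple[str, ...]
    B: np.ndarray

    def __post_init__(self):
        B = np.asarray(self.B)
        n = len(self.ids)
        if B.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.all((B == 0) | (B == 1)):
            raise ValueError("entries must be 0/1")
        if np.any((B == 1) & (B.T == 1)):
            raise ValueError("mutual dominance is contradictory")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.B, index=list(self.ids), columns=list(self.ids))


def build_sociomatrix(
    records: Iterable[InteractionRecord],
    pen_id: str,
    ids: Sequence[str],
) -> Sociomatrix:
    """Tally decided wins per ordered pair for one pen.

    Draws (and standoffs without a winner) contribute nothing.  Row/column
    order is the stable sort of ``ids`` so that results do not depend on
    input ordering.
    """
    ids = tuple(sorted(ids))
    if not ids:
        raise ValueError(f"pen {pen_id!r} has no animals")
    pos = {aid: i for i, aid in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)), dtype=int)
    for r in records:
        if r.pen_id != pen_id:
            continue
        wl = r.winner_loser()
        if wl is None:
            continue
        winner, loser = wl
        W[pos[winner], pos[loser]] += 1
    return Sociomatrix(pen_id=pen_id, ids=ids, W=W)


def binarize(m: Sociomatrix) -> BinaryDominanceMatrix:
    """1/0 dominance matrix: the more frequent winner of each dyad gets 1;
    tied dyads (equal counts, including 0 = 0) get 0 in both cells."""
    B = (m.W > m.W.T).astype(int)
    return BinaryDominanceMatrix(pen_id=m.pen_id, ids=m.ids, B=B)
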