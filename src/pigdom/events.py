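"""Fight validity filtering, same-pair fight merging, and per-animal
dyadic behavior summaries.

Two observational conventions are enforced before any hierarchy index is
computed: a fight must last at least 3 s to count, and two fights between
the same pair of pigs must be separated by at least 8 s (end-to-start);
closer events are bouts of a single fight and are merged.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AnimalMeta, Behavior, InteractionRecord

__all__ = ["filter_and_merge_fights", "summarize_dyadic", "DYADIC_COLUMNS"]

#: Raw and log-transformed dyadic indicator columns, in output order.
DYADIC_COLUMNS = [
    "DAA", "DSO", "DBB", "FAA", "FSO", "FBB",
    "lgDAA", "lgDSO", "lgDBB", "lgFAA", "lgFSO", "lgFBB",
]


def filter_and_merge_fights(
    records: Sequence[InteractionRecord],
    min_dur_s: float = 3.0,
    merge_gap_s: float = 8.0,
) -> list[InteractionRecord]:
    """Drop sub-threshold fights, then merge same-pair fights closer than
    ``merge_gap_s``.

    Merging is applied transitively left-to-right on the time-sorted
    stream: whenever the next event of the same unordered pair (within the
    same pen) starts less than ``merge_gap_s`` after the previous one
    ends, the two become one event spanning both, with behavior and
    outcome taken from the last constituent.  With ``min_dur_s = 0`` and
    ``merge_gap_s = 0`` the operation is the identity.
    """
    kept = [r for r in records if r.duration_s >= min_dur_s]
    merged: list[InteractionRecord] = []
    # open fight per (pen, unordered pair)
    open_idx: dict[tuple[str, frozenset[str]], int] = {}
    for rec in kept:
        key = (rec.pen_id, rec.pair)
        i = open_idx.get(key)
        if i is not None and rec.t_start - merged[i].t_end < merge_gap_s:
            prev = merged[i]
            span_end = max(prev.t_end, rec.t_end)
            merged[i] = replace(
                rec,
                t_start=prev.t_start,
                duration_s=span_end - prev.t_start,
            )
        else:
            open_idx[key] = len(merged)
            merged.append(rec)
    return merged


def _log10p1(x: np.ndarray) -> np.ndarray:
    # log10(x + 1): keeps zero-activity animals defined at 0
    return np.log10(np.asarray(x, dtype=float) + 1.0)


def summarize_dyadic(
    records: Iterable[InteractionRecord],
    animals: Iterable[AnimalMeta],
) -> pd.DataFrame:
    """Per-animal totals of the six dyadic behavior indicators.

    Accrual rules per event:

    * ``active_attack`` — the actor accrues attack duration/count
      (DAA/FAA); the receiver accrues being-bullied duration/count
      (DBB/FBB).
    * ``being_bullied`` — the receiver accrues DBB/FBB (the withdrawal
      without retaliation is what defines the class, so only the
      receiving side is summarised).
    * ``standoff`` — symmetric by definition; both participants accrue
      DSO/FSO.

    Durations are seconds; ``lg*`` columns are log10(x + 1) of the raw
    fields, the transform used for all downstream statistics.  Animals
    with no events get all-zero rows.

    Returns a DataFrame indexed by ``animal_id`` with the 12 columns of
    :data:`DYADIC_COLUMNS`.
    """
    ids = sorted(a.animal_id for a in animals)
    out = pd.DataFrame(
        0.0, index=pd.Index(ids, name="animal_id"), columns=DYADIC_COLUMNS[:6]
    )
    for r in records:
        if r.behavior is Behavior.ACTIVE_ATTACK:
            out.loc[r.actor_id, "DAA"] += r.duration_s
            out.loc[r.actor_id, "FAA"] += 1
            out.loc[r.receiver_id, "DBB"] += r.duration_s
            out.loc[r.receiver_id, "FBB"] += 1
        elif r.behavior is Behavior.BEING_BULLIED:
            out.loc[r.receiver_id, "DBB"] += r.duration_s
            out.loc[r.receiver_id, "FBB"] += 1
        else:  # standoff
            for aid in (r.actor_id, r.receiver_id):
                out.loc[aid, "DSO"] += r.duration_s
                out.loc[aid, "FSO"] += 1
    for col in DYADIC_COLUMNS[:6]:
        out["lg" + col] = _log10p1(out[col].to_numpy())
    return out
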