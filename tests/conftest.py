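from __future__ import annotations

import pytest

from pigdom.io import (
    AnimalMeta,
    Behavior,
    Dataset,
    InteractionRecord,
    Outcome,
    Sex,
)


def make_animals(ids, pen="P", sex=Sex.FEMALE, **kwargs):
    defaults = dict(
        litter_id="L1", parity=2, sire_id="S1",
        initial_bw_kg=9.0, final_bw_kg=9.5, backtest_1=2, backtest_2=4,
    )
    defaults.update(kwargs)
    return [AnimalMeta(animal_id=i, pen_id=pen, sex=sex, **defaults) for i in ids]


def rec(actor, receiver, t=0.0, dur=10.0, pen="P",
        behavior=Behavior.ACTIVE_ATTACK, outcome=Outcome.ACTOR_WINS):
    return InteractionRecord(
        pen_id=pen, t_start=t, duration_s=dur, actor_id=actor,
        receiver_id=receiver, behavior=behavior, outcome=outcome,
    )


@pytest.fixture
def trio_dataset():
    """Three pen-mates with a clear A > B > C structure."""
    animals = make_animals(["A", "B", "C"])
    inter = [
        rec("A", "B", t=10), rec("A", "B", t=100), rec("A", "C", t=200),
        rec("B", "C", t=300), rec("A", "B", t=400), rec("B", "A", t=500),
    ]
    return Dataset(animals=animals, interactions=inter)
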