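import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from pigdom.dynamics import (
    first_rank_emergence,
    hourly_final_correlation,
    hourly_ranks,
    stability_table,
    stability_time,
)
from pigdom.glicko import GlickoState


def states_from_matrix(ratings, ids=None, hours=None):
    """Build Glicko states from an hours x animals rating array."""
    ratings = np.asarray(ratings, dtype=float)
    ids = ids or [f"a{i}" for i in range(ratings.shape[1])]
    out = {}
    for j, aid in enumerate(ids):
        hist = [(h + 1, ratings[h, j], 50.0) for h in range(ratings.shape[0])]
        out[aid] = GlickoState(aid, ratings[-1, j], 50.0, hist)
    return out


class TestHourlyRanks:
    def test_distinct_ratings_rank_by_value(self):
        states = states_from_matrix([[2300, 2100, 2200]])
        ranks = hourly_ranks(states)
        assert list(ranks.loc[1]) == [1, 3, 2]

    def test_tie_broken_by_previous_hour_then_id(self):
        states = states_from_matrix([[2300, 2100, 2200], [2250, 2250, 2240]])
        ranks = hourly_ranks(states)
        # hour 2: a0 and a1 tie at 2250; a0 was higher at hour 1
        assert ranks.loc[2, "a0"] == 1 and ranks.loc[2, "a1"] == 2

    def test_matches_hand_ranked_table(self):
        mat = [[2200, 2210, 2190], [2250, 2180, 2205], [2100, 2260, 2230]]
        ranks = hourly_ranks(states_from_matrix(mat))
        expected = pd.DataFrame(
            [[2, 1, 3], [1, 3, 2], [3, 1, 2]],
            index=ranks.index, columns=["a0", "a1", "a2"],
        )
        assert (ranks == expected).all().all()


class TestStabilityTime:
    def test_constant_rank_is_hour_one(self):
        states = states_from_matrix([[2300, 2100]] * 5)
        ranks = hourly_ranks(states)
        assert stability_time(ranks, "a0") == 1

    def test_last_change_between_hours_five_and_six(self):
        mat = [[2300, 2100]] * 5 + [[2100, 2300]] * 4
        ranks = hourly_ranks(states_from_matrix(mat))
        assert stability_time(ranks, "a0") == 6

    def test_change_at_final_hour_gives_final_hour(self):
        mat = [[2300, 2100]] * 8 + [[2100, 2300]]
        ranks = hourly_ranks(states_from_matrix(mat))
        assert stability_time(ranks, "a0") == 9

    def test_matches_reverse_scan_oracle(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(2200, 60, (72, 6))
        ranks = hourly_ranks(states_from_matrix(mat))
        for aid in ranks.columns:
            col = ranks[aid].to_numpy()
            expected = 72
            for h in range(72, 1, -1):
                if col[h - 2] != col[71]:
                    break
                expected = h - 1
            if (col == col[71]).all():
                expected = 1
            assert stability_time(ranks, aid) == expected

    def test_freezing_from_hour_h_bounds_stability(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(2200, 60, (72, 5))
        h_freeze = 30
        mat[h_freeze - 1:] = mat[h_freeze - 1]
        ranks = hourly_ranks(states_from_matrix(mat))
        for aid in ranks.columns:
            assert stability_time(ranks, aid) <= h_freeze


class TestFirstRankEmergence:
    def test_leader_from_hour_three(self):
        mat = [[2100, 2300], [2150, 2250], [2400, 2200], [2380, 2150]]
        top, h = first_rank_emergence(hourly_ranks(states_from_matrix(mat)))
        assert (top, h) == ("a0", 3)

    def test_wire_to_wire_leader_gives_one(self):
        mat = [[2300, 2100]] * 10
        top, h = first_rank_emergence(hourly_ranks(states_from_matrix(mat)))
        assert (top, h) == ("a0", 1)

    def test_late_takeover(self):
        mat = [[2100, 2300]] * 54 + [[2400, 2200]] * 18
        top, h = first_rank_emergence(hourly_ranks(states_from_matrix(mat)))
        assert (top, h) == ("a0", 55)


class TestHourlyFinalCorrelation:
    def test_final_hour_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        states = states_from_matrix(rng.normal(2200, 80, (10, 5)))
        corr = hourly_final_correlation(states)
        assert corr.iloc[-1]["rho"] == pytest.approx(1.0)
        assert corr.iloc[-1]["significant"]

    def test_degenerate_subset_rejected(self):
        states = states_from_matrix(np.full((5, 3), 2200.0))
        with pytest.raises(ValueError, match="at least 3"):
            hourly_final_correlation(states, subset=["a0", "a1"])

    def test_constant_hour_reported_missing(self):
        mat = np.vstack([np.full((1, 4), 2200.0), [[2300, 2250, 2150, 2100]]])
        corr = hourly_final_correlation(states_from_matrix(mat))
        assert np.isnan(corr.iloc[0]["rho"]) and not corr.iloc[0]["significant"]

    def test_matches_independent_rho(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(2200, 80, (6, 8))
        states = states_from_matrix(mat)
        corr = hourly_final_correlation(states)
        for h in range(6):
            rho, p = spearmanr(mat[h], mat[-1])
            assert corr.iloc[h]["rho"] == pytest.approx(rho)
            assert corr.iloc[h]["p_value"] == pytest.approx(p)


class TestStabilityTable:
    def test_both_definitions_cover_all_animals(self):
        rng = np.random.default_rng(4)
        pens = {
            "P1": states_from_matrix(rng.normal(2200, 60, (72, 4))),
            "P2": states_from_matrix(rng.normal(2200, 60, (72, 5))),
        }
        for definition in ("rank_fixation", "rating_plateau"):
            t = stability_table(pens, definition)
            assert len(t) == 9
            assert t["stability_h"].between(1, 72).all()

    def test_unknown_definition_rejected(self):
        with pytest.raises(ValueError, match="definition"):
            stability_table({}, "vibes")
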