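"""Prediction stage: combination table, headline percentages, Spearman."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from izof import (
    COMBINATION_ORDER,
    CombinationTable,
    Cohort,
    EstimabilityError,
    Phase,
    Zone,
    ZoneSet,
    at_least_k_in,
    combination_table,
    distance_score_dataset,
    estimate_zones,
    membership_tally,
    spearman,
)

from conftest import make_occ, oracle_midranks, oracle_spearman

#: Published pattern counts (SA, CA, SC order, all-in first, all-out last).
TABLE3_COUNTS = (14, 1, 2, 1, 1, 0, 1, 10)


def _zoneset(pid, ca=(18, 22), sa=(18, 22), sc=(18, 22)):
    def z(bounds):
        lo, hi = bounds
        return Zone(center=(lo + hi) / 2, half_width=(hi - lo) / 2)

    return ZoneSet(participant_id=pid, ca=z(ca), sa=z(sa), sc=z(sc),
                   n_occasions_used=4)


class TestCombinationTable:
    def test_empty_predicted_set_gives_blank_rows(self):
        table = combination_table([], {})
        assert len(table.summary) == 8
        assert (table.summary["n"] == 0).all()
        assert table.summary["mean"].isna().all()

    def test_patterns_partition_and_percentages_count(self):
        zonesets = {p: _zoneset(p) for p in ("a", "b", "c")}
        occs = [
            make_occ("a", "J1", 93.0, ca=20, sa=20, sc=20, phase=Phase.PREDICTED),
            make_occ("b", "J1", 94.0, ca=20, sa=20, sc=20, phase=Phase.PREDICTED),
            make_occ("c", "J1", 85.0, ca=30, sa=9, sc=36, phase=Phase.PREDICTED),
        ]
        table = combination_table(occs, zonesets)
        ns = table.summary["n"].tolist()
        assert ns == [2, 0, 0, 0, 0, 0, 0, 1]
        assert table.summary["pct"][0] == pytest.approx(200 / 3)
        assert table.summary["pct"][7] == pytest.approx(100 / 3)
        assert table.summary["n"].sum() == 3
        assert table.summary["mean"][0] == pytest.approx(93.5)

    def test_below_and_above_both_collapse_to_out(self):
        zonesets = {"a": _zoneset("a")}
        below = make_occ("a", "J1", 90.0, ca=10, phase=Phase.PREDICTED)
        above = make_occ("a", "J2", 90.0, ca=35, phase=Phase.PREDICTED)
        for occ in (below, above):
            t = combination_table([occ], zonesets)
            assert t.assignments["ca"].iloc[0] == "Out"

    def test_missing_zoneset_raises(self):
        occ = make_occ("nobody", "J1", 90.0, phase=Phase.PREDICTED)
        with pytest.raises(EstimabilityError, match="nobody"):
            combination_table([occ], {})

    @given(
        st.lists(
            st.tuples(
                st.integers(9, 36), st.integers(9, 36), st.integers(9, 36),
                st.integers(60, 100),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_n_column_always_sums_to_cohort_size(self, rows):
        zonesets = {}
        occs = []
        for i, (ca, sa, sc, score) in enumerate(rows):
            pid = f"p{i}"
            zonesets[pid] = _zoneset(pid)
            occs.append(
                make_occ(pid, "J1", float(score), ca=ca, sa=sa, sc=sc,
                         phase=Phase.PREDICTED)
            )
        table = combination_table(occs, zonesets)
        assert int(table.summary["n"].sum()) == len(rows)
        assert table.summary["pct"].sum() == pytest.approx(100.0)


class TestPublishedCounts:
    def test_published_counts_reproduce_headline_percentages(self):
        table = CombinationTable.from_counts(TABLE3_COUNTS)
        assert table.summary["pct"][0] == pytest.approx(46.7, abs=0.05)
        assert table.summary["pct"][7] == pytest.approx(100 / 3)
        assert at_least_k_in(table, 2) == pytest.approx(60.0)
        assert at_least_k_in(table, 3) == pytest.approx(46.7, abs=0.05)
        assert at_least_k_in(table, 0) == 100.0

    def test_score_floor_filters_individuals(self):
        scores = [[93.0] * 14, [95.0], [92.0, 91.0], [90.0],
                  [96.0], None, [88.0], [86.0] * 10]
        table = CombinationTable.from_counts(TABLE3_COUNTS, scores=scores)
        assert at_least_k_in(table, 2, score_floor=90.0) == pytest.approx(60.0)
        assert at_least_k_in(table, 0, score_floor=95.0) == pytest.approx(
            100.0 * 2 / 30
        )


class TestMembershipTally:
    def test_trichotomy_retained(self):
        zonesets = {"a": _zoneset("a"), "b": _zoneset("b")}
        occs = [
            make_occ("a", "J1", 90.0, ca=10, sa=20, sc=35, phase=Phase.PREDICTED),
            make_occ("b", "J1", 90.0, ca=20, sa=25, sc=9, phase=Phase.PREDICTED),
        ]
        tally = membership_tally(occs, zonesets)
        ca = tally[tally["subscale"] == "ca"].iloc[0]
        assert (ca["n_below"], ca["n_in"], ca["n_above"]) == (1, 1, 0)
        sc = tally[tally["subscale"] == "sc"].iloc[0]
        assert (sc["n_below"], sc["n_above"]) == (1, 1)


class TestSpearman:
    def test_perfect_monotone_decrease(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert spearman([1, 2, 3], [1, 3, 2]).rho == pytest.approx(0.5)

    def test_tied_input_uses_midranks(self):
        assert oracle_midranks([0, 0, 1, 2]) == [1.5, 1.5, 3, 4]
        r = spearman([0, 0, 1, 2], [4, 3, 2, 1])
        assert r.rho == pytest.approx(oracle_spearman([0, 0, 1, 2], [4, 3, 2, 1]),
                                      abs=1e-12)

    def test_constant_vector_is_undefined(self):
        r = spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(r.rho) and math.isnan(r.p_value)

    def test_exact_permutation_p_extremes(self):
        r = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], method="exact")
        assert r.rho == pytest.approx(-1.0)
        # both perfectly increasing and decreasing arrangements hit |rho|=1
        assert r.p_value == pytest.approx(2 / math.factorial(5))

    def test_exact_and_t_approx_agree_on_rho(self):
        x = [3, 1, 4, 1, 5, 9, 2]
        y = [2, 7, 1, 8, 2, 8, 1]
        a = spearman(x, y)
        b = spearman(x, y, method="exact")
        assert a.rho == pytest.approx(b.rho, abs=1e-12)

    @given(
        st.lists(st.integers(0, 8), min_size=3, max_size=12),
        st.data(),
    )
    def test_matches_midrank_pearson_oracle(self, x, data):
        y = data.draw(
            st.lists(st.integers(0, 8), min_size=len(x), max_size=len(x))
        )
        if len(set(x)) == 1 or len(set(y)) == 1:
            assert math.isnan(spearman(x, y).rho)
        else:
            assert spearman(x, y).rho == pytest.approx(
                oracle_spearman(x, y), abs=1e-12
            )

    @given(st.lists(st.integers(0, 100), min_size=4, max_size=10, unique=True),
           st.data())
    def test_invariant_under_strictly_monotone_transforms(self, x, data):
        y = data.draw(
            st.lists(st.integers(0, 100), min_size=len(x), max_size=len(x))
        )
        if len(set(y)) == 1:
            return
        base = spearman(x, y).rho
        assert spearman([math.exp(v / 20) for v in x], y).rho == pytest.approx(
            base, abs=1e-12
        )
        assert spearman(x, [v ** 3 for v in y]).rho == pytest.approx(
            base, abs=1e-12
        )


class TestDistanceScoreDataset:
    def test_pair_count_and_all_in_zone_distances(self):
        zonesets = {p: _zoneset(p) for p in ("a", "b")}
        occs = [
            make_occ(p, "J1", 92.0, ca=20, sa=20, sc=20, phase=Phase.PREDICTED)
            for p in ("a", "b")
        ]
        ds = distance_score_dataset(occs, zonesets)
        assert len(ds) == 2 * 3
        assert (ds["distance"] == 0.0).all()

    def test_distance_penalised_cohort_has_negative_correlations(self):
        # deterministic construction: further from zone -> lower score
        zonesets = {}
        occs = []
        for i, ca in enumerate(range(10, 36, 5)):
            pid = f"p{i}"
            zonesets[pid] = _zoneset(pid, ca=(18, 22), sa=(9, 36), sc=(9, 36))
            dist = max(0, 18 - ca, ca - 22)
            occs.append(
                make_occ(pid, "J1", 95.0 - dist, ca=ca, phase=Phase.PREDICTED)
            )
        ds = distance_score_dataset(occs, zonesets)
        sub = ds[ds["subscale"] == "ca"]
        r = spearman(sub["distance"].tolist(), sub["score"].tolist())
        assert r.rho < 0
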