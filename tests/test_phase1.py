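"""Retrospective validity metrics: threshold, D statistic, classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from izof import (
    Cohort,
    EstimabilityError,
    Zone,
    build_cohort_tables,
    correct_classification,
    d_statistic,
    estimate_zones,
    outstanding_threshold,
)

from conftest import make_occ, oracle_correct_classification


class TestOutstandingThreshold:
    def test_printed_mean_and_sd_report_92(self):
        # two scores with pooled mean 88.98 and population SD 3.47
        th = outstanding_threshold([85.51, 92.45])
        assert th.mean == pytest.approx(88.98)
        assert th.sd == pytest.approx(3.47)
        assert th.value == pytest.approx(92.45)
        assert th.reported == 92

    def test_zero_variance_threshold_is_the_constant(self):
        th = outstanding_threshold([88.0, 88.0, 88.0])
        assert th.value == 88.0 == th.reported

    def test_mean_plus_one_sd(self):
        # mean 80, population SD 5
        th = outstanding_threshold([75.0, 85.0])
        assert th.value == pytest.approx(85.0)

    def test_round_modes(self):
        scores = [85.51, 92.45]
        assert outstanding_threshold(scores, round_mode="floor").reported == 92
        assert outstanding_threshold(scores, round_mode="none").reported == pytest.approx(92.45)

    def test_single_score_not_estimable(self):
        with pytest.raises(EstimabilityError):
            outstanding_threshold([90.0])


class TestDStatistic:
    zone = Zone(center=20.0, half_width=2.0)

    def _occs(self, pairs):
        return [
            make_occ("p", f"R{i}", s, ca=v) for i, (v, s) in enumerate(pairs)
        ]

    def test_in_minus_out_mean(self):
        # mean(92, 94) - mean(85, 87) = 93 - 86
        occs = self._occs([(20, 92.0), (21, 94.0), (25, 85.0), (15, 87.0)])
        d = d_statistic(occs, self.zone, "ca")
        assert d.d_value == pytest.approx(7.0)
        assert (d.n_in, d.n_out) == (2, 2)

    def test_one_sided_is_undefined(self):
        occs = self._occs([(20, 92.0), (21, 94.0)])
        d = d_statistic(occs, self.zone, "ca")
        assert math.isnan(d.d_value)
        assert d.n_out == 0 and not d.defined

    def test_maximum_printed_d(self):
        occs = self._occs([(20, 91.0), (26, 80.0)])
        assert d_statistic(occs, self.zone, "ca").d_value == pytest.approx(11.0)

    def test_antisymmetry_under_label_swap(self):
        occs = self._occs([(20, 92.0), (25, 85.0), (19, 90.0), (30, 88.0)])
        d = d_statistic(occs, self.zone, "ca")
        # complement zone: everything previously in is now out and vice versa
        flipped = [
            make_occ("p", f"S{i}", o.score,
                     ca=25 if o.triplet.ca in (19, 20, 21, 22) else 20)
            for i, o in enumerate(occs)
        ]
        d2 = d_statistic(flipped, self.zone, "ca")
        assert d2.d_value == pytest.approx(-d.d_value)


class TestCorrectClassification:
    zone = Zone(center=20.0, half_width=2.0)

    def test_full_concordance(self):
        occs = [make_occ("p", f"R{i}", 95.0, ca=20) for i in range(4)]
        assert correct_classification(occs, self.zone, "ca", 92.0) == 100.0

    def test_three_of_four_concordant(self):
        occs = [
            make_occ("p", "R1", 95.0, ca=20),  # outstanding, in  -> hit
            make_occ("p", "R2", 85.0, ca=30),  # ordinary, out    -> hit
            make_occ("p", "R3", 85.0, ca=19),  # ordinary, in     -> miss
            make_occ("p", "R4", 84.0, ca=27),  # ordinary, out    -> hit
        ]
        assert correct_classification(occs, self.zone, "ca", 92.0) == 75.0

    def test_score_exactly_at_threshold_counts_as_outstanding(self):
        occs = [make_occ("p", "R1", 92.0, ca=20), make_occ("p", "R2", 92.0, ca=30)]
        assert correct_classification(occs, self.zone, "ca", 92.0) == 50.0

    @given(
        st.lists(
            st.tuples(st.integers(9, 36), st.integers(60, 100)),
            min_size=1,
            max_size=10,
        ),
        st.randoms(use_true_random=False),
    )
    def test_matches_oracle_and_permutation_invariant(self, pairs, rnd):
        occs = [
            make_occ("p", f"R{i}", float(s), ca=v)
            for i, (v, s) in enumerate(pairs)
        ]
        got = correct_classification(occs, self.zone, "ca", 92.0)
        values = [v for v, _ in pairs]
        scores = [s for _, s in pairs]
        expect = oracle_correct_classification(
            values, scores, self.zone.lower, self.zone.upper, 92.0
        )
        assert got == pytest.approx(expect, abs=1e-12)
        shuffled = list(occs)
        rnd.shuffle(shuffled)
        assert correct_classification(shuffled, self.zone, "ca", 92.0) == got

    def test_threshold_above_all_scores_gives_out_of_zone_fraction(self):
        occs = [
            make_occ("p", "R1", 90.0, ca=20),
            make_occ("p", "R2", 91.0, ca=30),
            make_occ("p", "R3", 89.0, ca=31),
            make_occ("p", "R4", 88.0, ca=17),
        ]
        got = correct_classification(occs, self.zone, "ca", 1000.0)
        assert got == 75.0  # 3 of 4 out of zone


class TestCohortTables:
    def _cohort(self):
        occs = []
        for pid, cas, scores in [
            ("p1", (18, 22, 20, 20), (95.0, 90.0, 92.0, 91.0)),
            ("p2", (25, 27, 30, 26), (88.0, 93.0, 90.0, 89.0)),
        ]:
            for i, (ca, s) in enumerate(zip(cas, scores)):
                occs.append(make_occ(pid, f"R{i}", s, ca=ca, sa=ca, sc=ca))
        return Cohort(occs)

    def test_every_cell_matches_brute_force_recomputation(self):
        cohort = self._cohort()
        zonesets = estimate_zones(cohort)
        tables = build_cohort_tables(cohort, zonesets)
        best = [95.0, 93.0]
        s_col = tables.descriptives["S"]
        assert s_col[0] == pytest.approx(np.mean(best))
        assert s_col[1] == pytest.approx(np.std(best, ddof=1))
        assert s_col[4] == pytest.approx(max(best))
        centers = [zonesets["p1"].ca.center, zonesets["p2"].ca.center]
        assert tables.descriptives["ca_M"][0] == pytest.approx(np.mean(centers))
        # classification report rebuilt per participant
        for row in tables.classification.itertuples():
            pcts = [
                correct_classification(
                    cohort.recalled(pid),
                    zonesets[pid].zone(row.subscale),
                    row.subscale,
                    tables.threshold.reported,
                )
                for pid in ("p1", "p2")
            ]
            assert row.mean_pct == pytest.approx(np.mean(pcts))
            assert row.min_pct == pytest.approx(min(pcts))
        assert ((tables.classification[["mean_pct", "min_pct", "max_pct"]] >= 0).all().all())

    def test_single_participant_sd_reported_as_zero(self):
        occs = [
            make_occ("p1", f"R{i}", s, ca=ca)
            for i, (ca, s) in enumerate(zip((18, 20, 22, 20), (92.0, 90.0, 95.0, 91.0)))
        ]
        cohort = Cohort(occs)
        tables = build_cohort_tables(cohort, estimate_zones(cohort))
        assert tables.descriptives["S"][1] == 0.0
        assert tables.descriptives["S"][0] == 95.0
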