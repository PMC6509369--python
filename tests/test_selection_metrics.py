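import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from opsel import selection_metrics as sm
from opsel.errors import UndefinedStatisticError
from opsel.neighborhoods import build_neighborhood
from opsel.survey_io import load_sightings
from tests.test_neighborhoods import make_band


def expanded_oracle(groups):
    """Brute-force variance/mean² of the expanded per-male success list."""
    vals = np.concatenate([[f] * m for f, m in groups]).astype(float)
    mean = vals.mean()
    return vals.var() / mean ** 2


class TestOpportunity:
    def test_all_equal_success_is_zero(self):
        assert sm.opportunity([(2, 3)]) == 0.0

    def test_two_male_hand_computation(self):
        # successes {2, 0}: mean 1, variance 1, I = 1
        assert sm.opportunity([(2, 1), (0, 1)]) == pytest.approx(1.0)

    def test_three_male_expanded_oracle(self):
        # successes {3, 1, 1}: mean 5/3, variance 8/9, I = 0.32
        assert sm.opportunity([(3, 1), (1, 2)]) == pytest.approx(0.32)

    def test_zero_mean_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            sm.opportunity([(0, 4)])
        with pytest.raises(UndefinedStatisticError):
            sm.opportunity([(1, 0)])

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(1, 8)),
                    min_size=1, max_size=10))
    def test_grouped_equals_expanded(self, groups):
        if sum(f * m for f, m in groups) == 0:
            return
        assert sm.opportunity(groups) == pytest.approx(
            expanded_oracle(groups), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(1, 8)),
                    min_size=1, max_size=10),
           st.integers(2, 7))
    def test_scale_invariance(self, groups, c):
        if sum(f * m for f, m in groups) == 0:
            return
        scaled = [(f * c, m) for f, m in groups]
        assert sm.opportunity(scaled) == pytest.approx(
            sm.opportunity(groups), abs=1e-9)


class TestEpisodes:
    ponds = np.array([[0.0, 0.0]])
    island = box(0, 0, 49, 1.5)

    def hood(self, bands, bachelors=0):
        bach = {(f"X{i}", 2008): np.array([[1.0, 0.5]])
                for i in range(bachelors)}
        h, _ = build_neighborhood(bands[0], bands, bach, self.ponds,
                                  self.island, radius_km=1e6)
        return h

    def test_single_band_neighborhood_total_is_zero(self):
        h = self.hood([make_band("a", 2008, [(1.0, 0.5)], mares=3)])
        assert sm.i_total(h) == 0.0

    def test_two_band_hand_computation(self):
        h = self.hood([make_band("a", 2008, [(1, 0.5)], mares=4),
                       make_band("b", 2008, [(2, 0.5)], mares=2)])
        assert sm.i_total(h) == pytest.approx(1.0 / 9.0)

    def test_tag_male_dilutes_total(self):
        # band with one tag (m=2, f=3) plus band (m=1, f=1): grouped
        # {(3,2),(1,1)}, expanded successes {3,3,1} -> 8/49
        h = self.hood([make_band("a", 2008, [(1, 0.5)], mares=3, tags=1),
                       make_band("b", 2008, [(2, 0.5)], mares=1)])
        vals = np.array([3.0, 3.0, 1.0])
        assert sm.i_total(h) == pytest.approx(vals.var() / vals.mean() ** 2)
        # tag band with one mare instead: grouped {(1,2),(3,1)}, expanded
        # {1,1,3} -> 0.32
        h = self.hood([make_band("a", 2008, [(1, 0.5)], mares=1, tags=1),
                       make_band("b", 2008, [(2, 0.5)], mares=3)])
        assert sm.i_total(h) == pytest.approx(0.32)

    def test_i_harem_closed_form(self):
        bands = [make_band("a", 2008, [(1, 0.5)])]
        # 1 holder among 4 qualified males -> (1 - 0.25) / 0.25 = 3
        assert sm.i_harem(self.hood(bands, bachelors=3)) == pytest.approx(3.0)
        # p = 0.5 -> 1
        assert sm.i_harem(self.hood(bands, bachelors=1)) == pytest.approx(1.0)
        # p = 1 -> 0
        assert sm.i_harem(self.hood(bands, bachelors=0)) == 0.0

    @pytest.mark.parametrize("holders,bachelors", [(1, 1), (2, 3), (5, 2),
                                                   (3, 9), (4, 0)])
    def test_i_harem_equals_bernoulli_form(self, holders, bachelors):
        bands = [make_band(str(i), 2008, [(1.0 + 0.01 * i, 0.5)])
                 for i in range(holders)]
        h = self.hood(bands, bachelors=bachelors)
        p = holders / (holders + bachelors)
        assert sm.i_harem(h) == pytest.approx((1 - p) / p, abs=1e-12)

    def test_i_harem_decreasing_in_holder_fraction(self):
        values = []
        for bachelors in (0, 1, 2, 4, 8, 16):
            h = self.hood([make_band("a", 2008, [(1, 0.5)])],
                          bachelors=bachelors)
            values.append(sm.i_harem(h))
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_i_mares_hand_computations(self):
        h = self.hood([make_band("a", 2008, [(1, 0.5)], mares=2),
                       make_band("b", 2008, [(2, 0.5)], mares=2)])
        assert sm.i_mares_given_harem(h) == 0.0
        h = self.hood([make_band("a", 2008, [(1, 0.5)], mares=3),
                       make_band("b", 2008, [(2, 0.5)], mares=1),
                       make_band("c", 2008, [(3, 0.5)], mares=1)])
        assert sm.i_mares_given_harem(h) == pytest.approx(0.32)


HEADER = ("date,occasion,year,individual_id,sex,age_class,status,band_id,"
          "x_km,y_km\n")


class TestLocalASR:
    def records(self, rows):
        recs, _ = load_sightings(io.StringIO(HEADER + rows))
        return recs

    def focal(self):
        return make_band("B1", 2008, [(5.0, 0.5)])

    def test_only_females_gives_zero(self):
        recs = self.records(
            "2008-06-01,1,2008,F1,F,4+,mare,B9,5.0,0.5\n"
            "2008-06-01,1,2008,F2,F,2-3,mare,B9,5.5,0.5\n")
        assert sm.local_asr(self.focal(), recs) == 0.0

    def test_equality_gives_half(self):
        recs = self.records(
            "2008-06-01,1,2008,M1,M,4+,bachelor,NA,5.0,0.5\n"
            "2008-06-01,1,2008,F1,F,4+,mare,B9,5.0,0.5\n"
            "2008-06-02,2,2008,M1,M,4+,bachelor,NA,5.0,0.5\n"
            "2008-06-02,2,2008,F1,F,4+,mare,B9,5.0,0.5\n")
        assert sm.local_asr(self.focal(), recs) == 0.5

    def test_mean_over_occasions(self):
        # occasion 1: 2 males, 3 females (0.4); occasion 2: 3 males,
        # 2 females (0.6) -> mean 0.5
        rows = []
        for i in range(2):
            rows.append(f"2008-06-01,1,2008,M{i},M,4+,bachelor,NA,5.0,0.5")
        for i in range(3):
            rows.append(f"2008-06-01,1,2008,F{i},F,4+,mare,B9,5.0,0.5")
        for i in range(3):
            rows.append(f"2008-06-02,2,2008,M{i},M,4+,bachelor,NA,5.0,0.5")
        for i in range(2):
            rows.append(f"2008-06-02,2,2008,F{i},F,4+,mare,B9,5.0,0.5")
        recs = self.records("\n".join(rows) + "\n")
        assert sm.local_asr(self.focal(), recs) == pytest.approx(0.5)

    def test_young_males_not_counted(self):
        recs = self.records(
            "2008-06-01,1,2008,M1,M,2-3,juvenile,NA,5.0,0.5\n"
            "2008-06-01,1,2008,F1,F,4+,mare,B9,5.0,0.5\n")
        assert sm.local_asr(self.focal(), recs) == 0.0

    def test_no_overlapping_adults_is_undefined(self):
        recs = self.records("2008-06-01,1,2008,M1,M,4+,bachelor,NA,40.0,0.5\n")
        with pytest.raises(UndefinedStatisticError):
            sm.local_asr(self.focal(), recs)


class TestSelectionTable:
    def test_one_row_per_male_year(self, small_table):
        assert small_table.groupby(["male_id", "year"]).size().max() == 1
        assert (small_table["asr"] >= 0).all()
        assert (small_table["asr"] <= 1).all()
        for col in ("I", "I_harem", "I_mares_given_harem"):
            assert (small_table[col] >= 0).all()

    def test_row_count_matches_band_seasons(self, small_table, small_bands):
        assert len(small_table) <= len(small_bands)
        assert len(small_table) > 0.9 * len(small_bands)
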