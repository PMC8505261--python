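import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moodmarkers.discovery import (DECREASED, INCREASED, MoodComparison,
                                   discovery_scores, enumerate_comparisons,
                                   internal_points, label_mood_state,
                                   score_ap_comparison, score_de_comparison)
from moodmarkers.preprocess import SCALE_LINEAR

from conftest import make_matrix, make_visits


class TestLabelMoodState:
    @pytest.mark.parametrize("sms7,state", [
        (0, "low"), (40, "low"), (41, "intermediate"), (50, "intermediate"),
        (59, "intermediate"), (60, "high"), (100, "high"),
    ])
    def test_cutoffs(self, sms7, state):
        assert label_mood_state(sms7) == state

    @pytest.mark.parametrize("bad", [-1, 101, 150.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            label_mood_state(bad)


class TestEnumerateComparisons:
    def test_low_high_low_gives_two(self):
        visits = make_visits([("a", 1, 0, "M", "BP", 20),
                              ("a", 2, 90, "M", "BP", 80),
                              ("a", 3, 180, "M", "BP", 30)])
        comps = enumerate_comparisons(visits)
        assert len(comps) == 2
        assert comps[0].sample_low == "a_v1" and comps[0].sample_high == "a_v2"
        assert comps[1].sample_low == "a_v3" and comps[1].sample_high == "a_v2"

    def test_intervening_intermediate_breaks_pair(self):
        visits = make_visits([("a", 1, 0, "M", "BP", 20),
                              ("a", 2, 90, "M", "BP", 50),
                              ("a", 3, 180, "M", "BP", 80)])
        assert enumerate_comparisons(visits) == []
        # the relaxed mode pairs any low with any high
        assert len(enumerate_comparisons(visits, adjacency="any")) == 1

    def test_matches_brute_force_on_synthetic_cohort(self, small_cohort):
        visits, _, _, _ = small_cohort
        disc = visits[visits["cohort"] == "discovery"]
        comps = enumerate_comparisons(disc)

        # independent brute-force enumeration over adjacent visit pairs
        expected = 0
        for _, grp in disc.groupby("subject_id"):
            grp = grp.sort_values("visit_number")
            s = ["low" if v <= 40 else "high" if v >= 60 else "mid"
                 for v in grp["sms7"]]
            expected += sum({s[i], s[i + 1]} == {"low", "high"}
                            for i in range(len(s) - 1))
        assert len(comps) == expected
        assert expected >= len(disc["subject_id"].unique())  # >=1 per subject


class TestDeScore:
    @pytest.mark.parametrize("fc,score", [
        (1.25, 1.0), (1.2, 1.0), (1.15, 0.5), (1.1, 0.5), (1.05, 0.0),
        (1 / 1.05, 0.0), (1 / 1.15, -0.5), (1 / 1.1, -0.5),
        (0.8, -1.0), (1 / 1.2, -1.0),
    ])
    def test_thresholds(self, fc, score):
        assert score_de_comparison(fc) == score

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            score_de_comparison(bad)

    def test_symmetry(self):
        for fc in (1.25, 1.15, 1.05):
            assert score_de_comparison(1 / fc) == -score_de_comparison(fc)


class TestDeScoreProperties:
    @given(st.floats(min_value=0.01, max_value=100.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, derandomize=True)
    def test_reciprocal_antisymmetry(self, fc):
        assert score_de_comparison(1.0 / fc) == -score_de_comparison(fc)

    @given(st.floats(min_value=0.01, max_value=100.0),
           st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_fold_change(self, a, b):
        lo, hi = sorted((a, b))
        assert score_de_comparison(lo) <= score_de_comparison(hi)


class TestApScore:
    @pytest.mark.parametrize("low,high,score", [
        (False, True, 1), (True, False, -1), (True, True, 0), (False, False, 0),
    ])
    def test_transitions(self, low, high, score):
        assert score_ap_comparison(low, high) == score


class TestInternalPoints:
    @pytest.mark.parametrize("pct,points", [
        (33.7, 2), (64.1, 4), (100.0, 6), (33.2, 0), (33.4, 2),
        (50.0, 4), (80.0, 6), (79.9, 4), (0.0, 0),
    ])
    def test_mapping(self, pct, points):
        assert internal_points(pct) == points


def _comparisons(pairs):
    return [MoodComparison("s", lo, hi, (1, 2), True) for lo, hi in pairs]


class TestDiscoveryScores:
    def test_all_plus_one_gives_six_points(self):
        # probeset doubling in every high-mood visit: fc 2 -> +1 each time
        m = make_matrix([[1, 2, 1, 2], [5, 5, 5, 5]],
                        ["l1", "h1", "l2", "h2"], scale=SCALE_LINEAR)
        res = discovery_scores(m, _comparisons([("l1", "h1"), ("l2", "h2")]), "DE")
        top = res.loc["p0"]
        assert top["raw_score"] == 2 and top["pct_of_max"] == 100.0
        assert top["internal_points"] == 6 and top["direction"] == INCREASED
        assert res.loc["p1", "internal_points"] == 0

    def test_ap_scoring(self):
        calls = pd.DataFrame([[False, True, False, True],
                              [True, True, True, False]],
                             index=["p0", "p1"],
                             columns=["l1", "h1", "l2", "h2"])
        m = make_matrix(np.ones((2, 4)), ["l1", "h1", "l2", "h2"],
                        scale=SCALE_LINEAR)
        res = discovery_scores(m, _comparisons([("l1", "h1"), ("l2", "h2")]),
                               "AP", calls=calls)
        assert res.loc["p0", "raw_score"] == 2        # turned on twice
        assert res.loc["p1", "raw_score"] == -1       # turned off once
        assert res.loc["p1", "direction"] == DECREASED

    def test_half_points_sum_unrounded(self):
        # fc 1.15 in each of three comparisons -> raw 1.5, pct 50 -> 4 points
        m = make_matrix([[1, 1.15, 1, 1.15, 1, 1.15]],
                        ["l1", "h1", "l2", "h2", "l3", "h3"],
                        scale=SCALE_LINEAR)
        comps = _comparisons([("l1", "h1"), ("l2", "h2"), ("l3", "h3")])
        res = discovery_scores(m, comps, "DE")
        assert res.loc["p0", "raw_score"] == pytest.approx(1.5)
        assert res.loc["p0", "pct_of_max"] == pytest.approx(50.0)
        assert res.loc["p0", "internal_points"] == 4

    def test_scale_invariance(self):
        # multiplying a subject's whole linear series by a constant leaves
        # every fold change, hence every DE score, unchanged
        rng = np.random.default_rng(5)
        vals = rng.uniform(10, 200, (6, 4))
        comps = _comparisons([("l1", "h1"), ("l2", "h2")])
        cols = ["l1", "h1", "l2", "h2"]
        base = discovery_scores(make_matrix(vals, cols, scale=SCALE_LINEAR),
                                comps, "DE")
        scaled_vals = vals.copy()
        scaled_vals[:, :2] *= 37.5  # first subject's two samples
        scaled = discovery_scores(make_matrix(scaled_vals, cols,
                                              scale=SCALE_LINEAR), comps, "DE")
        assert np.allclose(base["raw_score"], scaled["raw_score"])

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(10, 200, (8, 4))
        cols = ["a", "b", "c", "d"]
        m = make_matrix(vals, cols, scale=SCALE_LINEAR)
        fwd = discovery_scores(m, _comparisons([("a", "b"), ("c", "d")]), "DE")
        rev = discovery_scores(m, _comparisons([("b", "a"), ("d", "c")]), "DE")
        assert np.allclose(fwd["raw_score"], -rev["raw_score"])

    def test_log2_input_equivalent_to_linear(self):
        rng = np.random.default_rng(7)
        lin = rng.uniform(10, 200, (5, 4))
        cols = ["a", "b", "c", "d"]
        comps = _comparisons([("a", "b"), ("c", "d")])
        from_lin = discovery_scores(make_matrix(lin, cols, scale=SCALE_LINEAR),
                                    comps, "DE")
        from_log = discovery_scores(make_matrix(np.log2(lin), cols), comps, "DE")
        assert np.allclose(from_lin["raw_score"], from_log["raw_score"])

    def test_empty_comparisons_rejected(self):
        m = make_matrix([[1.0]], ["a"], scale=SCALE_LINEAR)
        with pytest.raises(ValueError):
            discovery_scores(m, [], "DE")
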