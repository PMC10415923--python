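"""Wilcoxon, Kaplan-Meier, log-rank, markers, gain/loss, IC50 ranking."""

import numpy as np
import pandas as pd
import pytest

from twinmatch.comparative import (
    compare_markers,
    gof_lof_call,
    km_estimate,
    logrank_test,
    rank_drug_sensitivity,
    wilcoxon_ranksum,
)
from twinmatch.errors import ComparativeError

from conftest import enumerate_wilcoxon_p, product_limit_by_hand


class TestWilcoxon:
    def test_exact_toy_case(self):
        w, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6], mode="exact")
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1, rel=1e-12)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="normal")
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_for_all_small_partitions(self):
        rng = np.random.default_rng(9)
        for nx, ny in [(1, 1), (2, 3), (3, 3), (4, 4), (2, 7), (5, 5)]:
            vals = rng.permutation(np.arange(1, nx + ny + 1)).astype(float)
            x, y = vals[:nx], vals[nx:]
            _, p = wilcoxon_ranksum(x, y, mode="exact")
            assert p == pytest.approx(enumerate_wilcoxon_p(x, y), abs=1e-12)

    def test_exact_refused_with_ties(self):
        with pytest.raises(ComparativeError, match="ties"):
            wilcoxon_ranksum([1, 1, 2], [3, 4, 5], mode="exact")

    def test_exact_refused_for_large_samples(self):
        with pytest.raises(ComparativeError, match="<= 20"):
            wilcoxon_ranksum(np.arange(15), np.arange(15) + 100, mode="exact")

    def test_empty_sample_is_error(self):
        with pytest.raises(ComparativeError):
            wilcoxon_ranksum([], [1.0])

    def test_auto_picks_exact_when_permitted(self):
        _, p_auto = wilcoxon_ranksum([1, 2, 3], [4, 5, 6], mode="auto")
        assert p_auto == pytest.approx(0.1, rel=1e-12)


class TestKaplanMeier:
    def test_four_uncensored_deaths(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.event_times == (1.0, 2.0, 3.0, 4.0)
        assert curve.survival == pytest.approx((0.75, 0.5, 0.25, 0.0))
        assert curve.at_risk == (4, 3, 2, 1)
        assert curve.n_censored == 0

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert curve.event_times == ()
        assert curve.n_censored == 3

    def test_censored_six_subject_toy_matches_hand_product_limit(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 0, 1, 0, 1]
        curve = km_estimate(times, events)
        hand = product_limit_by_hand(times, events)
        assert curve.event_times == tuple(t for t, _, _ in hand)
        for s_est, (_, s_hand, n_risk), n_est in zip(
            curve.survival, hand, curve.at_risk
        ):
            assert s_est == pytest.approx(s_hand, abs=1e-12)
        assert curve.survival == pytest.approx((5 / 6, 2 / 3, 4 / 9, 0.0), abs=1e-12)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=40).round(3)
        curve = km_estimate(times, np.ones(40, dtype=int))
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_negative_time_is_error(self):
        with pytest.raises(ComparativeError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        # alternating deaths at t=1..6; summed O-E = 23/30, V = 1091/900
        stat, p = logrank_test([1, 3, 5], [1, 1, 1], [2, 4, 6], [1, 1, 1])
        assert stat == pytest.approx(529 / 1091, rel=1e-10)
        assert 0 < p < 1

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(8)
        ta, tb = rng.exponential(5, 30), rng.exponential(8, 25)
        ea, eb = np.ones(30, int), np.ones(25, int)
        s1, p1 = logrank_test(ta, ea, tb, eb)
        s2, p2 = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_no_events_is_error(self):
        with pytest.raises(ComparativeError, match="no events"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestCompareMarkers:
    def _markers(self):
        rng = np.random.default_rng(3)
        pos = [f"p{i}" for i in range(10)]
        neg = [f"n{i}" for i in range(30)]
        data = pd.DataFrame(
            {
                "CD8": np.concatenate([rng.uniform(0, 1, 10), rng.uniform(2, 3, 30)]),
                "CD14": rng.uniform(1, 2, 40),
                "flat": 5.0,
            },
            index=pos + neg,
        )
        return data, pos, neg

    def test_lower_abundance_detected_with_small_p(self):
        data, pos, neg = self._markers()
        res = compare_markers(data, pos, neg).set_index("marker")
        assert res.loc["CD8", "median_positive"] < res.loc["CD8", "median_negative"]
        assert res.loc["CD8", "p_value"] < 1e-4

    def test_constant_marker_p_one(self):
        data, pos, neg = self._markers()
        res = compare_markers(data, pos, neg).set_index("marker")
        assert res.loc["flat", "p_value"] == pytest.approx(1.0)

    def test_bh_matches_hand_step_up(self):
        data, pos, neg = self._markers()
        res = compare_markers(data, pos, neg)
        raw = res["p_value"].to_numpy()
        m = len(raw)
        order = np.argsort(raw)
        hand = np.empty(m)
        prev = 1.0
        for rank_pos, idx in enumerate(order[::-1]):
            i = m - rank_pos  # 1-based rank from the largest down
            prev = min(prev, raw[idx] * m / i)
            hand[idx] = prev
        assert res["p_adjusted"].to_numpy() == pytest.approx(hand, rel=1e-12)

    def test_invariant_under_positive_rescaling(self):
        data, pos, neg = self._markers()
        scaled = data.copy()
        scaled["CD8"] = scaled["CD8"] * 137.5
        p1 = compare_markers(data, pos, neg).set_index("marker").loc["CD8", "p_value"]
        p2 = compare_markers(scaled, pos, neg).set_index("marker").loc["CD8", "p_value"]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_disjoint_samples_is_error(self):
        data, pos, neg = self._markers()
        with pytest.raises(ComparativeError):
            compare_markers(data, ["absent1"], neg)


class TestGofLof:
    def _expression(self, mutant_vals, wt_vals):
        cols = [f"m{i}" for i in range(len(mutant_vals))] + [
            f"w{i}" for i in range(len(wt_vals))
        ]
        frame = pd.DataFrame(
            [list(mutant_vals) + list(wt_vals)], index=["KRAS"], columns=cols
        )
        mut = [c for c in cols if c.startswith("m")]
        wt = [c for c in cols if c.startswith("w")]
        return frame, mut, wt

    def test_higher_mutant_expression_called_gain(self):
        frame, mut, wt = self._expression([10, 11, 12, 13], [1, 2, 3, 4])
        call = gof_lof_call(frame, mut, wt, "KRAS")
        assert call.direction == "potential_gain"
        assert call.median_mutant > call.median_wildtype

    def test_lower_mutant_expression_called_loss(self):
        frame, mut, wt = self._expression([1, 2, 3, 4], [10, 11, 12, 13])
        call = gof_lof_call(frame, mut, wt, "KRAS")
        assert call.direction == "potential_loss"

    def test_single_mutant_insufficient(self):
        frame, mut, wt = self._expression([10], [1, 2, 3, 4])
        call = gof_lof_call(frame, mut, wt, "KRAS")
        assert call.direction == "insufficient_samples"
        assert call.p_value is None

    def test_overlapping_groups_indeterminate(self):
        rng = np.random.default_rng(0)
        frame, mut, wt = self._expression(rng.normal(0, 1, 10), rng.normal(0, 1, 10))
        call = gof_lof_call(frame, mut, wt, "KRAS")
        assert call.direction == "indeterminate"

    def test_missing_gene_is_error(self):
        frame, mut, wt = self._expression([1, 2, 3], [4, 5, 6])
        with pytest.raises(ComparativeError):
            gof_lof_call(frame, mut, wt, "TP53")


class TestDrugSensitivity:
    def _ic50(self):
        rng = np.random.default_rng(6)
        lines = [f"L{i}" for i in range(20)]
        frame = pd.DataFrame(
            np.exp(rng.normal(1.0, 0.5, size=(3, 20))),
            index=["drugA", "drugB", "drugC"],
            columns=lines,
        )
        # matched lines are strongly sensitive to drugA
        frame.loc["drugA", ["L0", "L1", "L2"]] = np.exp(-2.0)
        return frame

    def test_single_compound_rank_one(self):
        frame = self._ic50()
        rows = rank_drug_sensitivity(frame, ["L0", "L1"], ["drugB"])
        assert len(rows) == 1 and rows[0].rank == 1

    def test_sensitive_compound_ranked_first(self):
        rows = rank_drug_sensitivity(self._ic50(), ["L0", "L1", "L2"])
        assert rows[0].compound == "drugA"
        assert rows[0].relative_z < rows[1].relative_z
        assert [r.rank for r in rows] == [1, 2, 3]

    def test_missing_ic50_shrinks_n_lines(self):
        frame = self._ic50()
        frame.loc["drugB", "L0"] = np.nan
        rows = {r.compound: r for r in rank_drug_sensitivity(frame, ["L0", "L1", "L2"])}
        assert rows["drugB"].n_lines == rows["drugA"].n_lines - 1

    def test_rank_invariant_to_request_order(self):
        frame = self._ic50()
        r1 = rank_drug_sensitivity(frame, ["L0", "L1"], ["drugA", "drugB", "drugC"])
        r2 = rank_drug_sensitivity(frame, ["L0", "L1"], ["drugC", "drugB", "drugA"])
        assert [(r.compound, r.rank) for r in r1] == [(r.compound, r.rank) for r in r2]

    def test_no_requested_compound_is_error(self):
        with pytest.raises(ComparativeError):
            rank_drug_sensitivity(self._ic50(), ["L0"], ["nosuchdrug"])
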