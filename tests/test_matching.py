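"""Connecting scores, pre-match filtering, and community splits."""

import numpy as np
import pytest

import twinmatch as tm
from twinmatch.errors import MatchingError
from twinmatch.matching import (
    CohortSample,
    Criterion,
    alteration_match,
    connecting_score,
    extended_connecting_score,
    prematch_filter,
    score_cohort,
    split_communities,
)
from twinmatch.profiles import GeneAlteration

from conftest import brute_force_score, random_profile_and_sample


def _alt(gene, cls="mutation", pc=None):
    return GeneAlteration(gene, cls, pc)


def _sample(sid, *alts, **features):
    return CohortSample(sid, frozenset(alts), features)


class TestAlterationMatch:
    def test_gene_level_ignores_class(self):
        a = _alt("KRAS", "mutation", "p.G12D")
        b = _alt("KRAS", "amplification")
        assert alteration_match(a, b, "gene")
        assert not alteration_match(a, b, "gene_alteration")

    def test_gene_protein_compares_protein_change(self):
        a = _alt("KRAS", "mutation", "p.G12D")
        assert not alteration_match(a, _alt("KRAS", "mutation", "p.G12V"), "gene_protein")
        assert alteration_match(a, _alt("KRAS", "mutation", "p.G12D"), "gene_protein")

    def test_gene_protein_degrades_for_non_mutations(self):
        a = _alt("ERBB2", "amplification")
        assert alteration_match(a, _alt("ERBB2", "amplification"), "gene_protein")
        assert not alteration_match(a, _alt("ERBB2", "deletion"), "gene_protein")

    def test_different_genes_never_match(self):
        assert not alteration_match(_alt("APC"), _alt("TP53"), "gene")


class TestConnectingScore:
    def test_hand_counted_three_quarters(self, case_profile):
        # case has APC/TP53/KRAS/PARP2 mutations; the sample carries APC and
        # TP53 mutations plus a KRAS amplification -> 3 of 4 genes hit
        sample = _sample(
            "s1",
            _alt("APC", "mutation", "p.T1556fs"),
            _alt("TP53", "mutation", "p.R175H"),
            _alt("KRAS", "amplification"),
        )
        row = connecting_score(case_profile, sample, "gene")
        assert (row.n_matched, row.n_case_alterations) == (3, 4)
        assert row.score == pytest.approx(0.75)
        # stricter level: the KRAS amplification no longer satisfies the
        # KRAS mutation
        row2 = connecting_score(case_profile, sample, "gene_alteration")
        assert row2.n_matched == 2

    def test_superset_sample_scores_one(self, case_profile):
        sample = _sample("s", *case_profile.alterations, _alt("EXTRA"))
        assert connecting_score(case_profile, sample, "gene_protein").score == 1.0

    def test_disjoint_sample_scores_zero(self, case_profile):
        sample = _sample("s", _alt("BRAF"), _alt("NRAS"))
        assert connecting_score(case_profile, sample, "gene").score == 0.0

    def test_empty_gene_subset_is_error(self, case_profile):
        with pytest.raises(MatchingError, match="subset"):
            connecting_score(case_profile, _sample("s"), "gene", gene_subset=["MYC"])

    def test_case_alteration_counts_at_most_once(self):
        profile = tm.MolecularProfile.from_alterations("c", [_alt("KRAS")])
        sample = _sample(
            "s", _alt("KRAS", "mutation", "p.G12D"), _alt("KRAS", "mutation", "p.G13D")
        )
        assert connecting_score(profile, sample, "gene").n_matched == 1

    def test_score_distance_complement(self, case_profile):
        sample = _sample("s", _alt("APC", "mutation", "p.T1556fs"))
        row = connecting_score(case_profile, sample, "gene")
        assert row.distance == pytest.approx(1 - row.score)


class TestScoreOracle:
    """connecting_score equals the brute-force double-loop counter."""

    @pytest.mark.parametrize("level", ["gene", "gene_alteration", "gene_protein"])
    def test_matches_brute_force_on_random_pairs(self, level):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            profile, sample = random_profile_and_sample(rng)
            matched, total = brute_force_score(profile, sample, level)
            row = connecting_score(profile, sample, level)
            assert (row.n_matched, row.n_case_alterations) == (matched, total)
            assert row.score == matched / total

    def test_stricter_level_never_increases_score(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            profile, sample = random_profile_and_sample(rng)
            s_gene = connecting_score(profile, sample, "gene").score
            s_alt = connecting_score(profile, sample, "gene_alteration").score
            s_prot = connecting_score(profile, sample, "gene_protein").score
            assert s_gene >= s_alt >= s_prot

    def test_adding_matching_alteration_never_decreases_score(self, case_profile):
        rng = np.random.default_rng(5)
        for _ in range(100):
            _, sample = random_profile_and_sample(rng)
            before = connecting_score(case_profile, sample, "gene_alteration").score
            extra = _alt("APC", "mutation", "p.T1556fs")
            grown = CohortSample("g", sample.alterations | {extra}, {})
            after = connecting_score(case_profile, grown, "gene_alteration").score
            assert after >= before


class TestScoreCohort:
    def test_sorted_by_score_then_id(self, case_profile):
        full = _sample("z_full", *case_profile.alterations)
        half_b = _sample("B", _alt("APC", "mutation", "p.T1556fs"),
                         _alt("TP53", "mutation", "p.R175H"))
        half_a = _sample("A", _alt("KRAS", "mutation", "p.G12D"),
                         _alt("PARP2", "mutation", "p.I333V"))
        none = _sample("none", _alt("BRAF"))
        rows = score_cohort(case_profile, [none, half_b, full, half_a], "gene_protein")
        assert [r.sample_id for r in rows] == ["z_full", "A", "B", "none"]

    def test_full_gene_subset_is_identity(self, case_profile):
        samples = [
            _sample("a", _alt("APC", "mutation", "p.T1556fs")),
            _sample("b", _alt("KRAS", "mutation", "p.G12D"), _alt("BRAF")),
        ]
        base = score_cohort(case_profile, samples, "gene")
        sub = score_cohort(case_profile, samples, "gene",
                           gene_subset=case_profile.gene_set("total"))
        assert [(r.sample_id, r.score) for r in base] == [
            (r.sample_id, r.score) for r in sub
        ]

    def test_empty_cohort_is_error(self, case_profile):
        with pytest.raises(MatchingError, match="empty cohort"):
            score_cohort(case_profile, [], "gene")


class TestPrematchFilter:
    def _samples(self):
        return [
            _sample("low", tmb=3.0, ms_status="MSS"),
            _sample("high", tmb=12.0, ms_status="MSS"),
            _sample("msi", tmb=4.0, ms_status="MSI-H"),
            _sample("nofeat"),
        ]

    def test_tmb_threshold(self):
        kept = prematch_filter(self._samples(), ["tmb<10"])
        assert {s.sample_id for s in kept} == {"low", "msi"}

    def test_ms_status_equality(self):
        kept = prematch_filter(self._samples(), ["ms_status=MSS"])
        assert {s.sample_id for s in kept} == {"low", "high"}

    def test_conjunction(self):
        kept = prematch_filter(self._samples(), ["tmb<10", "ms_status=MSS"])
        assert {s.sample_id for s in kept} == {"low"}

    def test_contradictory_bounds_empty_not_error(self):
        kept = prematch_filter(self._samples(), ["tmb<3", "tmb>12"])
        assert kept == []

    def test_missing_value_fails_criterion(self):
        kept = prematch_filter(self._samples(), ["tmb<100"])
        assert "nofeat" not in {s.sample_id for s in kept}

    def test_unknown_feature_is_error(self):
        with pytest.raises(MatchingError, match="unknown feature"):
            prematch_filter(self._samples(), ["stage=IV"])

    def test_in_set_comparator(self):
        kept = prematch_filter(self._samples(), ["ms_status in MSI-H;MSI-L"])
        assert {s.sample_id for s in kept} == {"msi"}

    def test_tuple_criteria_accepted(self):
        kept = prematch_filter(self._samples(), [("tmb", "<=", 4.0)])
        assert {s.sample_id for s in kept} == {"low", "msi"}

    def test_criterion_parse_rejects_garbage(self):
        with pytest.raises(MatchingError):
            Criterion.parse("???")


class TestSplitCommunities:
    def _scores(self):
        return [
            tm.ScoreRow("s1", 1.0, 4, 4),
            tm.ScoreRow("s2", 0.8, 4, 5),
            tm.ScoreRow("s3", 0.75, 3, 4),
        ]

    def test_at_cutoff_is_positive(self):
        a = split_communities(self._scores(), 0.8)
        assert a.dt_positive == {"s1", "s2"}
        assert a.dt_negative == {"s3"}

    def test_cutoff_zero_all_positive(self):
        a = split_communities(self._scores(), 0.0)
        assert a.dt_negative == frozenset()

    def test_cutoff_one_without_perfect_matches(self):
        a = split_communities(self._scores()[1:], 1.0)
        assert a.dt_positive == frozenset()

    @pytest.mark.parametrize("cutoff", [-0.1, 1.1])
    def test_cutoff_out_of_range(self, cutoff):
        with pytest.raises(MatchingError):
            split_communities(self._scores(), cutoff)

    def test_partition_covers_all_samples(self):
        a = split_communities(self._scores(), 0.5)
        assert a.dt_positive | a.dt_negative == {"s1", "s2", "s3"}
        assert not (a.dt_positive & a.dt_negative)

    def test_nested_in_cutoff(self):
        rng = np.random.default_rng(3)
        scores = [tm.ScoreRow(f"s{i}", float(v), 0, 1)
                  for i, v in enumerate(rng.random(50))]
        prev = None
        for cutoff in (0.2, 0.5, 0.8):
            pos = split_communities(scores, cutoff).dt_positive
            if prev is not None:
                assert pos <= prev
            prev = pos


class TestExtendedScore:
    def test_no_shared_biomarkers_returns_genomic(self, case_profile):
        sample = _sample("s", _alt("APC", "mutation", "p.T1556fs"))
        base = connecting_score(case_profile, sample, "gene").score
        assert extended_connecting_score(case_profile, sample, "gene").score == base

    def test_blends_biomarker_agreement(self, case_profile):
        # genomic 0.25; biomarkers: tmb within 2x agrees, ms_status differs
        sample = _sample("s", _alt("APC", "mutation", "p.T1556fs"),
                         tmb=5.0, ms_status="MSI-H")
        row = extended_connecting_score(case_profile, sample, "gene", weight=0.5)
        assert row.score == pytest.approx(0.5 * 0.25 + 0.5 * 0.5)
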