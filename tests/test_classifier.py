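"""Haplogroup screening, hierarchical assignment, and frequency tables."""

import pytest
from hypothesis import given, settings, strategies as st

from bovmito.classifier import (
    ClassificationResult,
    aggregate_frequencies,
    classify,
    round_half_up,
    screen_T1,
)
from bovmito.reference_variants import CoverageError, HaplotypeProfile, Region


class TestScreen:
    def test_full_motif_passes(self, make_profile):
        assert screen_T1(make_profile("16050", "16113", "16255"))

    def test_empty_profile_fails(self, make_profile):
        assert not screen_T1(make_profile())

    def test_single_reversion_tolerated(self, make_profile):
        assert screen_T1(make_profile("16113", "16255", "7542"))
        assert screen_T1(make_profile("16050", "16255"))

    def test_16255_required(self, make_profile):
        # two motif positions without the anchor are not enough
        assert not screen_T1(make_profile("16050", "16113"))
        assert not screen_T1(make_profile("16113"))

    def test_uncovered_motif_raises_not_false(self, make_profile):
        profile = make_profile("200", covered=Region(1, 600))
        with pytest.raises(CoverageError):
            screen_T1(profile)


class TestClassify:
    @pytest.mark.parametrize(
        "labels,expected,missing",
        [
            (("16050", "16113", "16255", "7542", "16022"), "T1b1", []),
            (("16113", "16255", "7542"), "T1b", ["16050"]),
            (("16113", "16255", "8"), "T1e", []),
            (("16050", "16255", "12492"), "T1f", []),
            (("16050", "16113", "16255", "2055+C"), "T1a", []),
            (("16050", "16113", "16255", "6235", "4856", "1600d"), "T1d1", []),
            (
                ("16050", "16113", "16255", "16122", "16196", "16053",
                 "1324", "11542", "16139"),
                "T1c1a1",
                [],
            ),
        ],
    )
    def test_assignments(self, hierarchy, make_profile, labels, expected, missing):
        result = classify(make_profile(*labels), hierarchy)
        assert result.best_node == expected
        assert result.missing_expected == missing
        assert result.path[-1] == expected

    def test_reverted_16050_with_16122_is_ambiguous_vs_T1e(self, hierarchy, make_profile):
        # the hypervariable 16122 alone cannot decide between a T1c member
        # with a 16050 reversion and a T1e member lacking the np 8 transition
        result = classify(make_profile("16113", "16255", "16122"), hierarchy)
        assert result.best_node == "T1c"
        assert result.ambiguous
        assert result.alternative_nodes[0][0] == "T1e"
        assert result.missing_expected == ["16050"]

    def test_non_t1_profile_unclassified(self, hierarchy, make_profile):
        result = classify(make_profile("5000"), hierarchy)
        assert result.best_node == "unclassified"
        assert not result.classified

    def test_incompatible_coding_markers_reported_ambiguous(self, hierarchy, make_profile):
        result = classify(
            make_profile("16050", "16113", "16255", "7542", "6235"), hierarchy
        )
        names = {result.best_node} | {n for n, _ in result.alternative_nodes}
        assert result.ambiguous
        assert {"T1b", "T1d"} <= names

    def test_nodal_t1_not_flagged_ambiguous(self, hierarchy, make_profile):
        result = classify(make_profile("16050", "16113", "16255"), hierarchy)
        assert result.best_node == "T1"
        assert not result.ambiguous

    def test_deterministic(self, hierarchy, make_profile):
        a = classify(make_profile("16113", "16255", "16122"), hierarchy)
        b = classify(make_profile("16113", "16255", "16122"), hierarchy)
        assert a == b

    @given(
        extra=st.sets(
            st.sampled_from(["16022", "16196", "16053"]), max_size=3
        )
    )
    @settings(derandomize=True, max_examples=30)
    def test_adding_deeper_markers_never_moves_shallower(
        self, hierarchy, extra
    ):
        base_labels = {"16050", "16113", "16255", "16122"}
        region = Region(1, 16338)
        base = classify(
            HaplotypeProfile.from_labels("x", base_labels, region), hierarchy
        )
        richer = classify(
            HaplotypeProfile.from_labels("x", base_labels | extra, region), hierarchy
        )
        assert len(richer.path) >= len(base.path)

    def test_ancestor_markers_satisfied_or_reported_missing(self, hierarchy, make_profile):
        result = classify(make_profile("16113", "16255", "7542", "16022"), hierarchy)
        path_markers = {
            m.label
            for name in result.path
            for m in hierarchy.nodes[name].markers
            if not m.required_absent
        }
        assert set(result.missing_expected) <= path_markers
        assert set(result.matched_markers) & path_markers


class TestAggregation:
    def _results_and_meta(self, counts):
        results, meta = [], {}
        i = 0
        for (continent, country, breed, group), n in counts.items():
            for _ in range(n):
                sid = f"s{i}"
                results.append(ClassificationResult(sid, group, path=["T1", group]))
                meta[sid] = {"breed": breed, "country": country, "continent": continent}
                i += 1
        return results, meta

    def test_single_sample_is_100_percent(self, hierarchy):
        results, meta = self._results_and_meta(
            {("Europe", "Italy", "Chianina", "T1a"): 1}
        )
        table = aggregate_frequencies(results, meta, hierarchy)
        assert table.percent("TOTAL", "T1a") == 100.0
        assert table.count("TOTAL", "Total") == 1

    def test_survey_counts_reproduce_published_percentages(self, hierarchy):
        from bovmito.synthetic_data import survey_cohort_spec

        spec = survey_cohort_spec()
        counts = {
            (r.continent, r.country, r.breed, r.haplogroup): r.count for r in spec.rows
        }
        results, meta = self._results_and_meta(counts)
        table = aggregate_frequencies(results, meta, hierarchy)
        assert table.count("TOTAL", "Total") == 281
        assert table.percent("Europe total", "T1a") == 65.0
        assert table.percent("TOTAL", "T1b") == 49.1
        assert table.percent("Egypt total", "T1c") == 38.5
        assert table.percent("Ethiopia total", "T1b") == 69.4
        # each row's group counts sum to its total
        group_cols = [c for c in table.counts.columns if c != "Total"]
        assert (
            table.counts[group_cols].sum(axis=1) == table.counts["Total"]
        ).all()

    def test_missing_metadata_goes_to_rejects(self, hierarchy):
        results, meta = self._results_and_meta(
            {("Europe", "Italy", "Chianina", "T1a"): 2}
        )
        results.append(ClassificationResult("orphan", "T1b", path=["T1", "T1b"]))
        table = aggregate_frequencies(results, meta, hierarchy)
        assert table.rejects == ["orphan"]
        assert table.count("TOTAL", "Total") == 2

    def test_deep_clades_pool_into_top_level(self, hierarchy):
        results = [
            ClassificationResult("a", "T1c1a1", path=["T1", "T1c", "T1c1", "T1c1a", "T1c1a1"]),
            ClassificationResult("b", "T1b1", path=["T1", "T1b", "T1b1"]),
        ]
        meta = {
            "a": {"breed": "X", "country": "Egypt", "continent": "Africa"},
            "b": {"breed": "X", "country": "Egypt", "continent": "Africa"},
        }
        table = aggregate_frequencies(results, meta, hierarchy)
        assert table.count("TOTAL", "T1c") == 1
        assert table.count("TOTAL", "T1b") == 1


def test_round_half_up_matches_print_convention():
    assert round_half_up(65.05, 1) == 65.1
    assert round_half_up(49.1103, 1) == 49.1
    assert round_half_up(1.9825, 1) == 2.0
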