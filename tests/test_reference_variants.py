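"""Variant notation, circular regions, calling, and profile distances."""

import pytest
from hypothesis import given, settings, strategies as st

from bovmito.reference_variants import (
    CODING_REGION,
    CONTROL_REGION,
    CoverageError,
    HaplotypeProfile,
    Region,
    VariantCall,
    VariantKind,
    VariantLabelError,
    apply_variants,
    call_variants,
    parse_variant_label,
    profile_distance,
    transition_partner,
)


class TestRegions:
    def test_coding_region_length_is_15428(self, reference):
        assert CODING_REGION.length(reference.length) == 15791 - 364 + 1 == 15428

    def test_control_region_wraps_the_origin(self):
        assert CONTROL_REGION.wraps
        assert 16200 in CONTROL_REGION
        assert 200 in CONTROL_REGION
        assert 10000 not in CONTROL_REGION

    def test_wrapped_extraction_concatenates_around_origin(self, reference):
        seq = reference.extract(CONTROL_REGION)
        assert len(seq) == CONTROL_REGION.length(reference.length)
        assert seq.startswith(reference.sequence[15717:15727])
        assert seq.endswith(reference.sequence[:517][-10:])


class TestVariantLabels:
    @pytest.mark.parametrize(
        "label,kind,position",
        [
            ("16050", VariantKind.TRANSITION, 16050),
            ("2055+C", VariantKind.INSERTION, 2055),
            ("1600d", VariantKind.DELETION, 1600),
            ("@16113", VariantKind.TRANSITION, 16113),
            ("16057A", VariantKind.TRANSVERSION, 16057),
            ("8h", VariantKind.TRANSITION, 8),
        ],
    )
    def test_parse_examples(self, label, kind, position):
        call = parse_variant_label(label)
        assert call.kind is kind
        assert call.position == position
        assert call.back_mutation == label.startswith("@")
        assert call.heteroplasmic == label.endswith("h")

    @pytest.mark.parametrize("label", ["", "x123", "123e", "123+", "@@12", "12hh"])
    def test_malformed_labels_raise(self, label):
        with pytest.raises(VariantLabelError):
            parse_variant_label(label)

    @given(
        back=st.booleans(),
        pos=st.integers(min_value=1, max_value=16338),
        suffix=st.sampled_from(["", "A", "C", "G", "T", "+A", "+C", "+G", "+T", "d"]),
        het=st.booleans(),
    )
    @settings(derandomize=True, max_examples=200)
    def test_label_round_trip(self, back, pos, suffix, het):
        label = ("@" if back else "") + str(pos) + suffix + ("h" if het else "")
        assert parse_variant_label(label).label() == label


class TestCallVariants:
    def test_identity_gives_empty_profile(self, reference):
        profile = call_variants(reference.sequence, reference)
        assert len(profile) == 0

    def test_single_forced_transition(self, reference):
        seq = list(reference.sequence)
        seq[16049] = transition_partner(seq[16049])
        profile = call_variants("".join(seq), reference)
        assert profile.labels() == ["16050"]
        (call,) = profile.variants
        assert call.kind is VariantKind.TRANSITION

    def test_motif_plus_insertion_recovered_exactly(self, reference):
        # brute-force oracle: construct the sample by explicit edits, then
        # verify that calling recovers the same label set
        targets = ["16050", "16113", "16255", "2055+C"]
        seq = apply_variants(reference, [parse_variant_label(s) for s in targets])
        profile = call_variants(seq, reference)
        assert profile.labels() == sorted(targets, key=lambda s: int(s.rstrip("+C")))
        # position-by-position comparison against the untouched reference
        # confirms the substitutions (the insertion shifts the frame after it)
        for pos in (16050, 16113, 16255):
            assert profile.substitution_at(pos) is not None

    def test_short_sample_raises_coverage_error(self, reference):
        with pytest.raises(CoverageError):
            call_variants(reference.sequence[:1000], reference)

    def test_heteroplasmic_base_flagged(self, reference):
        seq = list(reference.sequence)
        code = {"A": "R", "G": "R", "C": "Y", "T": "Y"}[seq[7541]]
        seq[7541] = code
        profile = call_variants("".join(seq), reference)
        (call,) = profile.variants
        assert call.position == 7542 and call.heteroplasmic

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_apply_then_call_round_trip_random(self, reference, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        positions = rng.choice(np.arange(600, 15000, 10), size=8, replace=False)
        calls = []
        for pos in positions:
            pos = int(pos)
            base = reference.base(pos)
            if rng.random() < 0.7:
                calls.append(VariantCall(pos, VariantKind.TRANSITION))
            else:
                other = sorted(set("ACGT") - {base, transition_partner(base)})[0]
                calls.append(VariantCall(pos, VariantKind.TRANSVERSION, other))
        sample = apply_variants(reference, calls)
        profile = call_variants(sample, reference)
        assert profile.keys == frozenset(c.key for c in calls)
        # and re-applying the called profile reconstructs the sample
        assert apply_variants(reference, profile.variants) == sample


class TestProfileDistance:
    def test_identity_and_single_difference(self):
        a = HaplotypeProfile.from_labels("a", ["16050"])
        b = HaplotypeProfile.from_labels("b", [])
        assert profile_distance(a, a) == 0
        assert profile_distance(a, b) == 1

    def test_indels_excluded_when_substitutions_only(self):
        a = HaplotypeProfile.from_labels("a", ["1600d", "4856"])
        b = HaplotypeProfile.from_labels("b", [])
        assert profile_distance(a, b, CODING_REGION, substitutions_only=True) == 1
        assert profile_distance(a, b, CODING_REGION, substitutions_only=False) == 2

    def test_mismatched_references_raise(self):
        from bovmito.reference_variants import ReferenceMismatchError

        a = HaplotypeProfile.from_labels("a", ["100"], reference_name="ref1")
        b = HaplotypeProfile.from_labels("b", [], reference_name="ref2")
        with pytest.raises(ReferenceMismatchError):
            profile_distance(a, b)

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_distance_is_a_metric(self, data):
        labels = [str(p) for p in range(100, 130)]
        pick = st.sets(st.sampled_from(labels), max_size=10)
        a = HaplotypeProfile.from_labels("a", data.draw(pick))
        b = HaplotypeProfile.from_labels("b", data.draw(pick))
        c = HaplotypeProfile.from_labels("c", data.draw(pick))
        dab = profile_distance(a, b)
        assert dab == profile_distance(b, a)
        assert (dab == 0) == (a.keys == b.keys)
        assert dab <= profile_distance(a, c) + profile_distance(c, b)


class TestProfileInvariants:
    def test_two_substitutions_at_one_position_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeProfile(
                "x",
                frozenset(
                    {
                        VariantCall(100, VariantKind.TRANSITION),
                        VariantCall(100, VariantKind.TRANSVERSION, "A"),
                    }
                ),
            )

    def test_substitution_and_insertion_at_same_position_are_distinct(self):
        profile = HaplotypeProfile.from_labels("x", ["2055", "2055+C"])
        assert len(profile) == 2

    def test_variant_outside_covered_region_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeProfile.from_labels("x", ["300"], covered_region=Region(1000, 2000))
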