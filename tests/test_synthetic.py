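"""Synthetic references, cohorts, and clade expansions."""

import numpy as np
import pytest

from bovmito.classifier import classify
from bovmito.dating import rho, time_from_rho
from bovmito.reference_variants import call_variants
from bovmito.synthetic_data import (
    CohortRow,
    CohortSpec,
    ExpansionSpec,
    generate_cohort,
    generate_reference,
    simulate_expansion,
    survey_cohort_spec,
)


class TestReferenceGeneration:
    def test_seed_determinism(self):
        a = generate_reference(16338, 0.4, seed=1)
        b = generate_reference(16338, 0.4, seed=1)
        assert a.sequence == b.sequence

    def test_canonical_length_uses_published_regions(self):
        ref = generate_reference(seed=2)
        assert ref.regions["control"].start == 15718
        assert ref.regions["control"].end == 517
        assert ref.regions["coding"].start == 364
        assert ref.regions["coding"].end == 15791

    def test_scaled_regions_consistent(self):
        ref = generate_reference(1000, seed=3)
        control = ref.regions["control"]
        coding = ref.regions["coding"]
        assert control.wraps
        assert 1 <= coding.start < coding.end <= 1000
        assert control.length(1000) + 0 < 1000

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(100)

    @pytest.mark.parametrize("seed", [0, 4, 8])
    def test_marker_indels_keep_canonical_anchor(self, hierarchy, seed):
        # the insertion and deletion markers must survive an apply/call round
        # trip at their printed coordinates regardless of the random sequence
        from bovmito.synthetic_data import CohortRow, CohortSpec

        ref = generate_reference(seed=seed)
        spec = CohortSpec(
            [CohortRow("B", "C", "K", "T1a", 1), CohortRow("B", "C", "K", "T1d1", 1)],
            seed=seed,
            private_lambda=0.0,
        )
        cohort = generate_cohort(spec, ref, hierarchy)
        truth = dict(zip(cohort.metadata["sample"], cohort.metadata["true_haplogroup"]))
        for sid, seq in cohort.sequences.items():
            result = classify(call_variants(seq, ref, sample_id=sid), hierarchy)
            assert result.best_node == truth[sid]


class TestCohorts:
    def test_round_trip_counts_recovered_without_noise(self, reference, hierarchy):
        rows = [
            CohortRow("Chianina", "Italy", "Europe", "T1a", 3),
            CohortRow("Horro", "Ethiopia", "Africa", "T1b", 4),
            CohortRow("Menofi", "Egypt", "Africa", "T1c", 2),
            CohortRow("Calvana", "Italy", "Europe", "T1e", 2),
        ]
        cohort = generate_cohort(CohortSpec(rows, seed=11), reference, hierarchy)
        truth = dict(zip(cohort.metadata["sample"], cohort.metadata["true_haplogroup"]))
        for sid, seq in cohort.sequences.items():
            result = classify(call_variants(seq, reference, sample_id=sid), hierarchy)
            assert hierarchy.top_level(result.best_node) == truth[sid]

    def test_zero_count_rows_emit_nothing(self, reference, hierarchy):
        spec = CohortSpec([CohortRow("X", "Y", "Z", "T1a", 0)], seed=1)
        cohort = generate_cohort(spec, reference, hierarchy)
        assert not cohort.sequences

    def test_unknown_haplogroup_rejected(self, reference, hierarchy):
        spec = CohortSpec([CohortRow("X", "Y", "Z", "T9", 1)], seed=1)
        with pytest.raises(KeyError):
            generate_cohort(spec, reference, hierarchy)

    def test_forced_reversion_at_16050_reported_missing(self, reference, hierarchy):
        spec = CohortSpec(
            [CohortRow("Arsi", "Ethiopia", "Africa", "T1b", 5)],
            reversion_noise=1.0,
            reversion_positions=(16050,),
            private_lambda=0.0,
            seed=4,
        )
        cohort = generate_cohort(spec, reference, hierarchy)
        for sid, seq in cohort.sequences.items():
            result = classify(call_variants(seq, reference, sample_id=sid), hierarchy)
            assert result.best_node == "T1b"
            assert result.missing_expected == ["16050"]

    def test_bit_reproducible_for_fixed_seed(self, reference, hierarchy):
        spec_rows = [CohortRow("Boran", "Ethiopia", "Africa", "T1d", 3)]
        a = generate_cohort(CohortSpec(spec_rows, seed=9), reference, hierarchy)
        b = generate_cohort(CohortSpec(spec_rows, seed=9), reference, hierarchy)
        assert a.sequences == b.sequences

    def test_survey_spec_totals(self):
        spec = survey_cohort_spec()
        assert spec.total == 281
        assert {r.haplogroup for r in spec.rows} == {"T1a", "T1b", "T1c", "T1d", "T1e", "T1f"}


class TestExpansions:
    def test_age_zero_gives_identical_tips(self, reference):
        result = simulate_expansion(ExpansionSpec(n_tips=5, age_ka=0.0, seed=1), reference)
        assert all(not p.variants for p in result.profiles)
        assert result.mean_mutations == 0.0

    def test_true_tree_rho_equals_mean_poisson_draw(self, reference):
        spec = ExpansionSpec(n_tips=30, age_ka=11.6, seed=2)
        result = simulate_expansion(spec, reference)
        counts = [len(t.edge_mutations) for t in result.true_tree.tips()]
        assert result.mean_mutations == pytest.approx(np.mean(counts))

    def test_star_recovery_small(self, reference):
        # 50 replicates at the whole-haplogroup age: the mean estimate must
        # land within 3 standard errors of the simulated age
        ages = []
        for rep in range(50):
            spec = ExpansionSpec(n_tips=50, age_ka=11.6, seed=1000 + rep)
            result = simulate_expansion(spec, reference)
            ages.append(time_from_rho(rho(result.true_tree, region=None)))
        se = np.std(ages, ddof=1) / np.sqrt(len(ages))
        assert abs(np.mean(ages) - 11.6) <= 3 * se

    def test_coalescent_topology_paths_consistent(self, reference):
        spec = ExpansionSpec(n_tips=8, age_ka=6.0, topology="coalescent", seed=3)
        result = simulate_expansion(spec, reference)
        tree = result.true_tree
        for tip in tree.tips():
            state = set()
            for node in tree.path_from(tree.root, tip):
                for m in node.edge_mutations:
                    if m.gained:
                        state.add(m.call.key)
                    else:
                        state.discard(m.call.key)
            assert frozenset(state) == tip.profile

    def test_mutations_confined_to_counting_region(self, reference):
        spec = ExpansionSpec(n_tips=10, age_ka=11.6, seed=5)
        result = simulate_expansion(spec, reference)
        coding = reference.regions["coding"]
        for node in result.true_tree.walk():
            for m in node.edge_mutations:
                assert m.position in coding

    def test_determinism(self, reference):
        a = simulate_expansion(ExpansionSpec(n_tips=10, age_ka=4.8, seed=7), reference)
        b = simulate_expansion(ExpansionSpec(n_tips=10, age_ka=4.8, seed=7), reference)
        assert [p.keys for p in a.profiles] == [p.keys for p in b.profiles]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ExpansionSpec(n_tips=1, age_ka=1.0)
        with pytest.raises(ValueError):
            ExpansionSpec(n_tips=5, age_ka=-1.0)
        with pytest.raises(ValueError):
            ExpansionSpec(n_tips=5, age_ka=1.0, topology="ladder")
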